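"""On-disk artifacts of a run: FASTA alignments, traces, dumps, manifest.

Layout of the output directory::

    gene_1.fasta ... gene_n.fasta   one record per tip (same length, no
                                    indels, so each file is an alignment)
    branches/<name>/trace.tsv       fitness/participation trace
    branches/<name>/...             (tips only) regulatory dump, participation
    effective_config.txt            config as actually run, for exact replay
    run.log                         master seed, parameters, file list
    MANIFEST.txt                    sha256 checksum of every written file
"""

from __future__ import annotations

import hashlib
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .config import RunConfig, config_text
from .evolution import TraceRecord
from .phylogeny import PhylogenyRun
from .regulatory import RegulatoryParams

__all__ = ["write_outputs", "write_trace", "regulatory_dump"]

_TRACE_COLS = (
    "generation",
    "mean_total",
    "mean_boundedness",
    "mean_participation",
    "mean_stability",
    "fraction_mature",
)


def write_trace(trace: list[TraceRecord], path: Path) -> None:
    n = len(trace[0].gene_participation)
    header = "\t".join(_TRACE_COLS + tuple(f"participation_gene_{i+1}" for i in range(n)))
    lines = [header]
    for rec in trace:
        row = [str(rec.generation)] + [
            f"{getattr(rec, col):.6g}" for col in _TRACE_COLS[1:]
        ] + [f"{v:.6g}" for v in rec.gene_participation]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def regulatory_dump(params: RegulatoryParams, header: str = "") -> str:
    n = params.n_genes
    lines = [f"# {header}" if header else "# regulatory parameters", f"# n = {n}"]
    lines.append("# R (rows = target gene, columns = source gene)")
    for i in range(n):
        lines.append("\t".join(f"{v:.10g}" for v in params.R[i]))
    lines.append("# theta")
    lines.append("\t".join(f"{v:.10g}" for v in params.theta))
    lines.append("# lambda")
    lines.append("\t".join(f"{v:.10g}" for v in params.lam))
    return "\n".join(lines) + "\n"


def write_outputs(run: PhylogenyRun, config: RunConfig, out_dir) -> dict[str, str]:
    """Write all artifacts of a completed run; returns {relpath: sha256}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tips = sorted(run.lineages)
    for g in range(config.n_genes):
        records = [
            SeqRecord(
                Seq(run.lineages[tip].representative_genome.gene(g)),
                id=tip,
                description="",
            )
            for tip in tips
        ]
        path = out / f"gene_{g + 1}.fasta"
        SeqIO.write(records, path, "fasta")
        written.append(path)

    branches = out / "branches"
    for name, trace in run.branch_traces.items():
        bdir = branches / name
        bdir.mkdir(parents=True, exist_ok=True)
        tpath = bdir / "trace.tsv"
        write_trace(trace, tpath)
        written.append(tpath)
    for tip, res in run.lineages.items():
        bdir = branches / tip
        rpath = bdir / "regulatory.tsv"
        rpath.write_text(
            regulatory_dump(res.representative_regulatory, f"tip {tip} representative")
        )
        ppath = bdir / "participation.tsv"
        ppath.write_text(
            "gene\tparticipation\n"
            + "".join(
                f"{i + 1}\t{v:.6g}\n" for i, v in enumerate(res.participation)
            )
        )
        written.extend([rpath, ppath])

    cfg_path = out / "effective_config.txt"
    cfg_path.write_text(config_text(config))
    written.append(cfg_path)

    log_path = out / "run.log"
    log_lines = [
        f"master_seed = {config.master_seed}",
        f"tips = {', '.join(tips)}",
        f"defaulted_keys = {', '.join(config.defaulted_keys) or '(none)'}",
        "files:",
    ] + [f"  {p.relative_to(out)}" for p in written]
    log_path.write_text("\n".join(log_lines) + "\n")
    written.append(log_path)

    manifest: dict[str, str] = {}
    for p in written:
        manifest[str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "MANIFEST.txt").write_text(
        "".join(f"{digest}  {rel}\n" for rel, digest in sorted(manifest.items()))
    )
    return manifest
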