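"""Run configuration: a flat key = value text format with per-branch overrides.

Example::

    n_genes = 5
    gene_length = 3000
    mu = 5.33333e-6
    p = 0.1
    strategy = high_pressure
    population_size = 100
    dev_steps = 20
    master_seed = 42
    trace_every = 100

    [branch A]
    mu = 1e-5
    strategy = relaxed

Unknown keys and out-of-range values are rejected with a descriptive
error.  Every default actually applied is recorded so the run log can
state the full effective configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .errors import ConfigurationError
from .evolution import EvolutionParams
from .fitness import FitnessConfig
from .regulatory import RegInitConfig

__all__ = ["RunConfig", "load_config", "loads_config", "save_config", "config_text"]

_FLOAT_KEYS = {
    "mu", "p", "seed_quantity", "value_min", "value_max", "sparseness",
    "theta_min", "theta_max", "lam_min", "lam_max", "maturity_threshold",
    "growth_cap", "gaussian_sigma",
}
_INT_KEYS = {
    "n_genes", "gene_length", "population_size", "dev_steps", "master_seed",
    "trace_every", "marker_gene", "stability_window",
}
_STR_KEYS = {"strategy", "mutation_kernel"}
# keys overridable per branch (the evolutionary/regulatory/fitness surface)
_BRANCH_KEYS = _FLOAT_KEYS | (_INT_KEYS - {"n_genes", "gene_length", "master_seed", "trace_every"}) | _STR_KEYS


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    n_genes: int = 5
    gene_length: int = 3000
    mu: float = 5.33333e-6
    p: float = 0.1
    strategy: str = "high_pressure"
    population_size: int = 100
    dev_steps: int = 20
    seed_quantity: float = 1.0
    value_min: float = -2.0
    value_max: float = 2.0
    sparseness: float = 0.25
    theta_min: float = 0.0
    theta_max: float = 1.0
    lam_min: float = 0.0
    lam_max: float = 2.0
    mutation_kernel: str = "resample"
    gaussian_sigma: float = 0.1
    marker_gene: int = -1  # -1 = last gene
    maturity_threshold: float = 1.0
    stability_window: int = -1  # -1 = dev_steps // 5
    growth_cap: float = 1.0
    master_seed: int = 0
    trace_every: int = 100
    branch_overrides: dict[str, dict] = field(default_factory=dict)
    defaulted_keys: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self):
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.gene_length < 3 or self.gene_length % 3:
            raise ConfigurationError("gene_length must be a positive multiple of 3")
        if not 0.0 <= self.mu <= 1.0:
            raise ConfigurationError(f"mu must be in [0, 1], got {self.mu}")
        if not 0.0 < self.p <= 1.0:
            raise ConfigurationError(f"p must be in (0, 1], got {self.p}")
        if self.strategy not in ("high_pressure", "relaxed"):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        if self.population_size < 1:
            raise ConfigurationError("population_size must be >= 1")
        if self.dev_steps < 1:
            raise ConfigurationError("dev_steps must be >= 1")
        if not 0.0 <= self.sparseness <= 1.0:
            raise ConfigurationError("sparseness must be in [0, 1]")
        if self.maturity_threshold <= 0:
            raise ConfigurationError("maturity_threshold must be positive")
        if self.growth_cap <= 0:
            raise ConfigurationError("growth_cap must be positive")
        if self.trace_every < 1:
            raise ConfigurationError("trace_every must be >= 1")

    def to_evolution_params(self) -> EvolutionParams:
        return EvolutionParams(
            n_genes=self.n_genes,
            gene_length=self.gene_length,
            mu=self.mu,
            p=self.p,
            strategy=self.strategy,
            N=self.population_size,
            m=self.dev_steps,
            seed_quantity=self.seed_quantity,
            fitness_cfg=FitnessConfig(
                marker_gene=None if self.marker_gene < 0 else self.marker_gene,
                maturity_threshold=self.maturity_threshold,
                stability_window=None if self.stability_window < 0 else self.stability_window,
                growth_cap=self.growth_cap,
            ),
            reg_cfg=RegInitConfig(
                value_range=(self.value_min, self.value_max),
                sparseness=self.sparseness,
                theta_range=(self.theta_min, self.theta_max),
                lam_range=(self.lam_min, self.lam_max),
                mutation_kernel=self.mutation_kernel,
                gaussian_sigma=self.gaussian_sigma,
            ),
        )

    def evolution_overrides(self) -> dict[str, dict]:
        """Branch overrides translated to EvolutionParams keyword form."""
        out: dict[str, dict] = {}
        for branch, kv in self.branch_overrides.items():
            shadow = RunConfig(
                **{**{f.name: getattr(self, f.name) for f in fields(self)
                      if f.name not in ("branch_overrides", "defaulted_keys")},
                   **kv}
            )
            ep = shadow.to_evolution_params()
            out[branch] = {
                "mu": ep.mu, "p": ep.p, "strategy": ep.strategy, "N": ep.N,
                "m": ep.m, "seed_quantity": ep.seed_quantity,
                "fitness_cfg": ep.fitness_cfg, "reg_cfg": ep.reg_cfg,
            }
        return out


def _parse_value(key: str, raw: str):
    try:
        if key in _FLOAT_KEYS:
            return float(raw)
        if key in _INT_KEYS:
            return int(raw)
        if key in _STR_KEYS:
            return raw
    except ValueError as exc:
        raise ConfigurationError(f"bad value for {key!r}: {raw!r}") from exc
    raise ConfigurationError(f"unknown configuration key {key!r}")


def loads_config(text: str) -> RunConfig:
    """Parse the flat key = value format (see module docstring)."""
    top: dict = {}
    overrides: dict[str, dict] = {}
    current: dict | None = None
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            header = line[1:-1].strip()
            if not header.startswith("branch "):
                raise ConfigurationError(
                    f"line {lineno}: section must be '[branch NAME]', got {line!r}"
                )
            name = header[len("branch "):].strip()
            current = overrides.setdefault(name, {})
            continue
        if "=" not in line:
            raise ConfigurationError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        value = _parse_value(key, raw)
        if current is None:
            if key in top:
                raise ConfigurationError(f"line {lineno}: duplicate key {key!r}")
            top[key] = value
        else:
            if key not in _BRANCH_KEYS:
                raise ConfigurationError(
                    f"line {lineno}: {key!r} cannot be overridden per branch"
                )
            current[key] = value
    all_keys = _FLOAT_KEYS | _INT_KEYS | _STR_KEYS
    defaulted = tuple(sorted(all_keys - set(top)))
    return RunConfig(**top, branch_overrides=overrides, defaulted_keys=defaulted)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return loads_config(fh.read())


def config_text(cfg: RunConfig) -> str:
    lines = []
    for f in fields(cfg):
        if f.name in ("branch_overrides", "defaulted_keys"):
            continue
        lines.append(f"{f.name} = {getattr(cfg, f.name)!r}".replace("'", ""))
    for branch, kv in cfg.branch_overrides.items():
        lines.append("")
        lines.append(f"[branch {branch}]")
        for k, v in kv.items():
            lines.append(f"{k} = {v!r}".replace("'", ""))
    return "\n".join(lines) + "\n"


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(config_text(cfg))
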