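"""Regulatory genotype initialisation and the mutation-coupling rule."""

import numpy as np
import pytest

from grnevolve import (
    RegInitConfig,
    RegulatoryParams,
    active_link_set,
    apply_regulatory_mutation,
    init_regulatory,
    nonsense_effect,
)
from grnevolve.genome import NONSENSE, NONSYNONYMOUS, SYNONYMOUS

from conftest import make_E


def count_scalar_diffs(a: RegulatoryParams, b: RegulatoryParams) -> int:
    return (
        int((a.R != b.R).sum())
        + int((a.theta != b.theta).sum())
        + int((a.lam != b.lam).sum())
    )


def test_full_sparseness_gives_zero_matrix(rng):
    params = init_regulatory(4, RegInitConfig(sparseness=1.0), rng)
    assert not params.R.any()


def test_zero_sparseness_masks_nothing(rng):
    params = init_regulatory(4, RegInitConfig(sparseness=0.0), rng)
    assert (params.R != 0).all()


def test_sparseness_fraction_matches_bernoulli_expectation(rng):
    cfg = RegInitConfig(sparseness=0.3)
    zeros = total = 0
    for _ in range(10_000):
        R = init_regulatory(5, cfg, rng).R
        zeros += int((R == 0).sum())
        total += R.size
    frac = zeros / total
    se = np.sqrt(0.3 * 0.7 / total)
    assert abs(frac - 0.3) < 3 * se


def test_exact_sparseness_masks_exact_count(rng):
    cfg = RegInitConfig(sparseness=0.4, exact_sparseness=True)
    R = init_regulatory(5, cfg, rng).R
    assert int((R == 0).sum()) == 10  # 0.4 * 25


def test_init_ranges_respected(rng):
    cfg = RegInitConfig(value_range=(-1, 1), theta_range=(0.2, 0.3), lam_range=(1, 2))
    p = init_regulatory(6, cfg, rng)
    assert ((p.R >= -1) & (p.R <= 1)).all()
    assert ((p.theta >= 0.2) & (p.theta <= 0.3)).all()
    assert ((p.lam >= 1) & (p.lam <= 2)).all()


def test_nonnegative_ranges_enforced():
    with pytest.raises(ValueError):
        RegInitConfig(theta_range=(-0.1, 1.0))
    with pytest.raises(ValueError):
        RegInitConfig(value_range=(2.0, -2.0))


def test_active_link_set_single_expressed_source():
    E = make_E([[0, 1.0, 2.0], [0, 0, 0], [0, 0, 0]], q0=[0, 0, 0])
    assert active_link_set(E) == {(i, 0) for i in range(3)}


def test_active_link_set_all_expressed():
    E = make_E(np.ones((3, 4)), q0=[0, 0, 0])
    assert len(active_link_set(E)) == 9


def test_active_link_set_empty_for_silent_system():
    E = make_E(np.zeros((3, 4)), q0=[0, 0, 0])
    assert active_link_set(E) == set()


@pytest.mark.parametrize("classification", [SYNONYMOUS, NONSYNONYMOUS])
def test_mutation_changes_exactly_one_scalar_and_is_pure(rng, reg_cfg, classification):
    params = init_regulatory(5, reg_cfg, rng)
    snapshot = params.copy()
    E = make_E(np.vstack([np.ones((3, 4)), np.zeros((2, 4))]), q0=[1, 0, 0, 0, 0])
    for _ in range(200):
        new, target = apply_regulatory_mutation(params, 2, classification, E, reg_cfg, rng)
        assert count_scalar_diffs(params, new) == 1
        if target.kind == "R":
            assert target.gene == 2
    assert count_scalar_diffs(params, snapshot) == 0  # input untouched


def test_nonsynonymous_hits_active_sources_synonymous_inactive(rng, reg_cfg):
    E = make_E(np.vstack([np.ones((3, 4)), np.zeros((2, 4))]), q0=[1, 0, 0, 0, 0])
    active = {0, 1, 2}
    params = init_regulatory(5, reg_cfg, rng)
    for _ in range(500):
        _, t_non = apply_regulatory_mutation(params, 1, NONSYNONYMOUS, E, reg_cfg, rng)
        if t_non.kind == "R":
            assert t_non.source in active
        _, t_syn = apply_regulatory_mutation(params, 1, SYNONYMOUS, E, reg_cfg, rng)
        if t_syn.kind == "R":
            assert t_syn.source not in active


def test_synonymous_with_all_sources_active_falls_back_to_theta_lam(rng, reg_cfg):
    E = make_E(np.ones((4, 3)), q0=[1, 0, 0, 0])
    params = init_regulatory(4, reg_cfg, rng)
    for _ in range(300):
        new, target = apply_regulatory_mutation(params, 0, SYNONYMOUS, E, reg_cfg, rng)
        assert target.kind in ("theta", "lam")
        assert (new.R == params.R).all()


def test_theta_lam_allocation_frequency(rng, reg_cfg):
    """The theta/lambda share of regulatory hits converges to 2/(2+n)."""
    n = 5
    E = make_E(np.vstack([np.ones((3, 4)), np.zeros((2, 4))]), q0=[1, 0, 0, 0, 0])
    params = init_regulatory(n, reg_cfg, rng)
    draws = 20_000
    hits = 0
    for i in range(draws):
        cls = NONSYNONYMOUS if i % 2 else SYNONYMOUS
        _, target = apply_regulatory_mutation(params, 0, cls, E, reg_cfg, rng)
        hits += target.kind in ("theta", "lam")
    expect = 2 / (2 + n)
    se = np.sqrt(expect * (1 - expect) / draws)
    assert abs(hits / draws - expect) < 3 * se


def test_theta_lam_stay_nonnegative_under_mutation(rng, reg_cfg):
    params = init_regulatory(3, reg_cfg, rng)
    E = make_E(np.ones((3, 4)))
    for _ in range(500):
        params, _ = apply_regulatory_mutation(params, 1, NONSYNONYMOUS, E, reg_cfg, rng)
    assert (params.theta >= 0).all() and (params.lam >= 0).all()


def test_mutation_is_replayable_with_a_seed(reg_cfg):
    E = make_E(np.ones((3, 4)))
    params = init_regulatory(3, reg_cfg, np.random.default_rng(7))
    a, ta = apply_regulatory_mutation(
        params, 0, NONSYNONYMOUS, E, reg_cfg, np.random.default_rng(99)
    )
    b, tb = apply_regulatory_mutation(
        params, 0, NONSYNONYMOUS, E, reg_cfg, np.random.default_rng(99)
    )
    assert ta == tb
    assert count_scalar_diffs(a, b) == 0


def test_nonsense_classification_is_rejected_by_coupling(rng, reg_cfg):
    params = init_regulatory(3, reg_cfg, rng)
    with pytest.raises(ValueError):
        apply_regulatory_mutation(params, 0, NONSENSE, make_E(np.ones((3, 2))), reg_cfg, rng)


def test_nonsense_effect_leaves_parameters_untouched(rng, reg_cfg):
    params = init_regulatory(3, reg_cfg, rng)
    assert nonsense_effect(params) is params
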