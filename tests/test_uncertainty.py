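"""OWSA, PSA, CEAC, threshold pricing and subgroup hazard-ratio analysis."""

import dataclasses

import numpy as np
import pytest

from oncocea import (
    ParamSpec,
    PSADraws,
    ProportionalHazards,
    SubgroupSpec,
    ceac,
    dist_from_mean_range,
    owsa,
    run_pipeline,
    run_psa,
    subgroup_icer,
    threshold_price,
)

SG_PRICE_PATH = "arms.sg.regimen.sacituzumab.unit_price_per_mg"


def test_dist_from_mean_range_oracles():
    """Method-of-moments parameters recomputed by hand."""
    beta = dist_from_mean_range("beta", 0.85, 0.64, 1.0)
    assert beta["alpha"] == pytest.approx(12.0, rel=0.01)
    assert beta["beta"] == pytest.approx(2.118, rel=0.01)
    gamma = dist_from_mean_range("gamma", 1041.0, 781.0, 1302.0)
    assert gamma["shape"] == pytest.approx(61.35, rel=0.01)
    assert gamma["scale"] == pytest.approx(16.97, rel=0.01)
    normal = dist_from_mean_range("normal", 57.3, 43.0, 71.6)
    assert normal["se"] == pytest.approx(7.296, rel=0.001)
    with pytest.raises(ValueError):
        dist_from_mean_range("beta", 1.5, 1.0, 2.0)


def test_param_spec_ordering_enforced():
    with pytest.raises(ValueError):
        ParamSpec("x", 5.0, 6.0, 7.0, "gamma")
    with pytest.raises(ValueError):
        ParamSpec("x", 5.0, 4.0, 6.0, "cauchy")


def test_owsa_zero_span_and_unmapped(china_config):
    flat = [ParamSpec("utilities.u_pd", 0.52, 0.52, 0.52, "fixed")]
    entries = owsa(china_config, specs=flat)
    assert entries[0].span == pytest.approx(0.0)
    with pytest.raises(ValueError, match="unmapped"):
        owsa(china_config, specs=[ParamSpec("no.such.knob", 1, 1, 1, "fixed")])


def test_owsa_drug_price_dominates_tornado(china_config, us_config):
    """The reference drug's unit price leads the tornado (China); in the US
    the three near-equal leaders are the drug price, the progression-free
    utility and body weight — the trio the source analysis flags as most
    influential (all three ranges are ~+/-25%, and weight scales the
    weight-based dose one-for-one with price)."""
    assert owsa(china_config)[0].name == SG_PRICE_PATH
    top_us = [e.name for e in owsa(us_config)[:3]]
    assert SG_PRICE_PATH in top_us
    assert set(top_us) <= {SG_PRICE_PATH, "utilities.u_pfd", "population.weight_kg"}


def test_degenerate_psa_reproduces_base_case(china_config):
    fixed = [
        ParamSpec(s.name, s.base, s.base, s.base, "fixed")
        for s in china_config.param_specs
    ]
    cfg = dataclasses.replace(china_config, param_specs=fixed)
    draws = run_psa(cfg, n=8, seed=123)
    base = run_pipeline(china_config).ce
    assert np.allclose(draws.delta_cost, base.delta_cost)
    assert np.allclose(draws.delta_qalys, base.delta_qalys)


def test_psa_reproducible_and_centred(us_config):
    d1 = run_psa(us_config, n=150, seed=7)
    d2 = run_psa(us_config, n=150, seed=7)
    assert np.array_equal(d1.delta_cost, d2.delta_cost)
    assert np.array_equal(d1.delta_qalys, d2.delta_qalys)
    base = run_pipeline(us_config).ce
    # Monte-Carlo mean of the incremental effect stays near the base case
    se = d1.delta_qalys.std() / np.sqrt(d1.n)
    assert abs(d1.delta_qalys.mean() - base.delta_qalys) < 5 * se + 0.01


def test_ceac_monotone_and_strict_ties():
    draws = PSADraws(
        delta_cost=np.array([10.0, 50.0, 100.0]),
        delta_qalys=np.array([0.1, 0.5, 0.2]),
        seed=0,
        sampled={},
    )
    grid = [0.0, 100.0, 200.0, 500.0, 1000.0]
    curve = ceac(draws, grid)
    probs = [p for _, p in curve]
    assert probs == sorted(probs)  # all dE >= 0: monotone in WTP
    tie = PSADraws(np.array([100.0]), np.array([1.0]), 0, {})
    assert ceac(tie, [100.0])[0][1] == 0.0  # NMB exactly 0 counts against


def test_ceac_limits(us_config):
    draws = run_psa(us_config, n=100, seed=5)
    assert ceac(draws, [150000.0])[0][1] == 0.0  # base price: never cost-effective
    assert ceac(draws, [1e9])[0][1] == pytest.approx(1.0)  # WTP -> inf, all dE > 0


def test_threshold_price_monotone_in_target(us_config):
    p40 = threshold_price(us_config, wtp=150000.0, seed=11, target_prob=0.4, n_iter=300)
    p60 = threshold_price(us_config, wtp=150000.0, seed=11, target_prob=0.6, n_iter=300)
    assert p60 <= p40
    with pytest.raises(ValueError, match="monotone"):
        threshold_price(us_config, wtp=1.0, seed=11, target_prob=0.999, n_iter=100)


def test_subgroup_identity_and_monotonicity(china_config):
    same = subgroup_icer(china_config, SubgroupSpec("identity", 1.0, 1.0))
    assert abs(same.delta_qalys) < 0.02
    strong = subgroup_icer(china_config, SubgroupSpec("strong", 0.3, 0.3))
    weak = subgroup_icer(china_config, SubgroupSpec("weak", 0.7, 0.7))
    assert strong.delta_qalys > weak.delta_qalys
    assert strong.icer < weak.icer
    with pytest.raises(ValueError):
        SubgroupSpec("bad", -0.5, 1.0)


def test_subgroup_overall_hrs_near_base_case(china_config):
    """Feeding the overall trial HRs (0.48 OS, 0.41 PFS) through the
    proportional-hazards subgroup path lands in the base case's
    neighbourhood — a loose bound, since a PH reconstruction on the
    comparator baseline cannot equal the independently fitted curves."""
    ce = subgroup_icer(china_config, SubgroupSpec("overall", 0.48, 0.41))
    base = run_pipeline(china_config).ce
    assert ce.icer == pytest.approx(base.icer, rel=0.45)
    assert ce.delta_qalys > 0


def test_proportional_hazards_wrapper(china_config):
    base = china_config.arms["chemo"].os_model
    ph = ProportionalHazards(base, 0.5)
    t = np.linspace(0, 60, 20)
    assert np.allclose(ph.survival(t), np.asarray(base.survival(t)) ** 0.5)
    with pytest.raises(ValueError):
        ProportionalHazards(base, 0.0)
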