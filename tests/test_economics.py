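"""Dosing, per-cycle costs, discounted accrual and ICER logic."""

import dataclasses

import numpy as np
import pytest

from oncocea import (
    CohortTrace,
    CostInputs,
    DrugComponent,
    EconSettings,
    EngineSettings,
    Population,
    Regimen,
    StrategyResult,
    UtilitySet,
    accrue,
    ae_onetime,
    dose_mg,
    drug_cost_per_cycle,
    followup_cost_per_cycle,
    icer,
    run_pipeline,
)
from oncocea.economics import _effect_discount

SET = EngineSettings()
CN_POP = Population(weight_kg=57.3, bsa_m2=1.57)
US_POP = Population(weight_kg=77.5, bsa_m2=1.86)


def _component(**kw):
    base = dict(
        name="x",
        unit_price_per_mg=1.0,
        dose_rule="fixed",
        dose_value=100.0,
        administrations_per_cycle=1,
        native_cycle_days=28.0,
    )
    base.update(kw)
    return DrugComponent(**base)


def test_dose_rules():
    assert dose_mg(_component(dose_rule="per_kg", dose_value=10.0), CN_POP) == pytest.approx(573.0)
    assert dose_mg(_component(dose_rule="per_m2", dose_value=1.4), US_POP) == pytest.approx(2.604)
    assert dose_mg(_component(dose_rule="fixed", dose_value=100.0), CN_POP) == 100.0
    with pytest.raises(ValueError):
        _component(dose_rule="per_furlong")


def test_drug_cost_per_cycle_reference_arm():
    """Antibody-drug conjugate at 10 mg/kg, 2 doses per 21 d, rescaled to 28 d."""
    sg_us = Regimen("sg", (
        _component(name="sg", dose_rule="per_kg", dose_value=10.0,
                   unit_price_per_mg=11.2, administrations_per_cycle=2,
                   native_cycle_days=21.0),
    ))
    assert drug_cost_per_cycle(sg_us, US_POP, SET) == pytest.approx(
        775 * 2 * 11.2 * 28 / 21, rel=1e-9
    )  # ~ $23,147
    sg_cn = Regimen("sg", (
        _component(name="sg", dose_rule="per_kg", dose_value=10.0,
                   unit_price_per_mg=192.5, administrations_per_cycle=2,
                   native_cycle_days=21.0),
    ))
    assert drug_cost_per_cycle(sg_cn, CN_POP, SET) == pytest.approx(
        573 * 2 * 192.5 * 28 / 21, rel=1e-9
    )  # ~ CNY 294,140


def test_drug_cost_zero_proportions():
    reg = Regimen("mix", (_component(proportion=0.0), _component(name="y", proportion=0.0)))
    assert drug_cost_per_cycle(reg, CN_POP, SET) == 0.0


def test_followup_amortization_switch():
    assert followup_cost_per_cycle(0, 1041.0, SET) == pytest.approx(1041 * 2 / 3)
    late = int(np.ceil(36 * 7 / SET.cycle_days))
    assert followup_cost_per_cycle(late, 1041.0, SET) == pytest.approx(1041 * 4 / 9)
    assert followup_cost_per_cycle(3, 0.0, SET) == 0.0


def test_ae_onetime_terms():
    costs = {"neutropenia": 1000.0}
    assert ae_onetime({"neutropenia": 0.0}, costs, 0.28, SET) == (0.0, 0.0)
    cost, dec = ae_onetime({"neutropenia": 1.0}, costs, 0.28, SET)
    assert cost == pytest.approx(1000.0)
    assert dec == pytest.approx(0.28 * 28 / 365.25, rel=1e-9)  # ~0.02147
    with pytest.raises(ValueError):
        ae_onetime({"neutropenia": 1.2}, costs, 0.28, SET)


def test_ae_onetime_full_profile():
    """Spreadsheet oracle over the published China SG adverse-event rows."""
    probs = {"neutropenia": 0.512, "anemia": 0.078, "leukopenia": 0.101,
             "thrombocytopenia": 0.016, "diarrhea": 0.105,
             "nausea_vomiting": 0.039, "febrile_neutropenia": 0.058}
    costs = {"neutropenia": 2877.0, "anemia": 6298.0, "leukopenia": 2877.0,
             "thrombocytopenia": 1069.0, "diarrhea": 4152.0,
             "nausea_vomiting": 323.0, "febrile_neutropenia": 4283.0}
    expected = sum(probs[k] * costs[k] for k in probs)
    cost, _ = ae_onetime(probs, costs, 0.28, SET)
    assert cost == pytest.approx(expected, rel=1e-12)


def _flat_trace(n=SET.n_cycles):
    t = SET.boundaries_months()
    one = np.ones(n + 1)
    zero = np.zeros(n + 1)
    return CohortTrace(t_months=t, pfd=one, pd_=zero, dead=zero)


def _null_costs():
    return CostInputs(0.0, 0.0, {}, 0.0, 0.0)


def test_accrual_annuity_closed_form():
    """Full PFD occupancy: QALY equals the annual-step discount annuity."""
    trace = _flat_trace()
    reg = Regimen("none", (_component(unit_price_per_mg=0.0),))
    econ = EconSettings("china", 0.05, 0.0, 1.0, "CNY")
    res = accrue(trace, reg, CN_POP, _null_costs(), UtilitySet(1.0, 1.0, 0.0, 0.0),
                 {}, econ, SET)
    cy = SET.cycle_years
    expected = sum(cy * 1.05 ** -np.floor(k * cy) for k in range(SET.n_cycles))
    assert res.life_years == pytest.approx(expected, rel=1e-12)
    assert res.qalys == pytest.approx(expected, rel=1e-12)
    # zero discount: LY equals calendar coverage of the cycles
    econ0 = EconSettings("china", 0.0, 0.0, 1.0, "CNY")
    res0 = accrue(trace, reg, CN_POP, _null_costs(), UtilitySet(1.0, 1.0, 0.0, 0.0),
                  {}, econ0, SET)
    assert res0.life_years == pytest.approx(SET.n_cycles * cy, rel=1e-12)


def test_currency_invariance(china_config):
    """Scaling every cost by a constant scales dCost and ICER exactly."""
    factor = 7.3
    d = china_config.to_dict()
    for key in ("administration_per_month", "followup_per_visit",
                "bsc_per_cycle", "eol_per_death"):
        d["costs"][key] *= factor
    for ae in d["costs"]["ae_cost"]:
        d["costs"]["ae_cost"][ae] *= factor
    for arm in d["arms"].values():
        for comp in arm["regimen"]["components"]:
            comp["unit_price_per_mg"] *= factor
    from oncocea import ModelConfig

    scaled = ModelConfig.from_dict(d)
    base = run_pipeline(china_config).ce
    new = run_pipeline(scaled).ce
    assert new.delta_cost == pytest.approx(base.delta_cost * factor, rel=1e-12)
    assert new.icer == pytest.approx(base.icer * factor, rel=1e-12)
    assert new.delta_qalys == pytest.approx(base.delta_qalys, rel=1e-12)


@pytest.mark.parametrize("rates", [(0.0, 0.03), (0.03, 0.05), (0.05, 0.08)])
def test_discount_monotonicity(china_config, rates):
    lo, hi = rates
    results = []
    for r in (lo, hi):
        cfg = dataclasses.replace(
            china_config, econ=dataclasses.replace(china_config.econ, discount_rate=r)
        )
        results.append(run_pipeline(cfg).ce.reference)
    a, b = results
    assert b.life_years <= a.life_years
    assert b.qalys <= a.qalys
    for fieldname in ("cost_drug", "cost_admin", "cost_followup", "cost_bsc", "cost_eol"):
        assert getattr(b, fieldname) <= getattr(a, fieldname)


def test_qaly_never_exceeds_ly(china_ps, us_ps):
    for res in (china_ps, us_ps):
        for s in (res.ce.reference, res.ce.comparator):
            assert s.qalys <= s.life_years


def test_zero_price_wiring(us_config):
    """Free reference drug: the drug-cost difference is minus the comparator's."""
    d = us_config.to_dict()
    for comp in d["arms"]["sg"]["regimen"]["components"]:
        comp["unit_price_per_mg"] = 0.0
    from oncocea import ModelConfig

    ce = run_pipeline(ModelConfig.from_dict(d)).ce
    assert ce.reference.cost_drug == 0.0
    base = run_pipeline(us_config).ce
    assert ce.reference.cost_drug - ce.comparator.cost_drug == pytest.approx(
        -base.comparator.cost_drug
    )


def _strategy(cost, qaly):
    return StrategyResult("s", qaly, qaly, cost, 0, 0, 0, 0, 0)


def test_icer_cases():
    ce = icer(_strategy(175393 + 100.0, 0.35 + 0.0), _strategy(100.0, 0.0))
    assert ce.icer == pytest.approx(175393 / 0.35)  # ~ 501,123/QALY
    assert ce.dominance == "icer"
    dom = icer(_strategy(99.0, 0.1), _strategy(100.0, 0.0))
    assert dom.dominance == "dominant" and dom.icer is None
    dtd = icer(_strategy(101.0, -0.1), _strategy(100.0, 0.0))
    assert dtd.dominance == "dominated" and dtd.icer is None
    und = icer(_strategy(101.0, 0.5), _strategy(100.0, 0.5))
    assert und.dominance == "undefined" and und.icer is None


def test_effect_discount_steps_annually():
    disc = _effect_discount(SET, 0.05)
    # all cycles starting in the first model year are undiscounted
    first_year = int(np.ceil(1.0 / SET.cycle_years))
    assert np.all(disc[:first_year] == 1.0)
    assert disc[first_year] == pytest.approx(1 / 1.05)
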