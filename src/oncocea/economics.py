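"""Discounted cost and QALY accrual over a cohort trace, and ICERs.

Accrual conventions (fixed for the whole package, see docs/methods.md):

* Effectiveness (life-years, QALYs) accrues per cycle on the occupancy at
  the cycle's *start*, discounted annually with a beginning-of-year
  convention: a QALY accrued during year j is discounted by (1+r)^-(j-1).
* Costs accrue per cycle on the occupancy at the cycle's *end* (a cycle's
  treatment is charged to patients completing it in the state), discounted
  annually with an end-of-year convention: a cost in year j is discounted
  by (1+r)^-j.
* Adverse-event management costs and their disutility are one-time terms at
  cycle 0, undiscounted.

Drug, administration and follow-up costs accrue on progression-free
occupancy (treatment until progression), best supportive care on progressed
occupancy per cycle, and end-of-life care once per incident death.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort_engine import DAYS_PER_MONTH, CohortTrace, EngineSettings

__all__ = [
    "DrugComponent",
    "Regimen",
    "CostInputs",
    "UtilitySet",
    "Population",
    "EconSettings",
    "StrategyResult",
    "CEResult",
    "dose_mg",
    "drug_cost_per_cycle",
    "followup_cost_per_cycle",
    "ae_onetime",
    "accrue",
    "icer",
]

DOSE_RULES = ("per_kg", "per_m2", "fixed")


@dataclass(frozen=True)
class DrugComponent:
    """One drug of a regimen with its dosing rule and schedule."""

    name: str
    unit_price_per_mg: float
    dose_rule: str  # per_kg | per_m2 | fixed
    dose_value: float  # mg/kg, mg/m2 or mg per administration
    administrations_per_cycle: float  # per native treatment cycle
    native_cycle_days: float
    proportion: float = 1.0  # mixture share of patients on this drug
    oral: bool = False

    def __post_init__(self) -> None:
        if self.dose_rule not in DOSE_RULES:
            raise ValueError(f"unknown dose rule {self.dose_rule!r}")
        if self.native_cycle_days <= 0:
            raise ValueError("native cycle length must be positive")
        if not 0.0 <= self.proportion <= 1.0:
            raise ValueError("mixture proportion must lie in [0, 1]")
        if self.unit_price_per_mg < 0 or self.dose_value < 0:
            raise ValueError("prices and doses must be non-negative")


@dataclass(frozen=True)
class Regimen:
    """A treatment strategy: one drug or a proportion-weighted mixture."""

    name: str
    components: tuple[DrugComponent, ...]

    def __post_init__(self) -> None:
        if isinstance(self.components, list):
            object.__setattr__(self, "components", tuple(self.components))

    def scale_price(self, factor: float, drug: str | None = None) -> "Regimen":
        """Regimen with unit prices multiplied by ``factor`` (one drug or all)."""
        comps = tuple(
            replace(c, unit_price_per_mg=c.unit_price_per_mg * factor)
            if drug is None or c.name == drug
            else c
            for c in self.components
        )
        return replace(self, components=comps)


@dataclass(frozen=True)
class CostInputs:
    """Non-drug unit costs of one perspective."""

    administration_per_month: float
    followup_per_visit: float
    ae_cost: dict  # AE name -> cost per event
    bsc_per_cycle: float  # best supportive care, per model cycle in PD
    eol_per_death: float  # end-of-life care, once per death

    def __post_init__(self) -> None:
        vals = [self.administration_per_month, self.followup_per_visit,
                self.bsc_per_cycle, self.eol_per_death, *self.ae_cost.values()]
        if any(v < 0 for v in vals):
            raise ValueError("costs must be non-negative")


@dataclass(frozen=True)
class UtilitySet:
    u_pfd: float = 0.85
    u_pd: float = 0.52
    u_dead: float = 0.0
    ae_disutility: float = 0.28

    def __post_init__(self) -> None:
        for u in (self.u_pfd, self.u_pd, self.u_dead):
            if not 0.0 <= u <= 1.0:
                raise ValueError("utilities must lie in [0, 1]")
        if self.ae_disutility < 0:
            raise ValueError("disutility must be non-negative")


@dataclass(frozen=True)
class Population:
    """Cohort anthropometrics used for weight/BSA-based dosing."""

    weight_kg: float
    bsa_m2: float
    age: float = 56.0
    sex: str = "female"

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.bsa_m2 <= 0:
            raise ValueError("anthropometrics must be positive")


@dataclass(frozen=True)
class EconSettings:
    """Perspective-level economics: discounting, WTP, currency."""

    perspective: str  # 'china' | 'us'
    discount_rate: float
    wtp_low: float
    wtp_high: float
    currency: str
    cny_per_usd: float = 6.90

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        if self.wtp_low > self.wtp_high:
            raise ValueError("WTP bounds out of order")


@dataclass
class StrategyResult:
    """Discounted outcomes and itemized costs of one strategy."""

    name: str
    life_years: float
    qalys: float
    cost_drug: float
    cost_admin: float
    cost_followup: float
    cost_ae: float
    cost_bsc: float
    cost_eol: float

    @property
    def cost_total(self) -> float:
        return (self.cost_drug + self.cost_admin + self.cost_followup
                + self.cost_ae + self.cost_bsc + self.cost_eol)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "life_years": self.life_years,
            "qalys": self.qalys,
            "costs": {
                "drug": self.cost_drug,
                "administration": self.cost_admin,
                "followup": self.cost_followup,
                "adverse_events": self.cost_ae,
                "best_supportive_care": self.cost_bsc,
                "end_of_life": self.cost_eol,
                "total": self.cost_total,
            },
        }


@dataclass
class CEResult:
    """Two strategies compared: incremental cost, effect and ICER."""

    reference: StrategyResult  # the new treatment
    comparator: StrategyResult
    delta_cost: float
    delta_qalys: float
    delta_ly: float
    icer: float | None
    dominance: str  # 'icer' | 'dominant' | 'dominated' | 'undefined'

    def to_dict(self) -> dict:
        return {
            "strategies": [self.reference.to_dict(), self.comparator.to_dict()],
            "incremental": {
                "cost": self.delta_cost,
                "qalys": self.delta_qalys,
                "life_years": self.delta_ly,
                "icer": self.icer,
                "dominance": self.dominance,
            },
        }


# --- unit-cost building blocks --------------------------------------------


def dose_mg(component: DrugComponent, pop: Population) -> float:
    """Milligrams per administration under the component's dosing rule."""
    if component.dose_rule == "per_kg":
        return component.dose_value * pop.weight_kg
    if component.dose_rule == "per_m2":
        return component.dose_value * pop.bsa_m2
    if component.dose_rule == "fixed":
        return component.dose_value
    raise ValueError(f"unknown dose rule {component.dose_rule!r}")


def drug_cost_per_cycle(
    regimen: Regimen, pop: Population, settings: EngineSettings
) -> float:
    """Drug acquisition cost per model cycle (native schedule rescaled).

    Each component costs (administrations x mg x price) per native cycle,
    converted by cycle_days / native_cycle_days; mixtures are
    proportion-weighted sums (proportions used as given, not renormalized).
    """
    total = 0.0
    for comp in regimen.components:
        per_native = (
            comp.administrations_per_cycle * dose_mg(comp, pop) * comp.unit_price_per_mg
        )
        total += comp.proportion * per_native * settings.cycle_days / comp.native_cycle_days
    return total


def followup_cost_per_cycle(
    cycle: int, cost_per_visit: float, settings: EngineSettings
) -> float:
    """Amortized imaging/follow-up cost for one model cycle.

    Visits every 6 weeks while the cycle starts before week 36, every 9
    weeks thereafter; charged to progression-free occupancy by ``accrue``.
    """
    if cycle < 0:
        raise ValueError("cycle index must be non-negative")
    start_days = cycle * settings.cycle_days
    interval_days = 42.0 if start_days < 36 * 7 else 63.0
    return cost_per_visit * settings.cycle_days / interval_days


def ae_onetime(
    ae_probs: dict,
    ae_costs: dict,
    disutility: float,
    settings: EngineSettings,
) -> tuple[float, float]:
    """One-time adverse-event cost and QALY decrement (cycle 0).

    cost = sum p_AE x cost_AE; decrement = sum p_AE x disutility x cycle
    length in years (the AE burden is carried for the first cycle).
    """
    for name, p in ae_probs.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"AE probability for {name!r} outside [0, 1]")
        if name not in ae_costs:
            raise KeyError(f"no management cost for AE {name!r}")
    cost = sum(p * ae_costs[name] for name, p in ae_probs.items())
    decrement = sum(ae_probs.values()) * disutility * settings.cycle_years
    return cost, decrement


# --- accrual ---------------------------------------------------------------


def _effect_discount(settings: EngineSettings, rate: float) -> np.ndarray:
    """Per-cycle effect discount factors (beginning-of-year annual steps)."""
    k = np.arange(settings.n_cycles)
    years = np.floor(k * settings.cycle_years)
    return (1.0 + rate) ** (-years)


def _cost_discount(settings: EngineSettings, rate: float) -> np.ndarray:
    """Per-cycle cost discount factors (end-of-year annual steps)."""
    k = np.arange(settings.n_cycles)
    years = np.ceil((k + 1) * settings.cycle_years)
    return (1.0 + rate) ** (-years)


def accrue(
    trace: CohortTrace,
    regimen: Regimen,
    pop: Population,
    costs: CostInputs,
    utilities: UtilitySet,
    ae_probs: dict,
    econ: EconSettings,
    settings: EngineSettings,
) -> StrategyResult:
    """Discounted life-years, QALYs and itemized costs for one strategy."""
    if trace.n_cycles != settings.n_cycles:
        raise ValueError("trace length does not match engine settings")
    n = settings.n_cycles
    cy = settings.cycle_years
    disc_e = _effect_discount(settings, econ.discount_rate)
    disc_c = _cost_discount(settings, econ.discount_rate)

    pfd_start, pd_start = trace.pfd[:-1], trace.pd_[:-1]
    pfd_end, pd_end = trace.pfd[1:], trace.pd_[1:]
    deaths = np.diff(trace.dead)

    ly = float(np.sum((pfd_start + pd_start) * cy * disc_e))
    ae_cost, ae_dec = ae_onetime(ae_probs, costs.ae_cost, utilities.ae_disutility, settings)
    qaly = float(
        np.sum((pfd_start * utilities.u_pfd + pd_start * utilities.u_pd) * cy * disc_e)
    ) - ae_dec

    drug_pc = drug_cost_per_cycle(regimen, pop, settings)
    pfd_cost_sum = float(np.sum(pfd_end * disc_c))
    cost_drug = drug_pc * pfd_cost_sum
    cost_admin = (
        costs.administration_per_month * settings.cycle_months * pfd_cost_sum
    )
    fu_rates = np.array(
        [followup_cost_per_cycle(k, costs.followup_per_visit, settings) for k in range(n)]
    )
    cost_fu = float(np.sum(fu_rates * pfd_end * disc_c))
    cost_bsc = costs.bsc_per_cycle * float(np.sum(pd_end * disc_c))
    cost_eol = costs.eol_per_death * float(np.sum(deaths * disc_c))

    return StrategyResult(
        name=regimen.name,
        life_years=ly,
        qalys=qaly,
        cost_drug=cost_drug,
        cost_admin=cost_admin,
        cost_followup=cost_fu,
        cost_ae=ae_cost,
        cost_bsc=cost_bsc,
        cost_eol=cost_eol,
    )


def icer(reference: StrategyResult, comparator: StrategyResult) -> CEResult:
    """Incremental comparison; degenerate cases flagged, never divided."""
    d_cost = reference.cost_total - comparator.cost_total
    d_q = reference.qalys - comparator.qalys
    d_ly = reference.life_years - comparator.life_years
    if d_q > 0 and d_cost < 0:
        dom, ratio = "dominant", None
    elif d_q < 0 and d_cost > 0:
        dom, ratio = "dominated", None
    elif d_q == 0:
        dom, ratio = "undefined", None
    else:
        dom, ratio = "icer", d_cost / d_q
    return CEResult(
        reference=reference,
        comparator=comparator,
        delta_cost=d_cost,
        delta_qalys=d_q,
        delta_ly=d_ly,
        icer=ratio,
        dominance=dom,
    )
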