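"""Synthetic inputs: simulated trial IPD, digitized-KM fixtures, life
tables, and the two fully populated base-case configurations.

``builtin_configs`` embeds the complete published input set for the
sacituzumab govitecan vs single-agent chemotherapy comparison in metastatic
triple-negative breast cancer: fitted OS/PFS laws per arm, 2020 unit costs
for the China and US perspectives with sensitivity ranges, grade >= 3
adverse-event profiles, utilities and population anthropometrics.

The trial simulator and digitizer emulate the upstream data products
(figure-digitized KM coordinates plus number-at-risk tables) so the
reconstruction and fitting stages are testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_engine import EngineSettings, LifeTable
from .economics import (
    CostInputs,
    DrugComponent,
    EconSettings,
    Population,
    Regimen,
    UtilitySet,
)
from .km_reconstruct import DigitizedKM
from .survival_models import ParametricSurvival, inverse_survival
from .uncertainty import ParamSpec
from .workbench import ArmSpec, LifeTableSpec, ModelConfig

__all__ = [
    "TrialSimSpec",
    "simulate_trial",
    "digitize",
    "synthetic_life_table",
    "builtin_configs",
]


@dataclass(frozen=True)
class TrialSimSpec:
    """True survival laws and design of a simulated two-endpoint arm."""

    model: ParametricSurvival
    n: int
    censor_time_months: float
    seed: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two subjects")
        if self.censor_time_months <= 0:
            raise ValueError("censoring time must be positive")


def simulate_trial(spec: TrialSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw right-censored event times by inverse-CDF sampling.

    Returns (times, events); administrative censoring at
    ``censor_time_months``.  Reproducible given the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n)
    t = np.asarray(inverse_survival(spec.model, u), dtype=float)
    events = (t <= spec.censor_time_months).astype(int)
    times = np.minimum(t, spec.censor_time_months)
    return times, events


def digitize(
    times: np.ndarray,
    events: np.ndarray,
    grid,
    risk_times,
    jitter: float = 0.0,
    seed: int = 0,
    total_events: bool = True,
) -> DigitizedKM:
    """Emulate figure digitization: KM curve sampled at grid points plus a
    number-at-risk table.

    Optional uniform jitter (<= ``jitter``) mimics digitization error; the
    first grid point must be 0 so the curve starts at (0, 1).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("digitization grid must be non-empty")
    from .km_reconstruct import ReconstructedIPD, km_curve

    ipd = ReconstructedIPD(
        times=np.asarray(times, float), events=np.asarray(events, int)
    )
    S = km_curve(ipd)
    surv = np.asarray(S(grid), dtype=float)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        surv = surv + rng.uniform(-jitter, jitter, size=surv.size)
        surv = np.clip(surv, 0.0, 1.0)
        surv = np.minimum.accumulate(surv)
    surv[grid == 0.0] = 1.0
    risk = [
        (float(rt), int(np.sum(np.asarray(times) >= rt - 1e-12))) for rt in risk_times
    ]
    return DigitizedKM(
        points=list(zip(grid.tolist(), surv.tolist())),
        risk_table=risk,
        total_events=int(np.sum(events)) if total_events else None,
    )


def synthetic_life_table(
    q0: float, growth: float, max_age: int = 100, start_age: int = 56
) -> LifeTable:
    """Gompertz-like annual mortality: q(age) = min(1, q0 * g^(age - start)).

    A demographically plausible stand-in for a national female life table;
    extended backwards to age 0 at the starting value.
    """
    if not 0.0 < q0 < 1.0:
        raise ValueError("q0 must lie in (0, 1)")
    if growth < 1.0:
        raise ValueError("annual growth factor must be >= 1")
    ages = np.arange(0, max_age + 1)
    q = np.minimum(1.0, q0 * growth ** np.maximum(0, ages - start_age).astype(float))
    return LifeTable(ages=ages, q_annual=q)


# --- published base-case inputs -------------------------------------------

_AE_NAMES = (
    "neutropenia",
    "anemia",
    "leukopenia",
    "thrombocytopenia",
    "diarrhea",
    "nausea_vomiting",
    "febrile_neutropenia",
)

# probability of grade >= 3 AEs per arm: (base, low, high)
_AE_PROBS_SG = {
    "neutropenia": (0.512, 0.451, 0.573),
    "anemia": (0.078, 0.045, 0.110),
    "leukopenia": (0.101, 0.064, 0.138),
    "thrombocytopenia": (0.016, 0.0, 0.031),
    "diarrhea": (0.105, 0.067, 0.142),
    "nausea_vomiting": (0.039, 0.015, 0.062),
    "febrile_neutropenia": (0.058, 0.03, 0.087),
}
_AE_PROBS_CHEMO = {
    "neutropenia": (0.33, 0.269, 0.392),
    "anemia": (0.049, 0.021, 0.077),
    "leukopenia": (0.054, 0.024, 0.083),
    "thrombocytopenia": (0.013, 0.0, 0.028),
    "diarrhea": (0.004, 0.0, 0.013),
    "nausea_vomiting": (0.004, 0.0, 0.013),
    "febrile_neutropenia": (0.022, 0.003, 0.042),
}

# perspective-specific inputs: unit costs per mg where applicable
_PERSPECTIVES = {
    "china": {
        "econ": dict(
            perspective="china",
            discount_rate=0.05,
            wtp_low=72447.0,
            wtp_high=217341.0,
            currency="CNY",
        ),
        "population": dict(weight_kg=57.3, bsa_m2=1.57),
        "pop_ranges": {"weight_kg": (43.0, 71.6), "bsa_m2": (1.18, 1.96)},
        "prices": {  # per mg: (base, low, high)
            "sacituzumab": (192.5, 114.4, 240.6),
            "eribulin": (5277.0, 3958.0, 6596.0),
            "vinorelbine": (1.35, 1.01, 1.69),
            "capecitabine": (0.0056, 0.0042, 0.0070),
            "gemcitabine": (0.1585, 0.118, 0.198),
        },
        "costs": {
            "administration_per_month": (148.0, 111.0, 185.0),
            "followup_per_visit": (1041.0, 781.0, 1302.0),
            "bsc_per_cycle": (10325.0, 7465.0, 14755.0),
            "eol_per_death": (15879.0, 6166.0, 42411.0),
        },
        "ae_cost": {
            "neutropenia": (2877.0, 2158.0, 3597.0),
            "anemia": (6298.0, 4723.0, 7872.0),
            "leukopenia": (2877.0, 2158.0, 3597.0),
            "thrombocytopenia": (1069.0, 802.0, 1336.0),
            "diarrhea": (4152.0, 3114.0, 5190.0),
            "nausea_vomiting": (323.0, 208.0, 398.0),
            "febrile_neutropenia": (4283.0, 3213.0, 5354.0),
        },
        "life_table": dict(q0_at_start_age=0.005, annual_growth=1.09, max_age=100),
    },
    "us": {
        "econ": dict(
            perspective="us",
            discount_rate=0.03,
            wtp_low=100000.0,
            wtp_high=150000.0,
            currency="USD",
        ),
        "population": dict(weight_kg=77.5, bsa_m2=1.86),
        "pop_ranges": {"weight_kg": (58.1, 96.9), "bsa_m2": (1.40, 2.33)},
        "prices": {
            "sacituzumab": (11.2, 8.4, 14.0),
            "eribulin": (1177.0, 883.0, 1471.0),
            "vinorelbine": (0.95, 0.71, 1.19),
            "capecitabine": (0.0048, 0.0036, 0.0060),
            "gemcitabine": (0.0198, 0.0149, 0.0248),
        },
        "costs": {
            "administration_per_month": (683.0, 512.0, 853.0),
            "followup_per_visit": (1319.0, 989.0, 1648.0),
            "bsc_per_cycle": (4797.0, 3598.0, 5996.0),
            "eol_per_death": (9584.0, 7188.0, 11980.0),
        },
        "ae_cost": {
            "neutropenia": (9497.0, 7123.0, 11871.0),
            "anemia": (13110.0, 9832.0, 16387.0),
            "leukopenia": (9497.0, 7123.0, 11871.0),
            "thrombocytopenia": (11546.0, 8660.0, 14433.0),
            "diarrhea": (3866.0, 2899.0, 4832.0),
            "nausea_vomiting": (3876.0, 2907.0, 4346.0),
            "febrile_neutropenia": (22814.0, 17110.0, 28517.0),
        },
        "life_table": dict(q0_at_start_age=0.006, annual_growth=1.09, max_age=100),
    },
}

_UTILITY_RANGES = {
    "u_pfd": (0.85, 0.64, 1.0),
    "u_pd": (0.52, 0.39, 0.65),
    "ae_disutility": (0.28, 0.21, 0.35),
}

# fitted survival laws (months): family, shape, scale
_SURVIVAL = {
    "sg": {
        "os": ParametricSurvival("weibull", {"shape": 1.447, "scale": 17.034}),
        "pfs": ParametricSurvival("loglogistic", {"shape": 1.741, "scale": 5.133}),
    },
    "chemo": {
        "os": ParametricSurvival("loglogistic", {"shape": 1.783, "scale": 6.675}),
        "pfs": ParametricSurvival("loglogistic", {"shape": 2.499, "scale": 2.076}),
    },
}


def _regimens(prices: dict) -> dict:
    """SG monotherapy and the physician's-choice chemotherapy mixture.

    Capecitabine and gemcitabine are dosed at the midpoints of their
    published per-m2 ranges (1000-1250 twice daily x 14/21 d; 800-1200 on
    days 1, 8, 15 of 28 d).
    """
    sg = Regimen(
        name="sg",
        components=(
            DrugComponent(
                name="sacituzumab",
                unit_price_per_mg=prices["sacituzumab"][0],
                dose_rule="per_kg",
                dose_value=10.0,
                administrations_per_cycle=2,
                native_cycle_days=21.0,
            ),
        ),
    )
    chemo = Regimen(
        name="chemo",
        components=(
            DrugComponent(
                name="eribulin",
                unit_price_per_mg=prices["eribulin"][0],
                dose_rule="per_m2",
                dose_value=1.4,
                administrations_per_cycle=2,
                native_cycle_days=21.0,
                proportion=0.54,
            ),
            DrugComponent(
                name="vinorelbine",
                unit_price_per_mg=prices["vinorelbine"][0],
                dose_rule="per_m2",
                dose_value=25.0,
                administrations_per_cycle=1,
                native_cycle_days=7.0,
                proportion=0.20,
            ),
            DrugComponent(
                name="capecitabine",
                unit_price_per_mg=prices["capecitabine"][0],
                dose_rule="per_m2",
                dose_value=1125.0,
                administrations_per_cycle=28,
                native_cycle_days=21.0,
                proportion=0.13,
                oral=True,
            ),
            DrugComponent(
                name="gemcitabine",
                unit_price_per_mg=prices["gemcitabine"][0],
                dose_rule="per_m2",
                dose_value=1000.0,
                administrations_per_cycle=3,
                native_cycle_days=28.0,
                proportion=0.12,
            ),
        ),
    )
    return {"sg": sg, "chemo": chemo}


def _param_specs(p: dict) -> list[ParamSpec]:
    specs: list[ParamSpec] = []
    for drug, (base, low, high) in p["prices"].items():
        arm = "sg" if drug == "sacituzumab" else "chemo"
        specs.append(
            ParamSpec(
                f"arms.{arm}.regimen.{drug}.unit_price_per_mg", base, low, high, "gamma"
            )
        )
    for key, (base, low, high) in p["costs"].items():
        specs.append(ParamSpec(f"costs.{key}", base, low, high, "gamma"))
    for ae, (base, low, high) in p["ae_cost"].items():
        specs.append(ParamSpec(f"costs.ae_cost.{ae}", base, low, high, "gamma"))
    for arm, probs in (("sg", _AE_PROBS_SG), ("chemo", _AE_PROBS_CHEMO)):
        for ae, (base, low, high) in probs.items():
            specs.append(ParamSpec(f"arms.{arm}.ae_probs.{ae}", base, low, high, "beta"))
    for key, (low, high) in p["pop_ranges"].items():
        base = p["population"][key]
        specs.append(ParamSpec(f"population.{key}", base, low, high, "normal"))
    for key, (base, low, high) in _UTILITY_RANGES.items():
        specs.append(ParamSpec(f"utilities.{key}", base, low, high, "beta"))
    return specs


def builtin_config(perspective: str) -> ModelConfig:
    """Fully populated base-case configuration for one perspective."""
    if perspective not in _PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    p = _PERSPECTIVES[perspective]
    regimens = _regimens(p["prices"])
    arms = {
        arm: ArmSpec(
            os_model=_SURVIVAL[arm]["os"],
            pfs_model=_SURVIVAL[arm]["pfs"],
            regimen=regimens[arm],
            ae_probs={k: v[0] for k, v in probs.items()},
        )
        for arm, probs in (("sg", _AE_PROBS_SG), ("chemo", _AE_PROBS_CHEMO))
    }
    cfg = ModelConfig(
        name=perspective,
        reference="sg",
        comparator="chemo",
        arms=arms,
        costs=CostInputs(
            administration_per_month=p["costs"]["administration_per_month"][0],
            followup_per_visit=p["costs"]["followup_per_visit"][0],
            ae_cost={k: v[0] for k, v in p["ae_cost"].items()},
            bsc_per_cycle=p["costs"]["bsc_per_cycle"][0],
            eol_per_death=p["costs"]["eol_per_death"][0],
        ),
        utilities=UtilitySet(),
        population=Population(**p["population"]),
        econ=EconSettings(**p["econ"]),
        engine=EngineSettings(),
        life_table=LifeTableSpec(**p["life_table"]),
        param_specs=_param_specs(p),
    )
    cfg.validate()
    return cfg


def builtin_configs() -> tuple[ModelConfig, ModelConfig]:
    """The (china, us) base-case configuration pair."""
    return builtin_config("china"), builtin_config("us")
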