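"""Model configuration, validation, file I/O and the end-to-end pipeline.

A :class:`ModelConfig` carries everything one perspective needs: fitted
OS/PFS laws per arm, regimens, unit costs, utilities, population
anthropometrics, discounting/WTP settings, engine discretization, a
life-table specification and the sensitivity-analysis parameter list.
Configs round-trip through plain dicts (YAML on disk); every schema
violation is reported with its path.

``run_pipeline`` composes the stages: survival laws -> cohort trace
(partitioned-survival or Markov engine) -> discounted accrual -> ICER.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cohort_engine import (
    CohortTrace,
    EngineSettings,
    LifeTable,
    derive_transitions,
    run_markov,
    run_partitioned,
)
from .economics import (
    CEResult,
    CostInputs,
    DrugComponent,
    EconSettings,
    Population,
    Regimen,
    StrategyResult,
    UtilitySet,
    accrue,
    icer,
)
from .survival_models import ParametricSurvival
from .uncertainty import ParamSpec

__all__ = [
    "ArmSpec",
    "LifeTableSpec",
    "ModelConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "run_pipeline",
    "PipelineResult",
]


class ConfigError(ValueError):
    """Configuration invalid; message lists every violation with its path."""


@dataclass(frozen=True)
class LifeTableSpec:
    """Synthetic life-table generator inputs (see synthetic_data)."""

    q0_at_start_age: float
    annual_growth: float
    max_age: int = 100


@dataclass(frozen=True)
class ArmSpec:
    """One treatment strategy: survival laws, regimen, AE profile."""

    os_model: ParametricSurvival
    pfs_model: ParametricSurvival
    regimen: Regimen
    ae_probs: dict


@dataclass
class ModelConfig:
    name: str
    reference: str
    comparator: str
    arms: dict  # arm name -> ArmSpec
    costs: CostInputs
    utilities: UtilitySet
    population: Population
    econ: EconSettings
    engine: EngineSettings
    life_table: LifeTableSpec
    param_specs: list = field(default_factory=list)

    # ---- dict / YAML round trip ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "reference": self.reference,
            "comparator": self.comparator,
            "arms": {
                arm: {
                    "os_model": {
                        "family": spec.os_model.family,
                        "params": dict(spec.os_model.params),
                    },
                    "pfs_model": {
                        "family": spec.pfs_model.family,
                        "params": dict(spec.pfs_model.params),
                    },
                    "ae_probs": dict(spec.ae_probs),
                    "regimen": {
                        "name": spec.regimen.name,
                        "components": [asdict(c) for c in spec.regimen.components],
                    },
                }
                for arm, spec in self.arms.items()
            },
            "costs": {
                "administration_per_month": self.costs.administration_per_month,
                "followup_per_visit": self.costs.followup_per_visit,
                "ae_cost": dict(self.costs.ae_cost),
                "bsc_per_cycle": self.costs.bsc_per_cycle,
                "eol_per_death": self.costs.eol_per_death,
            },
            "utilities": asdict(self.utilities),
            "population": asdict(self.population),
            "econ": asdict(self.econ),
            "engine": asdict(self.engine),
            "life_table": asdict(self.life_table),
            "param_specs": [asdict(p) for p in self.param_specs],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        errors: list[str] = []

        def need(d: dict, key: str, path: str):
            if not isinstance(d, dict) or key not in d:
                errors.append(f"missing required field {path}")
                return None
            return d[key]

        for top in ("name", "reference", "comparator", "arms", "costs",
                    "utilities", "population", "econ", "engine", "life_table"):
            need(data, top, top)
        if errors:
            raise ConfigError("; ".join(errors))

        def build(factory, kwargs: dict, path: str):
            try:
                return factory(**kwargs)
            except (TypeError, ValueError) as exc:
                errors.append(f"{path}: {exc}")
                return None

        econ = build(EconSettings, data["econ"], "econ")
        if isinstance(data["econ"], dict) and "discount_rate" not in data["econ"]:
            errors.append("missing required field econ.discount_rate")
        engine = build(EngineSettings, data["engine"], "engine")
        utilities = build(UtilitySet, data["utilities"], "utilities")
        population = build(Population, data["population"], "population")
        costs = build(CostInputs, data["costs"], "costs")
        life_table = build(LifeTableSpec, data["life_table"], "life_table")

        arms = {}
        for arm_name, arm_d in (data.get("arms") or {}).items():
            path = f"arms.{arm_name}"
            try:
                os_m = ParametricSurvival(
                    arm_d["os_model"]["family"], dict(arm_d["os_model"]["params"])
                )
                pfs_m = ParametricSurvival(
                    arm_d["pfs_model"]["family"], dict(arm_d["pfs_model"]["params"])
                )
                comps = tuple(
                    DrugComponent(**c) for c in arm_d["regimen"]["components"]
                )
                reg = Regimen(name=arm_d["regimen"]["name"], components=comps)
                arms[arm_name] = ArmSpec(
                    os_model=os_m, pfs_model=pfs_m, regimen=reg,
                    ae_probs=dict(arm_d["ae_probs"]),
                )
            except (KeyError, TypeError, ValueError) as exc:
                errors.append(f"{path}: {exc}")

        param_specs = []
        for i, p in enumerate(data.get("param_specs", []) or []):
            try:
                param_specs.append(ParamSpec(**p))
            except (TypeError, ValueError) as exc:
                errors.append(f"param_specs[{i}]: {exc}")

        if errors:
            raise ConfigError("; ".join(errors))
        cfg = cls(
            name=data["name"],
            reference=data["reference"],
            comparator=data["comparator"],
            arms=arms,
            costs=costs,
            utilities=utilities,
            population=population,
            econ=econ,
            engine=engine,
            life_table=life_table,
            param_specs=param_specs,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        errors = []
        for role in ("reference", "comparator"):
            arm = getattr(self, role)
            if arm not in self.arms:
                errors.append(f"{role} arm {arm!r} not among arms {sorted(self.arms)}")
        for arm_name, spec in self.arms.items():
            for ae in spec.ae_probs:
                if ae not in self.costs.ae_cost:
                    errors.append(
                        f"arms.{arm_name}.ae_probs.{ae}: no matching entry in costs.ae_cost"
                    )
        if errors:
            raise ConfigError("; ".join(errors))


def load_config(path) -> ModelConfig:
    """Load and schema-validate a YAML config."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: not a mapping")
    return ModelConfig.from_dict(data)


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# --- pipeline --------------------------------------------------------------


@dataclass
class PipelineResult:
    """Full output of one deterministic run: comparison plus traces."""

    ce: CEResult
    traces: dict  # arm name -> CohortTrace
    engine: str
    transitions: dict | None = None  # arm -> TransitionSeries (markov only)

    def summary(self) -> str:
        lines = [f"engine: {self.engine}"]
        for s in (self.ce.reference, self.ce.comparator):
            lines.append(
                f"  {s.name}: LY={s.life_years:.3f} QALY={s.qalys:.3f} "
                f"drug={s.cost_drug:,.0f} total={s.cost_total:,.0f}"
            )
        inc = self.ce
        icer_txt = f"{inc.icer:,.0f}/QALY" if inc.icer is not None else inc.dominance
        lines.append(
            f"  incremental: dCost={inc.delta_cost:,.0f} dQALY={inc.delta_qalys:.4f} "
            f"ICER={icer_txt}"
        )
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {"engine": self.engine, **self.ce.to_dict()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _trace_for_arm(config: ModelConfig, arm: str, engine: str):
    spec = config.arms[arm]
    if engine == "ps":
        return run_partitioned(spec.os_model, spec.pfs_model, config.engine), None
    if engine == "markov":
        from .synthetic_data import synthetic_life_table

        lt = synthetic_life_table(
            q0=config.life_table.q0_at_start_age,
            growth=config.life_table.annual_growth,
            max_age=config.life_table.max_age,
            start_age=int(config.engine.start_age),
        )
        trans = derive_transitions(spec.os_model, spec.pfs_model, lt, config.engine)
        return run_markov(trans, config.engine), trans
    raise ValueError(f"unknown engine {engine!r} (expected 'ps' or 'markov')")


def run_pipeline(config: ModelConfig, engine: str = "ps") -> PipelineResult:
    """Deterministic base-case run of both arms under one engine."""
    traces, transitions, results = {}, {}, {}
    for arm in (config.reference, config.comparator):
        trace, trans = _trace_for_arm(config, arm, engine)
        traces[arm] = trace
        if trans is not None:
            transitions[arm] = trans
        spec = config.arms[arm]
        results[arm] = accrue(
            trace,
            spec.regimen,
            config.population,
            config.costs,
            config.utilities,
            spec.ae_probs,
            config.econ,
            config.engine,
        )
    ce = icer(results[config.reference], results[config.comparator])
    return PipelineResult(
        ce=ce,
        traces=traces,
        engine=engine,
        transitions=transitions or None,
    )
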