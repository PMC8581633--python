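"""Sensitivity machinery: one-way (tornado), probabilistic (PSA), CEAC,
value-based threshold pricing and subgroup hazard-ratio analysis.

Parameters are addressed by dotted paths into the config's dict form
(e.g. ``utilities.u_pfd`` or ``arms.sg.regimen.sacituzumab.unit_price_per_mg``;
regimen components are addressed by drug name).  PSA distributions are
derived from (mean, low, high) by treating the printed range as a 95%
interval — SE = (high - low)/3.92 — with gamma and beta parameters by the
method of moments.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParamSpec",
    "PSADraws",
    "SubgroupSpec",
    "ProportionalHazards",
    "dist_from_mean_range",
    "owsa",
    "run_psa",
    "ceac",
    "threshold_price",
    "subgroup_icer",
]

_DIST_KINDS = ("gamma", "beta", "normal", "fixed")


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain input: config path, base value, range, distribution."""

    name: str
    base: float
    low: float
    high: float
    dist: str = "fixed"

    def __post_init__(self) -> None:
        if self.dist not in _DIST_KINDS:
            raise ValueError(f"unknown distribution kind {self.dist!r}")
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.name}: require low <= base <= high, got "
                f"{self.low}, {self.base}, {self.high}"
            )


@dataclass
class PSADraws:
    """Paired incremental draws from Monte-Carlo parameter sampling."""

    delta_cost: np.ndarray
    delta_qalys: np.ndarray
    seed: int
    sampled: dict  # param name -> sampled values array

    @property
    def n(self) -> int:
        return int(self.delta_cost.size)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iter": np.arange(self.n),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qalys,
            }
        )


@dataclass(frozen=True)
class SubgroupSpec:
    """A trial subgroup summarized by its OS and PFS hazard ratios."""

    name: str
    hr_os: float
    hr_pfs: float

    def __post_init__(self) -> None:
        if self.hr_os <= 0 or self.hr_pfs <= 0:
            raise ValueError("hazard ratios must be positive")


@dataclass(frozen=True)
class ProportionalHazards:
    """Survival law S_base(t)^HR — subgroup curves from an overall baseline."""

    baseline: object
    hazard_ratio: float

    def __post_init__(self) -> None:
        if self.hazard_ratio <= 0:
            raise ValueError("hazard ratio must be positive")

    def survival(self, t):
        return np.asarray(self.baseline.survival(t), dtype=float) ** self.hazard_ratio


# --- config-path plumbing --------------------------------------------------


def _resolve(node, segments, path):
    """Walk a config dict along ``segments``; return (parent, final_key)."""
    def _child(node, seg):
        if isinstance(node, dict):
            if seg in node:
                return node[seg]
            # regimens: address components by drug name
            if isinstance(node.get("components"), list):
                node = node["components"]
        if isinstance(node, list):
            for item in node:
                if isinstance(item, dict) and item.get("name") == seg:
                    return item
        return None

    for seg in segments[:-1]:
        nxt = _child(node, seg)
        if nxt is None:
            raise ValueError(f"unmapped parameter path {path!r} (at {seg!r})")
        node = nxt
    last = segments[-1]
    if isinstance(node, list):
        for item in node:
            if isinstance(item, dict) and item.get("name") == last:
                return node, item
        raise ValueError(f"unmapped parameter path {path!r} (at {last!r})")
    if not isinstance(node, dict) or last not in node:
        raise ValueError(f"unmapped parameter path {path!r} (at {last!r})")
    return node, last


def set_param(config_dict: dict, path: str, value: float) -> None:
    parent, key = _resolve(config_dict, path.split("."), path)
    parent[key] = float(value)


def get_param(config_dict: dict, path: str) -> float:
    parent, key = _resolve(config_dict, path.split("."), path)
    return float(parent[key])


def _rebuild(base_dict: dict, values: dict):
    from .workbench import ModelConfig

    d = copy.deepcopy(base_dict)
    for path, value in values.items():
        set_param(d, path, value)
    return ModelConfig.from_dict(d)


# --- distributions ---------------------------------------------------------


def dist_from_mean_range(kind: str, mean: float, low: float, high: float) -> dict:
    """Distribution parameters from a printed mean and 95% range.

    SE = (high - low) / (2 x 1.96); gamma and beta by the method of moments,
    normal returns (mean, SE).  Deterministic.
    """
    if kind not in _DIST_KINDS:
        raise ValueError(f"unknown distribution kind {kind!r}")
    se = (high - low) / (2.0 * 1.96)
    if kind == "fixed" or se == 0.0:
        return {"kind": "fixed", "value": mean}
    if kind == "gamma":
        if mean <= 0:
            raise ValueError("gamma requires a positive mean")
        shape = (mean / se) ** 2
        scale = se**2 / mean
        return {"kind": "gamma", "shape": shape, "scale": scale}
    if kind == "beta":
        if not 0.0 < mean < 1.0:
            raise ValueError("beta requires mean in (0, 1)")
        var = se**2
        nu = mean * (1.0 - mean) / var - 1.0
        if nu <= 0:
            raise ValueError("beta moment solution outside valid domain")
        return {"kind": "beta", "alpha": mean * nu, "beta": (1.0 - mean) * nu}
    return {"kind": "normal", "mean": mean, "se": se}


def _sample(spec: ParamSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    dist = dist_from_mean_range(spec.dist, spec.base, spec.low, spec.high)
    if dist["kind"] == "fixed":
        return np.full(size, dist.get("value", spec.base))
    if dist["kind"] == "gamma":
        return rng.gamma(dist["shape"], dist["scale"], size)
    if dist["kind"] == "beta":
        return rng.beta(dist["alpha"], dist["beta"], size)
    # normal, truncated to positive support by resampling
    out = rng.normal(dist["mean"], dist["se"], size)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            break
        out[bad] = rng.normal(dist["mean"], dist["se"], int(bad.sum()))
    return out


# --- analyses --------------------------------------------------------------


def _incremental(config, engine="ps"):
    from .workbench import run_pipeline

    res = run_pipeline(config, engine=engine)
    return res.ce.delta_cost, res.ce.delta_qalys, res.ce


@dataclass
class TornadoEntry:
    name: str
    icer_low: float
    icer_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def owsa(config, specs=None, engine: str = "ps") -> list:
    """One-way sensitivity: rerun the pipeline at each parameter's bounds.

    Returns tornado entries sorted by ICER span, widest first.
    """
    specs = config.param_specs if specs is None else specs
    base_dict = config.to_dict()
    entries = []
    for spec in specs:
        icers = []
        for value in (spec.low, spec.high):
            cfg = _rebuild(base_dict, {spec.name: value})
            _, _, ce = _incremental(cfg, engine)
            icers.append(ce.icer if ce.icer is not None else np.nan)
        entries.append(TornadoEntry(spec.name, icers[0], icers[1]))
    return sorted(entries, key=lambda e: (-e.span, e.name))


def run_psa(config, n: int, seed: int, engine: str = "ps") -> PSADraws:
    """Probabilistic sensitivity analysis: joint sampling of all ParamSpecs.

    Each iteration rebuilds the config with one sampled value per parameter
    and reruns the deterministic pipeline.  Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    specs = config.param_specs
    sampled = {s.name: _sample(s, rng, n) for s in specs}
    base_dict = config.to_dict()
    d_cost = np.empty(n)
    d_q = np.empty(n)
    for i in range(n):
        cfg = _rebuild(base_dict, {name: vals[i] for name, vals in sampled.items()})
        d_cost[i], d_q[i], _ = _incremental(cfg, engine)
    return PSADraws(delta_cost=d_cost, delta_qalys=d_q, seed=seed, sampled=sampled)


def ceac(draws: PSADraws, wtp_grid) -> list:
    """Cost-effectiveness acceptability: P(NMB > 0) per WTP (strict ties)."""
    if draws.n < 1:
        raise ValueError("ceac requires at least one draw")
    out = []
    for wtp in np.atleast_1d(np.asarray(wtp_grid, dtype=float)):
        nmb = wtp * draws.delta_qalys - draws.delta_cost
        out.append((float(wtp), float(np.mean(nmb > 0))))
    return out


def acceptability(config, wtp: float, n: int, seed: int, engine: str = "ps") -> float:
    """Probability the reference arm is cost-effective at one WTP."""
    draws = run_psa(config, n=n, seed=seed, engine=engine)
    return ceac(draws, [wtp])[0][1]


def threshold_price(
    config,
    wtp: float,
    seed: int,
    target_prob: float = 0.5,
    drug: str | None = None,
    n_iter: int = 1500,
    rel_tol: float = 0.005,
    engine: str = "ps",
) -> float:
    """Unit price at which acceptability reaches ``target_prob`` at ``wtp``.

    Bisection on the reference arm's drug price, evaluating the PSA
    acceptability with the same seed at every candidate price (common
    random numbers), until the bracket narrows below ``rel_tol`` of the
    base price; returns the bracket midpoint.
    """
    ref = config.arms[config.reference]
    if drug is None:
        drug = ref.regimen.components[0].name
    path = f"arms.{config.reference}.regimen.{drug}.unit_price_per_mg"
    base_dict = config.to_dict()
    base_price = get_param(base_dict, path)

    def prob_at(price: float) -> float:
        cfg = _rebuild(base_dict, {path: price})
        # keep the price's own PSA spec pinned to the evaluated price
        cfg = _strip_price_spec(cfg, path, price)
        return acceptability(cfg, wtp, n=n_iter, seed=seed, engine=engine)

    lo, hi = 0.0, base_price
    p_lo, p_hi = prob_at(lo), prob_at(hi)
    if not (p_lo > target_prob >= p_hi):
        raise ValueError(
            "threshold not bracketed: acceptability is assumed monotone in "
            f"price but P(0)={p_lo:.3f}, P(base)={p_hi:.3f}, target={target_prob}"
        )
    while (hi - lo) > rel_tol * base_price:
        mid = 0.5 * (lo + hi)
        if prob_at(mid) > target_prob:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _strip_price_spec(config, path: str, price: float):
    """Replace the sampled spec of the priced drug by a fixed value."""
    import dataclasses

    specs = []
    for s in config.param_specs:
        if s.name == path:
            specs.append(ParamSpec(s.name, price, price, price, "fixed"))
        else:
            specs.append(s)
    return dataclasses.replace(config, param_specs=specs) if dataclasses.is_dataclass(
        config
    ) else config


def subgroup_icer(config, sg: SubgroupSpec, engine: str = "ps"):
    """ICER for a subgroup via proportional hazards on the comparator curves.

    The reference arm's subgroup OS/PFS are S_comparator(t)^HR; the
    comparator arm is unchanged.
    """
    import dataclasses

    comp = config.arms[config.comparator]
    ref = config.arms[config.reference]
    new_ref = dataclasses.replace(
        ref,
        os_model=ProportionalHazards(comp.os_model, sg.hr_os),
        pfs_model=ProportionalHazards(comp.pfs_model, sg.hr_pfs),
    )
    cfg = dataclasses.replace(
        config, arms={**config.arms, config.reference: new_ref}
    )
    _, _, ce = _incremental(cfg, engine)
    return ce
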