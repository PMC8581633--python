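"""Three-state cohort traces from OS/PFS survival laws.

Two engines produce per-cycle occupancy of the progression-free (PFD),
progressed (PD) and dead states:

* the partitioned-survival rule reads occupancy directly off the curves
  (PFD = min(S_pfs, S_os), dead = 1 - S_os, PD = the remainder);
* a time-dependent Markov chain whose transitions are derived from the same
  curves, with background (life-table) mortality as the PFD-to-death floor.

Time is discretized into cycles of ``cycle_days`` (default 28 days, 65
cycles ~ 5 years); curve evaluation uses months of 30.4375 days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EngineSettings",
    "LifeTable",
    "CohortTrace",
    "run_partitioned",
    "background_mortality",
    "derive_transitions",
    "run_markov",
]

DAYS_PER_MONTH = 30.4375  # Julian year / 12
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class EngineSettings:
    """Cycle/horizon discretization and cohort entry age."""

    cycle_days: float = 28.0
    horizon_years: float = 5.0
    n_cycles: int = 65  # 65 x 28 d = 59.8 months; final partial month ignored
    start_age: float = 56.0

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / DAYS_PER_YEAR

    def boundaries_months(self) -> np.ndarray:
        """Cycle boundary times t_0..t_N in months."""
        return np.arange(self.n_cycles + 1) * self.cycle_months

    def __post_init__(self) -> None:
        if self.cycle_days <= 0 or self.n_cycles < 1:
            raise ValueError("cycle length and cycle count must be positive")
        covered = self.n_cycles * self.cycle_days / DAYS_PER_YEAR
        if covered < self.horizon_years - 2 * self.cycle_days / DAYS_PER_YEAR:
            raise ValueError("cycles do not cover the requested horizon")


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities by (integer) attained age."""

    ages: np.ndarray
    q_annual: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q_annual, dtype=float)
        if ages.size != q.size or ages.size == 0:
            raise ValueError("ages and q_annual must be non-empty, equal length")
        if np.any(np.diff(ages) != 1):
            raise ValueError("ages must be contiguous")
        if np.any((q < 0) | (q > 1)):
            raise ValueError("annual death probabilities must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q_annual", q)

    def q_at(self, age: float) -> float:
        """Annual q at integer attained age; clamped to the last row."""
        idx = int(np.floor(age)) - int(self.ages[0])
        idx = min(max(idx, 0), len(self.ages) - 1)
        return float(self.q_annual[idx])

    @classmethod
    def zero(cls, start: int = 0, stop: int = 120) -> "LifeTable":
        ages = np.arange(start, stop + 1)
        return cls(ages=ages, q_annual=np.zeros_like(ages, dtype=float))

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(ages=df["age"].values, q_annual=df["annual_death_prob"].values)

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "annual_death_prob": self.q_annual}).to_csv(
            path, index=False
        )


@dataclass
class CohortTrace:
    """State occupancy at each cycle boundary (arrays of length n_cycles+1)."""

    t_months: np.ndarray
    pfd: np.ndarray
    pd_: np.ndarray
    dead: np.ndarray

    def __post_init__(self) -> None:
        total = self.pfd + self.pd_ + self.dead
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("state occupancy must sum to 1 at every cycle")
        for arr in (self.pfd, self.pd_, self.dead):
            if np.any((arr < -1e-12) | (arr > 1 + 1e-12)):
                raise ValueError("occupancy outside [0, 1]")
        if np.any(np.diff(self.dead) < -1e-12):
            raise ValueError("dead occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return len(self.t_months) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.t_months)),
                "t_start_months": self.t_months,
                "pfd": self.pfd,
                "pd": self.pd_,
                "dead": self.dead,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_partitioned(os_model, pfs_model, settings: EngineSettings) -> CohortTrace:
    """Partitioned-survival occupancy at each cycle boundary.

    PFD = min(S_pfs, S_os) (independently fitted curves may cross), dead =
    1 - S_os, PD = S_os - S_pfs clipped at zero.
    """
    t = settings.boundaries_months()
    s_os = np.asarray(os_model.survival(t), dtype=float)
    s_pfs = np.asarray(pfs_model.survival(t), dtype=float)
    pfd = np.minimum(s_pfs, s_os)
    dead = 1.0 - s_os
    pd_ = np.maximum(0.0, s_os - s_pfs)
    return CohortTrace(t_months=t, pfd=pfd, pd_=pd_, dead=dead)


def background_mortality(
    lt: LifeTable, age0: float, cycle: int, settings: EngineSettings
) -> float:
    """Per-cycle probability of background death during ``cycle``.

    The annual probability is looked up at the integer age attained at the
    cycle's start (ages beyond the table clamp to its last row) and converted
    with 1 - (1 - q)^(cycle_years).
    """
    age = age0 + cycle * settings.cycle_years
    q = lt.q_at(age)
    return 1.0 - (1.0 - q) ** settings.cycle_years


@dataclass
class TransitionSeries:
    """Per-cycle transition probabilities of the three-state chain."""

    p_pfd_pd: np.ndarray
    p_pfd_dead: np.ndarray
    p_pd_dead: np.ndarray
    n_clipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(len(self.p_pfd_pd)),
                "p_pfd_pd": self.p_pfd_pd,
                "p_pfd_dead": self.p_pfd_dead,
                "p_pd_dead": self.p_pd_dead,
            }
        )


def derive_transitions(
    os_model, pfs_model, lt: LifeTable, settings: EngineSettings
) -> TransitionSeries:
    """Time-dependent transition probabilities from fitted OS/PFS curves.

    Per cycle: p(leave PFD) = 1 - S_pfs(t+d)/S_pfs(t); the PFD-to-death leg
    is background mortality, raised when the OS decrement cannot be absorbed
    by the (possibly empty) PD pool — without that floor the chain loses the
    early OS deaths, since in the first cycles everyone is progression-free;
    p(PD-to-death) matches the remaining OS decrement, clipped to [0, 1]
    (clipping is counted and logged).  Occupancy used in the PD denominator
    is propagated forward alongside the derivation.
    """
    t = settings.boundaries_months()
    s_os = np.asarray(os_model.survival(t), dtype=float)
    s_pfs = np.asarray(pfs_model.survival(t), dtype=float)
    # transitions reproduce the clipped partitioned-survival occupancy, so
    # crossing fitted curves (PFS above OS in the tail) stay consistent
    pfd_t = np.minimum(s_pfs, s_os)
    pd_t = np.maximum(0.0, s_os - s_pfs)
    n = settings.n_cycles
    p_fd_pd = np.zeros(n)
    p_fd_d = np.zeros(n)
    p_pd_d = np.zeros(n)
    n_clipped = 0
    for k in range(n):
        pfd, pd_ = pfd_t[k], pd_t[k]
        if pfd <= 0:
            leave = 0.0
        else:
            leave = 1.0 - pfd_t[k + 1] / pfd
        leave = min(max(leave, 0.0), 1.0)
        q_bg = background_mortality(lt, settings.start_age, k, settings)
        os_deaths = max(0.0, s_os[k] - s_os[k + 1])
        bg_floor = min(q_bg, leave)
        # deaths the PD pool cannot absorb (even dying entirely) fall on PFD
        residual = os_deaths - pd_ - bg_floor * pfd
        if residual > 1e-15 and pfd > 0:
            pfd_d = min(leave, bg_floor + residual / pfd)
        else:
            pfd_d = bg_floor
        fd_pd = max(0.0, leave - pfd_d)
        if pd_ > 1e-12:
            pdd = (os_deaths - pfd * pfd_d) / pd_
            if pdd > 1.0:
                n_clipped += 1
            pdd = min(max(pdd, 0.0), 1.0)
        else:
            pdd = 0.0
        p_fd_pd[k], p_fd_d[k], p_pd_d[k] = fd_pd, pfd_d, pdd
    if n_clipped:
        logger.warning("derive_transitions: clipped p(PD->death) in %d cycles", n_clipped)
    return TransitionSeries(
        p_pfd_pd=p_fd_pd, p_pfd_dead=p_fd_d, p_pd_dead=p_pd_d, n_clipped=n_clipped
    )


def run_markov(transitions: TransitionSeries, settings: EngineSettings) -> CohortTrace:
    """Forward-propagate the cohort from (1, 0, 0); death is absorbing."""
    n = settings.n_cycles
    for name in ("p_pfd_pd", "p_pfd_dead", "p_pd_dead"):
        arr = getattr(transitions, name)
        if len(arr) != n:
            raise ValueError(f"{name} must have one entry per cycle")
        bad = np.where((arr < -1e-12) | (arr > 1 + 1e-12))[0]
        if bad.size:
            raise ValueError(f"invalid probability in {name} at cycle {bad[0]}")
    stay = 1.0 - transitions.p_pfd_pd - transitions.p_pfd_dead
    bad = np.where(stay < -1e-12)[0]
    if bad.size:
        raise ValueError(f"PFD exit probabilities exceed 1 at cycle {bad[0]}")
    pfd = np.zeros(n + 1)
    pd_ = np.zeros(n + 1)
    dead = np.zeros(n + 1)
    pfd[0] = 1.0
    for k in range(n):
        pfd[k + 1] = pfd[k] * stay[k]
        pd_[k + 1] = pd_[k] * (1.0 - transitions.p_pd_dead[k]) + pfd[k] * transitions.p_pfd_pd[k]
        dead[k + 1] = dead[k] + pfd[k] * transitions.p_pfd_dead[k] + pd_[k] * transitions.p_pd_dead[k]
    # renormalize away accumulated floating error only
    total = pfd + pd_ + dead
    np.divide(pfd, total, out=pfd)
    np.divide(pd_, total, out=pd_)
    np.divide(dead, total, out=dead)
    return CohortTrace(
        t_months=settings.boundaries_months(), pfd=pfd, pd_=pd_, dead=dead
    )
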