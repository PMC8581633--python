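"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Published KM figures plus their number-at-risk tables carry enough
information to approximately recover the underlying event and censoring
times.  ``reconstruct_ipd`` implements the standard interval-wise algorithm:
within each interval between consecutive risk-table times, censoring is
assumed uniform and its amount is solved iteratively so that the implied
number at risk matches the published one, while events at each digitized
click are chosen to match the digitized survival drops.  ``km_curve``
re-estimates the product-limit curve from the reconstruction for round-trip
validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

__all__ = ["DigitizedKM", "ReconstructedIPD", "reconstruct_ipd", "km_curve"]


@dataclass
class DigitizedKM:
    """Digitized curve coordinates plus the published number-at-risk table.

    ``points``: (time_months, survival) pairs, first point (0, 1), survival
    non-increasing.  ``risk_table``: (time_months, n_at_risk) pairs with
    non-increasing counts.  ``total_events``: optional published event count
    used to pin down the final interval.
    """

    points: list[tuple[float, float]]
    risk_table: list[tuple[float, int]]
    total_events: int | None = None

    def __post_init__(self) -> None:
        if not self.points or not self.risk_table:
            raise ValueError("points and risk_table must be non-empty")
        t = np.array([p[0] for p in self.points], dtype=float)
        s = np.array([p[1] for p in self.points], dtype=float)
        if t[0] != 0 or abs(s[0] - 1.0) > 1e-9:
            raise ValueError("first digitized point must be (0, 1)")
        if np.any(np.diff(t) < 0):
            raise ValueError("digitized times must be non-decreasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("digitized survival must be non-increasing")
        if np.any((s < 0) | (s > 1)):
            raise ValueError("survival values must lie in [0, 1]")
        rt = np.array([r[0] for r in self.risk_table], dtype=float)
        rn = np.array([r[1] for r in self.risk_table], dtype=float)
        if np.any(np.diff(rt) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(np.diff(rn) > 0):
            raise ValueError("numbers at risk must be non-increasing")
        if np.any(rn < 0):
            raise ValueError("numbers at risk must be non-negative")

    @classmethod
    def from_csv(cls, points_path, risk_path, total_events=None) -> "DigitizedKM":
        pts = pd.read_csv(points_path)
        rt = pd.read_csv(risk_path)
        return cls(
            points=list(zip(pts["time_months"], pts["survival"])),
            risk_table=list(zip(rt["time_months"], rt["n_at_risk"].astype(int))),
            total_events=total_events,
        )


@dataclass
class ReconstructedIPD:
    """Reconstructed (time, event) records; event=1 observed, 0 censored."""

    times: np.ndarray
    events: np.ndarray

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.times, "event": self.events.astype(int)})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def reconstruct_ipd(dkm: DigitizedKM) -> ReconstructedIPD:
    """Solve for event/censoring times consistent with curve and risk table."""
    t = np.array([p[0] for p in dkm.points], dtype=float)
    s = np.array([p[1] for p in dkm.points], dtype=float)
    trisk = np.array([r[0] for r in dkm.risk_table], dtype=float)
    nrisk = np.array([r[1] for r in dkm.risk_table], dtype=int)
    n_int = len(trisk)
    t_end = t[-1]

    # click index ranges [lower, upper] per risk interval; a click exactly at
    # the next risk time belongs to the earlier interval (closed on the right),
    # so drops at risk-table times precede the published at-risk count
    upper = np.empty(n_int, dtype=int)
    upper[:-1] = np.searchsorted(t, trisk[1:], side="right") - 1
    upper[-1] = len(t) - 1
    lower = np.empty(n_int, dtype=int)
    lower[0] = 0
    lower[1:] = upper[:-1] + 1

    n_clicks = len(t)
    d = np.zeros(n_clicks, dtype=int)  # events at click k
    c = np.zeros(n_clicks, dtype=int)  # censors in (t[k], t[k+1])
    cens_times_extra: list[np.ndarray] = []
    n_hat = float(nrisk[0])
    km_prev = 1.0  # KM estimate at the previous click
    s_prev = 1.0  # digitized survival at previous click

    for i in range(n_int):
        lo, up = lower[i], upper[i]
        if lo > up:
            continue
        target_next = nrisk[i + 1] if i + 1 < n_int else None
        # initial guess for censors in the interval
        if target_next is None:
            ncen_guess = 0
        else:
            # survival-scaled first guess, refined by the loop below
            ncen_guess = 0
        state = None
        for _ in range(60):
            nk = n_hat
            kmp = km_prev
            sp = s_prev
            dints = np.zeros(up - lo + 1, dtype=int)
            cints = np.zeros(up - lo + 1, dtype=int)
            # spread guessed censors uniformly over the interval's clicks
            if ncen_guess > 0:
                pos = ((np.arange(ncen_guess) + 0.5) * (up - lo + 1) / ncen_guess).astype(int)
                for pp in pos:
                    cints[min(pp, up - lo)] += 1
            for j, k in enumerate(range(lo, up + 1)):
                if nk <= 0 or kmp <= 0:
                    dints[j] = 0
                else:
                    dints[j] = int(round(nk * (1.0 - s[k] / kmp)))
                    dints[j] = max(0, min(dints[j], int(round(nk))))
                if dints[j] > 0 and nk > 0:
                    kmp = kmp * (1.0 - dints[j] / nk)
                nk = nk - dints[j] - cints[j]
                sp = s[k]
            state = (dints, cints, nk, kmp, sp)
            if target_next is None:
                break
            diff = int(round(nk - target_next))
            if diff == 0:
                break
            ncen_guess = max(0, ncen_guess + diff)
        dints, cints, nk, kmp, sp = state
        d[lo : up + 1] = dints
        c[lo : up + 1] = cints
        n_hat, km_prev, s_prev = nk, kmp, sp

    # final interval: honour the published total event count if provided
    if dkm.total_events is not None:
        deficit = dkm.total_events - int(d.sum())
        if deficit > 0:
            # additional events at the last click
            add = min(deficit, int(round(n_hat)))
            d[-1] += add
            n_hat -= add
        elif deficit < 0:
            # remove surplus events from the tail
            surplus = -deficit
            for k in range(n_clicks - 1, -1, -1):
                take = min(surplus, d[k])
                d[k] -= take
                n_hat += take
                surplus -= take
                if surplus == 0:
                    break

    # patients still at risk at the curve end are censored there
    times: list[float] = []
    events: list[int] = []
    for k in range(n_clicks):
        times.extend([t[k]] * d[k])
        events.extend([1] * d[k])
        if c[k] > 0:
            hi = t[k + 1] if k + 1 < n_clicks else t_end
            # censoring uniform within (t[k], hi); event-before-censor tie rule
            ct = t[k] + (np.arange(c[k]) + 1) / (c[k] + 1) * (hi - t[k])
            times.extend(ct.tolist())
            events.extend([0] * c[k])
    leftover = int(round(n_hat))
    if leftover > 0:
        times.extend([t_end] * leftover)
        events.extend([0] * leftover)

    order = np.lexsort((np.array(events) == 0, np.array(times)))
    times_a = np.array(times, dtype=float)[order]
    events_a = np.array(events, dtype=int)[order]
    return ReconstructedIPD(times=times_a, events=events_a)


def km_curve(ipd: ReconstructedIPD):
    """Product-limit estimate as a right-continuous step function.

    Returns a callable ``S(t)`` (vectorized) with ``S(0) = 1``.
    """
    if ipd.n == 0:
        raise ValueError("km_curve requires at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.times, event_observed=ipd.events)
    grid = kmf.survival_function_.index.values.astype(float)
    surv = kmf.survival_function_.iloc[:, 0].values.astype(float)

    def S(t):
        arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(grid, arr, side="right") - 1
        idx = np.clip(idx, 0, len(grid) - 1)
        out = np.where(arr < grid[0], 1.0, surv[idx])
        return float(out) if arr.ndim == 0 else out

    return S
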