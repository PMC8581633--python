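"""Tornado, CEAC and cohort-trace figures (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_tornado", "plot_ceac", "plot_trace"]


def plot_tornado(entries, base_icer: float, path, top: int = 12) -> None:
    entries = entries[:top][::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(entries) + 1.5))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878d0")
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base case")
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.name for e in entries], fontsize=8)
    ax.set_xlabel("ICER")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve, path, wtp_lines=()) -> None:
    wtp, prob = zip(*curve)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(wtp, prob, lw=2)
    for line in wtp_lines:
        ax.axvline(line, color="grey", ls=":")
    ax.set_xlabel("willingness to pay per QALY")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_trace(trace, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.stackplot(
        trace.t_months,
        trace.pfd,
        trace.pd_,
        trace.dead,
        labels=["progression-free", "progressed", "dead"],
        colors=["#4878d0", "#ee854a", "#bbbbbb"],
    )
    ax.set_xlabel("months")
    ax.set_ylabel("proportion of cohort")
    ax.set_ylim(0, 1)
    if title:
        ax.set_title(title)
    ax.legend(loc="center right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
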