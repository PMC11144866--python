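"""Optional static plots: tornado diagram, CE plane scatter, CEAC."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .sensitivity import DSARecord, PSAResult

__all__ = ["tornado_plot", "ce_plane_plot", "ceac_plot"]


def tornado_plot(
    records: Sequence[DSARecord], base_outcome: float, path: str | Path
) -> None:
    """Horizontal tornado: one bar per parameter, widest on top."""
    records = [r for r in records if r.error is None]
    names = [r.name for r in records][::-1]
    lows = [r.outcome_at_low for r in records][::-1]
    highs = [r.outcome_at_high for r in records][::-1]
    fig, ax = plt.subplots(figsize=(7, 0.4 * max(len(names), 4) + 1))
    for i, (lo, hi) in enumerate(zip(lows, highs)):
        left, right = sorted((lo, hi))
        ax.barh(i, right - left, left=left, height=0.6, color="#4878a8")
    ax.axvline(base_outcome, color="black", lw=1)
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("outcome")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ce_plane_plot(psa: PSAResult, path: str | Path) -> None:
    """Incremental cost-effectiveness plane with the WTP line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.delta_qalys, psa.delta_cost, s=6, alpha=0.4)
    lim = max(abs(psa.delta_qalys).max(), 1e-6)
    ax.plot([-lim, lim], [-psa.wtp * lim, psa.wtp * lim], "k--", lw=1, label=f"WTP {psa.wtp:g}")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("incremental QALYs (comparator - reference)")
    ax.set_ylabel("incremental cost (yuan)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ceac_plot(curve: Sequence[tuple[float, float]], path: str | Path) -> None:
    """Acceptability of the reference arm across WTP thresholds."""
    wtps, fracs = zip(*curve)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(wtps, fracs, marker="o", ms=3)
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("willingness to pay (yuan/QALY)")
    ax.set_ylabel("probability cost-effective")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
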