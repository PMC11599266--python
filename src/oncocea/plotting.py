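"""Static figure exports: tornado diagram, cost-effectiveness plane, CEAC."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_tornado(entries: Sequence, base_icer: float, path: str | Path) -> Path:
    """Horizontal bars of the ICER range each parameter induces, widest on top."""
    entries = list(entries)[::-1]  # widest at the top of the axis
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(entries) + 1.5))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878a8")
    ax.axvline(base_icer, color="k", lw=1, ls="--", label="base-case ICER")
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.parameter for e in entries], fontsize=8)
    ax.set_xlabel("ICER (CNY/QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ce_scatter(psa, wtp: float, path: str | Path) -> Path:
    """Incremental cost vs incremental QALYs, with the WTP threshold line."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa.d_qaly, psa.d_cost, s=4, alpha=0.25, color="#4878a8")
    q = max(abs(psa.d_qaly).max(), 1e-9)
    ax.plot([-q, q], [-q * wtp, q * wtp], "k--", lw=1,
            label=f"WTP = ¥{wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (CNY)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_ceac(ceac_df, path: str | Path) -> Path:
    """Probability cost-effective against willingness-to-pay."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ceac_df["wtp"], ceac_df["p_ce"], color="#4878a8")
    ax.axhline(0.5, color="grey", lw=0.5, ls=":")
    ax.set_xlabel("Willingness-to-pay (CNY/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
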