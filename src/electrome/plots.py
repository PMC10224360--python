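"""TDAF figures: per-feature median traces with min-max shading.

Before- and after-phase summaries are drawn side by side in contrasting
colours, mirroring the usual presentation of stimulus-response electrome
time courses.  Figures are optional artifacts; the tidy tables remain the
authoritative output.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .tdaf import TDAFSummary

__all__ = ["plot_tdaf"]

_PHASE_COLORS = {"before": "tab:blue", "after": "tab:red"}


def plot_tdaf(
    summaries: list[TDAFSummary],
    path: str | Path,
    title: str | None = None,
) -> Path:
    """Plot one feature's TDAF summaries (one per phase) to *path*."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(8, 3.2), constrained_layout=True)
    offset = 0
    for summary in summaries:
        color = _PHASE_COLORS.get(summary.phase, "tab:gray")
        minutes = summary.minute_index + offset
        ax.fill_between(
            minutes, summary.min, summary.max, alpha=0.25, color=color, linewidth=0
        )
        ax.plot(minutes, summary.median, color=color, label=summary.phase)
        offset = minutes[-1] + 1
    first = summaries[0]
    ax.set_xlabel("minute")
    ax.set_ylabel(f"{first.feature_name} [{first.units}]")
    ax.set_title(title or f"{first.feature_name} — median with min–max range")
    ax.legend(frameon=False)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
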