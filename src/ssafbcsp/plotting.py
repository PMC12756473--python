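"""Band-layout visualization.

One horizontal row of colored blocks per fitted bank over a 4-40 Hz axis,
with the sensorimotor mu (8-12 Hz) and beta (13-30 Hz) ranges shaded for
reference — the figure style used to inspect whether optimized sub-bands
concentrate on the physiologically expected rhythms.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
from matplotlib.patches import Rectangle

from .filterbank import FilterBank

__all__ = ["plot_bank", "plot_report_bands"]

MU_BAND = (8.0, 12.0)
BETA_BAND = (13.0, 30.0)


def _shade_rhythms(ax) -> None:
    ax.axvspan(*MU_BAND, color="tab:blue", alpha=0.12, label="mu (8-12 Hz)")
    ax.axvspan(*BETA_BAND, color="tab:orange", alpha=0.10, label="beta (13-30 Hz)")


def plot_bank(bank: FilterBank, ax=None, y: float = 0.0, height: float = 0.8):
    """Draw one bank as colored blocks on a frequency axis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 1.8))
        _shade_rhythms(ax)
        ax.set_xlabel("frequency (Hz)")
        ax.set_yticks([])
    cmap = plt.get_cmap("tab10")
    for i, band in enumerate(bank):
        ax.add_patch(Rectangle((band.low, y), band.width, height,
                               facecolor=cmap(i % 10), edgecolor="k",
                               linewidth=0.5, alpha=0.75))
    ax.set_xlim(min(4.0, bank[0].low) - 1, max(40.0, bank[-1].high) + 1)
    ax.set_ylim(min(ax.get_ylim()[0], y - 0.2), max(ax.get_ylim()[1], y + height + 0.2))
    return ax


def plot_report_bands(report, out_path: str | Path):
    """One row of band blocks per experiment repeat; writes ``out_path``.

    ``report`` is an :class:`~ssafbcsp.pipeline.ExperimentReport`; raises
    on an empty one.
    """
    banks = [rec.bank for rec in report.repeats]
    if not banks:
        raise ValueError("report contains no fitted banks to plot")
    fig, ax = plt.subplots(figsize=(8, 0.6 * len(banks) + 1.2))
    _shade_rhythms(ax)
    for row, bank in enumerate(banks):
        plot_bank(bank, ax=ax, y=row + 0.1, height=0.8)
    ax.set_ylim(0, len(banks) + 0.2)
    ax.set_yticks([r + 0.5 for r in range(len(banks))])
    ax.set_yticklabels([f"repeat {r}" for r in range(len(banks))])
    ax.set_xlabel("frequency (Hz)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
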