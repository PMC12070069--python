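"""Plotting of averaged profiles: mean curves with s.e.m. shading per channel."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .alignment import AverageProfile

__all__ = ["plot_average_profile"]


def plot_average_profile(
    avg: AverageProfile, path: str | Path | None = None, ax: plt.Axes | None = None
) -> plt.Axes:
    """Plot each channel's mean ± s.e.m. against the centred position axis.

    Position 0 is the fitted reference peak; negative positions are medial.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.2))
    for ci, label in enumerate(avg.channel_labels):
        ax.plot(avg.grid, avg.means[ci], label=label)
        ax.fill_between(
            avg.grid,
            avg.means[ci] - avg.sems[ci],
            avg.means[ci] + avg.sems[ci],
            alpha=0.3,
            linewidth=0,
        )
    ax.set_xlabel("position (px, reference peak at 0, medial < 0)")
    ax.set_ylabel("normalized intensity")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
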