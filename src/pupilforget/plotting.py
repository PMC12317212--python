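"""Condition-mean trace plots with significant-cluster markers."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .cluster import ContrastResult  # noqa: E402


def plot_contrast(result: ContrastResult, path=None, title: str | None = None,
                  bin_width_ms: int = 20):
    """Per-condition mean ± SEM over time; significant bins as a black bar.

    Mirrors the standard presentation of binned pupil contrasts: one ribbon
    per condition, a horizontal marker under bins belonging to clusters that
    survived permutation correction (p < 0.05).
    """
    fig, ax = plt.subplots(figsize=(7, 4))
    means = result.condition_means
    for cond, g in means.groupby("condition"):
        t = g["time_ms"].to_numpy() + bin_width_ms / 2
        ax.plot(t, g["mean"], label=str(cond))
        ax.fill_between(t, g["mean"] - g["sem"], g["mean"] + g["sem"], alpha=0.25)
    ymin = (means["mean"] - means["sem"]).min()
    for c in result.permutation.clusters:
        if c.p is not None and c.p < 0.05:
            lo, hi = c.time_window_ms(bin_width_ms)
            ax.plot([lo, hi], [ymin, ymin], color="black", linewidth=3,
                    solid_capstyle="butt")
    ax.axhline(0.0, color="gray", linewidth=0.5)
    ax.set_xlabel("Time from stimulus onset (ms)")
    ax.set_ylabel("Baseline-corrected pupil size (a.u.)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
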