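"""Diagnostic plots: Bland-Altman scatter and Kaplan-Meier step curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .agreement import BlandAltmanResult, DifferenceCurve

__all__ = ["plot_bland_altman", "plot_difference_curves"]


def plot_bland_altman(ba: BlandAltmanResult, title: str = "", path=None):
    """Scatter of pair differences vs pair means with limit lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.pair_means, ba.pair_diffs, s=12, alpha=0.7, edgecolors="none")
    for yv, style, lab in [
        (ba.mean_diff, "-", f"mean {ba.mean_diff:.2f}"),
        (ba.loa_low, "--", f"-1.96 SD {ba.loa_low:.2f}"),
        (ba.loa_high, "--", f"+1.96 SD {ba.loa_high:.2f}"),
    ]:
        ax.axhline(yv, linestyle=style, color="k", linewidth=1)
        ax.annotate(lab, (0.99, yv), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=7)
    ax.set_xlabel("mean of pair (%)")
    ax.set_ylabel("difference of pair (%)")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_difference_curves(curves: dict[str, DifferenceCurve], path=None):
    """Superimposed step curves of P(|difference| > d)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        ax.step([0.0, *c.thresholds], [1.0, *c.survival], where="post", label=label)
    ax.set_xlabel("difference threshold d (%)")
    ax.set_ylabel("P(|difference| > d)")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
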