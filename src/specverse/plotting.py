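"""Static specification-curve figures (two-panel layout)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .multiverse import SpecCurve


def plot_spec_curve(curve: SpecCurve, out_path: str | None = None):
    """Top panel: ranked estimates with 95% intervals, colored by sign and
    interval evidence; bottom panel: decision-point membership marks."""
    df = curve.table
    reserved = {
        "fork_id", "term", "estimate", "lower", "upper", "excludes_zero",
        "sign", "rank", "converged",
    }
    decisions = [c for c in df.columns if c not in reserved]
    levels = [(d, lv) for d in decisions for lv in sorted(df[d].unique())]
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(10, 4 + 0.25 * len(levels)), sharex=True,
        height_ratios=[2, max(1, 0.12 * len(levels))],
    )
    x = df["rank"].to_numpy()
    colors = np.where(
        df["excludes_zero"],
        np.where(df["estimate"] < 0, "crimson", "purple"),
        np.where(df["estimate"] < 0, "steelblue", "seagreen"),
    )
    ax1.vlines(x, df["lower"], df["upper"], color=colors, alpha=0.4, lw=0.8)
    ax1.scatter(x, df["estimate"], c=colors, s=8)
    ax1.axhline(0, color="gray", lw=0.8)
    ax1.axhline(curve.median, color="black", ls=":", lw=1)
    ax1.set_ylabel("estimate (95% interval)")
    for i, (d, lv) in enumerate(levels):
        mask = df[d] == lv
        ax2.scatter(x[mask], np.full(mask.sum(), i), s=6, c="black")
    ax2.set_yticks(range(len(levels)))
    ax2.set_yticklabels([f"{d} = {lv}" for d, lv in levels], fontsize=7)
    ax2.set_xlabel("specification rank (ascending estimate)")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
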