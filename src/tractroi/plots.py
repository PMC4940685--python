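"""Publication-style figures: FA by position, reliability by position."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

_COLORS = {
    "manual_b0": "tab:blue",
    "manual_t1w": "tab:orange",
    "fa_skeleton": "tab:green",
    "tractography": "tab:red",
}


def plot_fa_by_position(table: pd.DataFrame, path: str) -> None:
    """Mean FA and 95 % CI per analysis position, one curve per ROI method."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for method, sub in table.groupby("method"):
        per = sub.groupby(["position", "subject"])["fa"].mean().reset_index()
        g = per.groupby("position")["fa"]
        mean, sd, n = g.mean(), g.std(ddof=1), g.count()
        ci = 1.96 * sd / np.sqrt(n)
        ax.errorbar(mean.index, mean, yerr=ci, label=method,
                    color=_COLORS.get(method), capsize=2, marker="o", ms=3)
    ax.set_xlabel("position (coronal slice, anterior to posterior)")
    ax.set_ylabel("FA")
    ax.legend(frameon=False)
    for x in (5.5, 10.5):
        ax.axvline(x, color="gray", lw=0.5, ls=":")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_reliability(inter: dict, intra: dict, path: str,
                     interscan: dict | None = None) -> None:
    """Limits-of-agreement (inter-rater) and repeatability intervals per position.

    Intervals share the mid-point of the corresponding limits of agreement so
    the widths are directly comparable.
    """
    methods = sorted(set(inter) | set(intra))
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True, sharey=True)
    for ax, method in zip(axes.ravel(), methods):
        t_inter = inter.get(method)
        t_intra = intra.get(method)
        if t_inter is not None and len(t_inter):
            mid = t_inter["mean_difference"]
            ax.fill_between(t_inter["position"], t_inter["loa_low"],
                            t_inter["loa_high"], alpha=0.25, color="tab:blue",
                            label="inter-rater LoA")
            if t_intra is not None and len(t_intra):
                m = t_intra.set_index("position").reindex(t_inter["position"])
                half = m["repeatability_coefficient"].to_numpy() / 2.0
                ax.fill_between(t_inter["position"], mid - half, mid + half,
                                alpha=0.4, color="tab:red",
                                label="intra-rater RC")
            if interscan and method in interscan and len(interscan[method]):
                sc = interscan[method].set_index("position").reindex(
                    t_inter["position"])
                half = sc["interval_halfwidth"].to_numpy() / 2.0
                ax.plot(t_inter["position"], mid + half, color="tab:cyan",
                        lw=1, label="inter-scan")
                ax.plot(t_inter["position"], mid - half, color="tab:cyan", lw=1)
        ax.set_title(method)
    axes[0, 0].legend(frameon=False, fontsize=8)
    for ax in axes[1]:
        ax.set_xlabel("position")
    for ax in axes[:, 0]:
        ax.set_ylabel("FA difference")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
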