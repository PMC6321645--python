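"""Figure export: ΔSNP-index chromosome tracks and per-group distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

_CATEGORY_COLORS = {"Aet": "tab:red", "Ldn": "tab:blue", "Unknown": "tab:gray"}


def plot_delta_tracks(tracks, path):
    """Scatter of averaged ΔSNP-index along each chromosome, colored by site
    category (one panel per chromosome)."""
    chroms = list(dict.fromkeys(tracks["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 1.6 * len(chroms)),
                             sharex=False, sharey=True, squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = tracks[tracks["chrom"] == chrom]
        for cat, color in _CATEGORY_COLORS.items():
            s = sub[sub["category"] == cat]
            ax.scatter(s["pos"] / 1e6, s["avg_delta"], s=3, color=color, label=cat, alpha=0.6)
        ax.axhline(0, lw=0.5, color="k")
        ax.set_ylabel(chrom)
        ax.set_ylim(-1.05, 1.05)
    axes[0, 0].legend(markerscale=3, fontsize=7, ncol=3)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.suptitle("averaged ΔSNP-index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_chromosome_boxes(groups, labels, path):
    """Box-and-dot plot of ΔSNP-index distributions per group."""
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 1, 4))
    ax.boxplot(groups, tick_labels=labels, showfliers=False)
    for i, g in enumerate(groups, start=1):
        x = [i] * len(g)
        ax.plot(x, g, ".", ms=2, alpha=0.4, color="tab:gray")
    ax.set_ylabel("averaged ΔSNP-index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
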