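"""Matplotlib figure helpers for the pipeline's standard plot layouts."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

SUPERORDER_STYLE = {
    "Afrotheria": dict(color="red", marker="o"),
    "Euarchontoglires": dict(color="grey", marker="v"),
    "Laurasiatheria": dict(color="green", marker="^"),
    "Xenarthra": dict(color="blue", marker="s"),
}


def window_plot(window_profiles, path, title: str | None = None):
    """Sliding-window tracks (midpoint vs value) with gene-boundary ticks."""
    fig, ax = plt.subplots(figsize=(10, 4))
    for wp in window_profiles:
        ax.plot(wp.midpoints, wp.values, lw=1, label=wp.taxon_or_pair)
    boundaries = window_profiles[0].gene_boundaries if window_profiles else None
    if boundaries:
        top = ax.get_ylim()[1]
        for gene, (start, end) in boundaries.items():
            ax.axvline(start, color="0.8", lw=0.5)
            ax.text((start + end) / 2, top, gene, ha="center", va="bottom",
                    fontsize=7)
    ax.set_xlabel("window midpoint (bp)")
    ax.set_ylabel(window_profiles[0].statistic if window_profiles else "")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ordination_plot(result, path, dims=(0, 1), title: str | None = None):
    """PCoA scatter in two axes, coloured by super-order."""
    fig, ax = plt.subplots(figsize=(6, 6))
    groups = result.group_labels or {}
    for name, style in SUPERORDER_STYLE.items():
        idx = [i for i, l in enumerate(result.labels) if groups.get(l) == name]
        if idx:
            ax.scatter(
                result.coordinates[idx, dims[0]],
                result.coordinates[idx, dims[1]],
                s=12, label=name, **style,
            )
    vf = result.variance_fractions
    ax.set_xlabel(f"axis {dims[0] + 1} ({100 * vf[dims[0]]:.1f}%)")
    ax.set_ylabel(f"axis {dims[1] + 1} ({100 * vf[dims[1]]:.1f}%)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def saturation_plot(series, path, title: str | None = None):
    """%Ti against pairwise K2P distance."""
    fig, ax = plt.subplots(figsize=(6, 4))
    df = series.to_frame()
    ax.scatter(df["k2p"], df["percent_ti"], s=4, alpha=0.4)
    ax.axhline(0.5, color="red", lw=0.8, ls="--")
    ax.set_xlabel("K2P distance")
    ax.set_ylabel("%Ti")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
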