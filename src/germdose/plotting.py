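"""Matplotlib views of the dosage results."""
from __future__ import annotations

import numpy as np

_CHROM_COLORS = {
    "MullerA": "#c23b3b",
    "MullerAD": "#7b3bc2",
    "MullerC": "#e08a2e",
    "neoY": "#3b6fc2",
}


def plot_xa_trajectories(xa, ax=None, chromosomes=None):
    """Chromosome-median X:A trajectories with bootstrap ribbons."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    if chromosomes is None:
        chromosomes = [c for c in _CHROM_COLORS
                       if c in xa.medians.index.get_level_values(0)]
    x = np.arange(len(xa.stages))
    for chrom in chromosomes:
        traj = xa.trajectory(chrom)
        color = _CHROM_COLORS.get(chrom, "gray")
        ax.plot(x, traj["median"], marker="o", label=chrom, color=color)
        ax.fill_between(x, traj["ci_lo"], traj["ci_hi"], alpha=0.2, color=color)
    ax.axhline(1.0, ls=":", color="gray")
    ax.axhline(0.5, ls="--", color="gray")
    ax.set_xticks(x, xa.stages, rotation=45, ha="right")
    ax.set_ylabel("X:A ratio (chromosome median)")
    ax.legend(frameon=False)
    return ax


def plot_dc_gene_dotplot(summary, ax=None):
    """Dot plot of DC-machinery genes: dot size = fraction of expressing
    cells, color = mean log1p expression."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    df = summary.reset_index()
    genes = list(dict.fromkeys(df.gene_id))
    stages = list(dict.fromkeys(df.cell_type))
    xi = df.cell_type.map({s: i for i, s in enumerate(stages)})
    yi = df.gene_id.map({g: i for i, g in enumerate(genes)})
    sc = ax.scatter(xi, yi, s=200 * df.fraction_expressing.fillna(0),
                    c=df.mean_log1p, cmap="viridis")
    ax.set_xticks(range(len(stages)), stages, rotation=45, ha="right")
    ax.set_yticks(range(len(genes)), genes)
    plt.colorbar(sc, ax=ax, label="mean log1p expression")
    return ax
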