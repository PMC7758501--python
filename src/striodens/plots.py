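"""Summary plots: group means with SEM bars, one panel per metric."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_group_summary"]


def plot_group_summary(
    table: pd.DataFrame,
    metric: str = "ismp",
    level: str = "rostral",
    ax: "plt.Axes | None" = None,
):
    """Bar chart of group mean +/- SEM per sector x age, split by genotype."""
    sub = table[(table["level"] == level)].dropna(subset=[metric])
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3.5))
    sectors = [s for s in ("whole", "DM", "DL", "VM", "VL") if s in set(sub["sector"])]
    ages = sorted(sub["age"].unique())
    genotypes = sorted(sub["genotype"].unique())
    width = 0.8 / max(len(genotypes), 1)
    positions, labels = [], []
    x = 0.0
    for age in ages:
        for sector in sectors:
            cell = sub[(sub["age"] == age) & (sub["sector"] == sector)]
            for gi, genotype in enumerate(genotypes):
                vals = cell[cell["genotype"] == genotype][metric]
                if not len(vals):
                    continue
                sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
                ax.bar(
                    x + gi * width,
                    vals.mean(),
                    width=width,
                    yerr=sem,
                    capsize=2,
                    color=f"C{gi}",
                    label=genotype if (age == ages[0] and sector == sectors[0]) else None,
                )
            positions.append(x + 0.4)
            labels.append(f"{sector}\n{age}m")
            x += 1.0
        x += 0.5
    ax.set_xticks(positions)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel(metric)
    ax.set_title(f"{metric} ({level})")
    ax.legend(frameon=False, fontsize=8)
    return ax
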