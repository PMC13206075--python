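"""Figures for concordance reports: candidate-vs-null PCC box plot and
per-(collection, direction) AUROC bar chart with the 0.5 random baseline."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402


def plot_pcc_boxes(report, ax=None):
    """Box plot of the null PCC sample beside each candidate's PCC."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    null = report.null_pcc.dropna().to_numpy()
    ax.boxplot([null], positions=[0], widths=0.5, tick_labels=["random"])
    for i, (gene, v) in enumerate(report.candidate_pcc.items(), start=1):
        ax.scatter([i], [v], zorder=3)
        ax.annotate(gene, (i, v), textcoords="offset points", xytext=(0, 5),
                    ha="center", fontsize=8)
    ax.set_xticks(range(len(report.candidate_pcc) + 1),
                  ["random", *report.candidate_pcc.index])
    ax.set_ylabel("PCC with drug profile")
    ax.axhline(0.0, color="grey", lw=0.5)
    return ax


def plot_auroc_bars(auroc_table, ax=None):
    """Bar chart of AUROC per (collection, direction, candidate); the
    dashed line marks the 0.5 random-classification baseline."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    table = auroc_table.dropna(subset=["auroc"])
    labels = [f"{r.collection}/{r.direction}\n{r.candidate}"
              for r in table.itertuples(index=False)]
    ax.bar(np.arange(len(table)), table["auroc"])
    ax.set_xticks(np.arange(len(table)), labels, fontsize=7, rotation=45,
                  ha="right")
    ax.axhline(0.5, color="red", ls="--", lw=1, label="random (0.5)")
    ax.set_ylim(0, 1)
    ax.set_ylabel("AUROC")
    ax.legend(fontsize=8)
    return ax
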