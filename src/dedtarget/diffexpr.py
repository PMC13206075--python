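"""Per-dataset differential expression for count data.

The stage mirrors the standard bulk RNA-seq recipe at desk scale: genes
with a group-total count below 10 in both groups are dropped, samples are
normalized with median-of-ratios size factors, fold changes are moderated
with a prior count (a deliberately simple stand-in for posterior shrinkage
estimators — the downstream statistics only need a shrunken log2FC), and
p-values come from an unequal-variance two-sample t-test on
log2(normalized + prior) values with Benjamini-Hochberg adjustment.
Differentially expressed genes are those with |log2FC| > 1 and adjusted
p < 0.05, both strict.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CONTROL, TREATMENT, CountMatrix, ValidationError
from .enrichment import RankedGeneList

logger = logging.getLogger(__name__)

#: Fixed output column names, for interoperability with downstream tools.
DE_COLUMNS = ["gene", "baseMean", "log2FoldChange", "pvalue", "padj"]


def filter_low_counts(
    counts: CountMatrix, min_count: int = 10, mode: str = "union"
) -> CountMatrix:
    """Drop low-abundance genes by group-total count.

    ``mode="union"`` (default) keeps a gene if its total count reaches
    ``min_count`` in *either* group; ``mode="intersection"`` requires both
    groups.  Gene order is preserved.
    """
    if mode not in ("union", "intersection"):
        raise ValidationError("mode must be 'union' or 'intersection'")
    ctrl = counts.counts[counts.samples_in(CONTROL)].sum(axis=1)
    trt = counts.counts[counts.samples_in(TREATMENT)].sum(axis=1)
    if mode == "union":
        keep = (ctrl >= min_count) | (trt >= min_count)
    else:
        keep = (ctrl >= min_count) & (trt >= min_count)
    if not keep.any():
        raise ValidationError("no genes pass filter")
    return counts.subset_genes(counts.counts.index[keep])


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    The per-gene reference is the geometric mean over samples, computed
    over genes with no zero count; each sample's factor is the median of
    its count/reference ratios over those reference genes.
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValidationError(
            "no gene is nonzero in every sample; cannot form the "
            "geometric-mean reference (consider a pseudo-reference fallback)"
        )
    ref = np.exp(np.mean(np.log(mat[all_nonzero]), axis=1))
    ratios = mat[all_nonzero] / ref[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.counts.columns,
                     name="size_factor")


def normalized_counts(counts: CountMatrix, size_factors: pd.Series | None = None) -> pd.DataFrame:
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    return counts.counts / size_factors


def differential_expression(
    counts: CountMatrix, prior_count: float = 2.0
) -> pd.DataFrame:
    """Moderated log2FC, Welch t p-values and BH adjustment per gene.

    log2FC = log2((mean normalized treatment + prior) /
    (mean normalized control + prior)); the prior count moderates fold
    changes of low-information genes toward zero.  Returns a DataFrame with
    the fixed ``DE_COLUMNS`` layout, indexed by gene in input order.
    """
    if prior_count <= 0:
        raise ValidationError("prior_count must be positive")
    norm = normalized_counts(counts)
    ctrl = norm[counts.samples_in(CONTROL)].to_numpy()
    trt = norm[counts.samples_in(TREATMENT)].to_numpy()
    if ctrl.shape[1] < 2 or trt.shape[1] < 2:
        raise ValidationError("each group needs >= 2 samples")

    base_mean = norm.mean(axis=1).to_numpy()
    log2fc = np.log2(trt.mean(axis=1) + prior_count) - \
        np.log2(ctrl.mean(axis=1) + prior_count)

    log_ctrl = np.log2(ctrl + prior_count)
    log_trt = np.log2(trt + prior_count)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvalue = stats.ttest_ind(log_trt, log_ctrl, axis=1, equal_var=False)
    # constant genes (zero variance in both groups) are definitionally null
    pvalue = np.where(np.isnan(pvalue), 1.0, pvalue)
    padj = multipletests(pvalue, method="fdr_bh")[1]

    return pd.DataFrame({
        "gene": counts.genes,
        "baseMean": base_mean,
        "log2FoldChange": log2fc,
        "pvalue": pvalue,
        "padj": padj,
    }).set_index("gene", drop=False).rename_axis(None)


def call_degs(results: pd.DataFrame, lfc_thresh: float = 1.0,
              alpha: float = 0.05) -> set[str]:
    """Genes with |log2FC| > lfc_thresh AND padj < alpha (both strict)."""
    if results.empty:
        raise ValidationError("DE results are empty")
    hit = (results["log2FoldChange"].abs() > lfc_thresh) & (results["padj"] < alpha)
    return set(results.loc[hit, "gene"])


def rank_genes(results: pd.DataFrame) -> RankedGeneList:
    """Rank genes by log2FC descending; ties broken by gene identifier
    (lexicographic), so the order is deterministic across runs."""
    if results.empty:
        raise ValidationError("DE results are empty")
    if results["gene"].duplicated().any():
        raise ValidationError("duplicate genes in DE results")
    if not np.isfinite(results["log2FoldChange"]).all():
        raise ValidationError("log2FC must be finite to rank")
    ordered = results.sort_values(
        ["log2FoldChange", "gene"], ascending=[False, True], kind="mergesort"
    )
    return RankedGeneList(list(ordered["gene"]),
                          ordered["log2FoldChange"].to_numpy())
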