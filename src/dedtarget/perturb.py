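"""Virtual-cell knockdown surrogate and perturbation-profile adapter.

The engine behind the original in-silico knockdown analysis is
unpublished, so this module provides a deliberately simple, documented
surrogate: a co-expression model fitted to baseline count datasets
(average per-dataset correlation of log-normalized expression, shrunk
toward zero and sparsified), and a first-order linear propagation rule — a
knockdown sets the target gene's log2FC to the primary effect and every
other gene to ``weight * primary effect``.  Any richer engine's output can
be dropped in through :func:`load_profiles` and validated by the same
concordance statistics.
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CountMatrix, PerturbationProfile, ValidationError
from .diffexpr import estimate_size_factors, normalized_counts

logger = logging.getLogger(__name__)


@dataclass
class CoexpressionModel:
    """Symmetric shrunken-correlation association weights over a gene
    universe; w_ii = 1, |w_ij| <= 1."""

    genes: list[str]
    weights: np.ndarray = field(repr=False)
    shrinkage: float = 0.5
    sparsity: float = 0.2

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.genes)
        if w.shape != (n, n):
            raise ValidationError("weight matrix shape mismatch")
        if not np.allclose(w, w.T):
            raise ValidationError("weights must be symmetric")
        if np.nanmax(np.abs(w)) > 1 + 1e-9:
            raise ValidationError("|weights| must be <= 1")
        if not np.allclose(np.diag(w), 1.0):
            raise ValidationError("diagonal weights must be 1")
        self.weights = w

    def index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            near = difflib.get_close_matches(gene, self.genes, n=3)
            raise ValidationError(
                f"gene {gene!r} not in model universe; nearest: {near}"
            ) from None

    # ------------------------------------------------------------------ IO
    def to_tsv(self, path) -> None:
        """Sparse triplet serialization (gene_i, gene_j, weight), upper
        triangle only (the matrix is symmetric with unit diagonal)."""
        i, j = np.nonzero(np.triu(self.weights, k=1))
        pd.DataFrame({
            "gene_i": np.array(self.genes)[i],
            "gene_j": np.array(self.genes)[j],
            "weight": self.weights[i, j],
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, genes, shrinkage: float = 0.5,
                 sparsity: float = 0.2) -> "CoexpressionModel":
        genes = list(genes)
        idx = {g: i for i, g in enumerate(genes)}
        w = np.eye(len(genes))
        for row in pd.read_csv(path, sep="\t").itertuples(index=False):
            i, j = idx[row.gene_i], idx[row.gene_j]
            w[i, j] = w[j, i] = row.weight
        return cls(genes, w, shrinkage, sparsity)


def fit_reference_model(
    baselines: list[CountMatrix],
    shrinkage: float = 0.5,
    sparsity: float = 0.2,
) -> CoexpressionModel:
    """Average per-dataset correlation of log-normalized expression,
    shrunk toward 0 by ``(1 - shrinkage)`` and thresholded at ``sparsity``.

    The shrinkage/sparsity defaults are chosen so that knockdowns of genes
    unrelated to the drug's targets produce near-zero concordance (the
    null concentrates near 0).
    """
    if not baselines:
        raise ValidationError("no baseline datasets supplied")
    if not (0 <= shrinkage <= 1):
        raise ValidationError("shrinkage must be in [0, 1]")
    genes = baselines[0].genes
    for b in baselines[1:]:
        if b.genes != genes:
            raise ValidationError("baseline datasets must share a gene universe")
    if sum(len(b.samples) for b in baselines) < 4:
        raise ValidationError("need >= 4 total samples (correlation unstable)")

    acc = np.zeros((len(genes), len(genes)))
    for b in baselines:
        norm = normalized_counts(b, estimate_size_factors(b))
        logx = np.log2(norm.to_numpy() + 1.0)
        sd = logx.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(logx)
        corr = np.nan_to_num(corr, nan=0.0)  # constant genes: no association
        corr[sd == 0, :] = 0.0
        corr[:, sd == 0] = 0.0
        acc += corr
    w = (acc / len(baselines)) * (1.0 - shrinkage)
    w[np.abs(w) < sparsity] = 0.0
    np.fill_diagonal(w, 1.0)
    return CoexpressionModel(genes, w, shrinkage, sparsity)


def simulate_knockdown(
    model: CoexpressionModel, gene: str, primary_log2fc: float = -2.0
) -> PerturbationProfile:
    """First-order linear knockdown: the target takes ``primary_log2fc``;
    gene j takes ``w_gj * primary_log2fc``.  Deterministic."""
    g = model.index(gene)
    vec = model.weights[g] * primary_log2fc
    return PerturbationProfile(
        f"KD:{gene}", pd.Series(vec, index=model.genes)
    )


def load_profiles(
    paths_labels: list[tuple[str, str]],
    universe=None,
    unknown: str = "drop",
) -> list[PerturbationProfile]:
    """Load external (gene, log2FC) TSV profiles onto a common universe.

    ``paths_labels`` is a list of (path, label) pairs.  If ``universe`` is
    given, genes outside it are dropped (``unknown="drop"``) or the
    universe is extended (``unknown="extend"``); genes of the universe
    missing from a file are imputed as 0 with a warning count.
    """
    if unknown not in ("drop", "extend"):
        raise ValidationError("unknown must be 'drop' or 'extend'")
    raw: list[tuple[str, pd.Series]] = []
    for path, label in paths_labels:
        try:
            frame = pd.read_csv(path, sep="\t", index_col=0)
            series = frame["log2FC"].astype(float)
        except (KeyError, ValueError) as exc:
            raise ValidationError(f"{path}: malformed profile TSV ({exc})") from exc
        bad = series.index[~np.isfinite(series.to_numpy())]
        if len(bad):
            raise ValidationError(
                f"{path}: non-finite log2FC at rows "
                f"{[int(series.index.get_loc(b)) + 2 for b in bad]}"
            )
        raw.append((label, series))

    if universe is None:
        universe = sorted(set().union(*(set(s.index) for _, s in raw)))
    else:
        universe = list(universe)
        extra = sorted(set().union(*(set(s.index) for _, s in raw)) - set(universe))
        if extra and unknown == "extend":
            universe = universe + extra
        elif extra:
            logger.warning("load_profiles: dropping %d genes outside the "
                           "universe", len(extra))

    out = []
    for label, series in raw:
        missing = len(set(universe) - set(series.index))
        if missing:
            logger.warning("load_profiles: %r imputing 0 for %d missing genes",
                           label, missing)
        out.append(PerturbationProfile(
            label, series.reindex(universe).fillna(0.0)
        ))
    return out
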