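"""Knockdown-vs-drug concordance statistics.

Transcriptome level: Pearson correlation between a knockdown's log2FC
profile and the drug profile, restricted to the top 20% most-altered genes
of the *drug* profile (one fixed subset for candidates and null alike, so
all knockdowns are compared on the same footing; a per-pair union basis is
offered as an alternative).  The null is built by knocking down randomly
selected genes (default 100) and candidate/null separation is tested with
the unpaired two-sided Wilcoxon rank-sum test.

Pathway level: with the drug's significant pathway alterations as binary
labels and a knockdown's signed NES as the prediction score, the AUROC is
computed in its Mann-Whitney U-statistic form (ties count one half), so an
uninformative predictor scores 0.5 in expectation.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PerturbationProfile, ValidationError
from .enrichment import EnrichmentResult
from .perturb import CoexpressionModel, simulate_knockdown

logger = logging.getLogger(__name__)


def select_top_altered(drug: PerturbationProfile, fraction: float = 0.2) -> list[str]:
    """The ceil(fraction * N) genes with largest |log2FC| in the drug
    profile; ties broken by gene identifier (lexicographic)."""
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    n = math.ceil(fraction * len(drug.log2fc))
    order = sorted(drug.log2fc.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    return [g for g, _ in order[:n]]


def pcc_concordance(kd: PerturbationProfile, drug: PerturbationProfile,
                    genes) -> float:
    """Pearson correlation of the two log2FC vectors over ``genes``.

    Zero variance in either restricted vector is flagged (NaN) rather than
    raised, so degenerate knockdowns are excluded from downstream tests.
    """
    genes = list(genes)
    if len(genes) < 3:
        raise ValidationError("need >= 3 genes for a correlation")
    x = kd.log2fc.loc[genes].to_numpy()
    y = drug.log2fc.loc[genes].to_numpy()
    if x.std() == 0 or y.std() == 0:
        logger.warning("pcc_concordance: zero variance for %r; returning NaN",
                       kd.label)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def random_null(
    model: CoexpressionModel,
    drug: PerturbationProfile,
    eligible,
    n_null: int = 100,
    fraction: float = 0.2,
    seed: int | None = None,
    primary_log2fc: float = -2.0,
) -> pd.Series:
    """Null PCC sample from knockdowns of randomly selected genes.

    ``eligible`` must already exclude the candidate genes (and is normally
    restricted to expressed, filter-passing genes).  Each sampled gene is
    knocked down through the model and its PCC with the drug profile is
    computed on the same top-fraction subset used for candidates.
    """
    eligible = sorted(set(eligible))
    if len(eligible) < n_null:
        raise ValidationError(
            f"eligible pool ({len(eligible)}) smaller than n_null ({n_null})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n_null, replace=False)
    genes = select_top_altered(drug, fraction)
    values = {}
    for g in chosen:
        kd = simulate_knockdown(model, g, primary_log2fc)
        values[g] = pcc_concordance(kd, drug, genes)
    return pd.Series(values, name="null_pcc")


def compare_to_null(candidate_pccs, null_sample) -> float:
    """Two-sided unpaired Wilcoxon rank-sum p-value, candidates vs null.

    Exact enumeration when the smaller sample has <= 20 observations and
    there are no ties (the normal approximation cannot resolve small tail
    probabilities for a handful of candidates against a large null);
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(pd.Series(candidate_pccs).dropna(), dtype=float)
    y = np.asarray(pd.Series(null_sample).dropna(), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 20 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def auroc(labels, scores) -> float:
    """AUROC in Mann-Whitney U form: P(score_pos > score_neg) with ties
    counting one half.  NaN when only one class is present."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)  # midranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pathway_auroc(
    drug_enrichment: list[EnrichmentResult],
    kd_enrichment: list[EnrichmentResult],
    direction: str,
    alpha: float = 0.05,
) -> tuple[float, int, int]:
    """Pathway-level concordance of a knockdown with the drug.

    Labels: 1 for pathways where the drug enrichment has p < alpha and NES
    sign matching ``direction``, else 0.  Scores: the knockdown's signed
    NES, negated for ``direction="down"`` so larger always means "more in
    the labeled direction".  Returns (AUROC, n_pos, n_neg); AUROC is NaN
    (flagged, excluded from summaries) when a class is missing.
    """
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    drug = {r.name: r for r in drug_enrichment}
    kd = {r.name: r for r in kd_enrichment}
    shared = sorted(set(drug) & set(kd))
    if not shared:
        raise ValidationError("no shared pathway universe")
    sign = 1.0 if direction == "up" else -1.0
    labels = [
        int(drug[p].pvalue < alpha and np.sign(drug[p].nes) == sign)
        for p in shared
    ]
    scores = [sign * kd[p].nes for p in shared]
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        logger.warning("pathway_auroc: single-class labels (%d pos, %d neg); "
                       "AUROC undefined", n_pos, n_neg)
    return auroc(labels, scores), n_pos, n_neg


@dataclass
class ConcordanceReport:
    """Candidate-vs-null concordance of knockdowns with the drug profile."""

    candidate_pcc: pd.Series
    null_pcc: pd.Series
    rank_sum_p: float
    auroc_table: pd.DataFrame  # collection, direction, candidate, auroc, n_pos, n_neg
    fraction: float
    n_null: int
    seed: int | None
    per_candidate_p: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "candidate_pcc": self.candidate_pcc.to_dict(),
                "null_pcc": self.null_pcc.to_dict(),
                "rank_sum_p": self.rank_sum_p,
                "per_candidate_p": self.per_candidate_p,
                "auroc": self.auroc_table.to_dict(orient="records"),
                "metadata": {"fraction": self.fraction, "n_null": self.n_null,
                             "seed": self.seed},
            }, fh, indent=1, sort_keys=True)


def concordance_report(
    model: CoexpressionModel,
    drug: PerturbationProfile,
    candidates: list[str],
    eligible,
    enrichments: dict[str, dict[str, list[EnrichmentResult]]] | None = None,
    fraction: float = 0.2,
    n_null: int = 100,
    seed: int | None = None,
    primary_log2fc: float = -2.0,
    alpha: float = 0.05,
    profiles: dict[str, PerturbationProfile] | None = None,
) -> ConcordanceReport:
    """End-to-end candidate scoring: PCC per candidate, the random-gene
    null, rank-sum p-values, and per-(collection, direction) AUROCs.

    ``enrichments`` maps collection name -> {"drug": results,
    "KD:<gene>": results} when pathway-level scoring is wanted.
    ``profiles`` optionally supplies externally computed knockdown profiles
    per candidate gene (e.g. from a richer perturbation engine); candidates
    without one are simulated through ``model``.
    """
    genes = select_top_altered(drug, fraction)
    profiles = profiles or {}
    cand_pcc = {}
    for g in candidates:
        kd = profiles.get(g) or simulate_knockdown(model, g, primary_log2fc)
        cand_pcc[g] = pcc_concordance(kd, drug, genes)
    cand_pcc = pd.Series(cand_pcc, name="pcc")

    pool = set(eligible) - set(candidates)
    null = random_null(model, drug, pool, n_null=n_null, fraction=fraction,
                       seed=seed, primary_log2fc=primary_log2fc)
    p_group = compare_to_null(cand_pcc, null)
    per_candidate = {
        g: compare_to_null([v], null)
        for g, v in cand_pcc.items() if np.isfinite(v)
    }

    rows = []
    for collection, res in (enrichments or {}).items():
        for g in candidates:
            key = f"KD:{g}"
            if key not in res or "drug" not in res:
                continue
            for direction in ("up", "down"):
                a, n_pos, n_neg = pathway_auroc(res["drug"], res[key],
                                                direction, alpha)
                rows.append((collection, direction, g, a, n_pos, n_neg))
    auroc_table = pd.DataFrame(
        rows, columns=["collection", "direction", "candidate", "auroc",
                       "n_pos", "n_neg"])

    return ConcordanceReport(cand_pcc, null, p_group, auroc_table,
                             fraction, n_null, seed, per_candidate)
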