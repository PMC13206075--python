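"""Pre-ranked gene-set enrichment analysis with leading-edge extraction.

Implements the weighted Kolmogorov-Smirnov-like running-sum enrichment
score, a Monte-Carlo gene-permutation null for p-values and NES, the
leading-edge subset (the members at or before the running-sum peak that
drive the score), and an exact hypergeometric over-representation test for
plain gene-list enrichment.

The permutation p-value uses a pseudo-count convention,
``p = (1 + #{|ES_perm| >= |ES|, same sign}) / (1 + #same-sign perms)``,
so it is never exactly zero, and the NES divides ES by the mean magnitude
of same-sign permuted scores.  An exact-tail algorithm is deliberately not
implemented: downstream rules only need p < 0.05 calls, for which
Monte-Carlo precision at the default 1000 permutations is ample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RankedGeneList:
    """Genes strictly ordered by a real-valued score (descending).

    Ties in the score must already be broken deterministically (the DE
    module breaks them by gene identifier).
    """

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores must have equal length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranked list contains duplicate genes")
        if not np.isfinite(self.scores).all():
            raise ValidationError("ranked scores must be finite")
        if np.any(np.diff(self.scores) > 0):
            raise ValidationError("scores must be sorted descending")

    def __len__(self) -> int:
        return len(self.genes)

    def position(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics: name, description, members)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: list(members) for name, members in self.sets.items()}
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                desc = self.descriptions.get(name, "na") or "na"
                fh.write("\t".join([name, desc, *members]) + "\n")

    @classmethod
    def read_gmt(cls, path) -> "GeneSetCollection":
        sets, descriptions = {}, {}
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValidationError(
                        f"{path}: line {ln}: GMT needs name, description and "
                        f">=1 member"
                    )
                sets[parts[0]] = parts[2:]
                descriptions[parts[0]] = parts[1]
        return cls(sets, descriptions)


@dataclass
class EnrichmentResult:
    """One gene set's enrichment against one ranked list."""

    name: str
    size: int
    es: float
    nes: float
    pvalue: float
    padj: float
    direction: str  # "up" | "down", the sign of NES/ES
    leading_edge: list[str] = field(default_factory=list)


def _hit_weights(scores: np.ndarray, hit_pos: np.ndarray, weight: float) -> np.ndarray:
    w = np.abs(scores[hit_pos]) ** weight
    total = w.sum()
    if total == 0:  # all member scores zero: fall back to equal mass
        return np.full(len(hit_pos), 1.0 / len(hit_pos))
    return w / total


def enrichment_score(
    ranked: RankedGeneList, members, weight: float = 1.0
) -> tuple[float, int]:
    """Weighted running-sum enrichment score and its peak position.

    The walk gains ``|score|^weight / sum(|score|^weight over members)`` at
    each member ("hit") and loses ``1/(N - N_hit)`` at each non-member.  ES
    is the running-sum value of maximal absolute deviation; ``peak_index``
    is the 0-based rank position attaining it (first such position on ties).
    """
    pos = ranked.position()
    hit_pos = np.sort([pos[g] for g in set(members) if g in pos])
    n = len(ranked)
    if len(hit_pos) == 0:
        raise ValidationError("gene set has no members in the ranked universe")
    if len(hit_pos) >= n:
        raise ValidationError("gene set covers the whole ranked universe")

    delta = np.full(n, -1.0 / (n - len(hit_pos)))
    delta[hit_pos] = _hit_weights(ranked.scores, hit_pos, weight)
    running = np.cumsum(delta)
    # first position attaining the maximal deviation, with a small
    # tolerance so accumulated rounding cannot flip the tie convention
    dev = np.abs(running)
    peak = int(np.argmax(dev >= dev.max() - 1e-12))
    return float(running[peak]), peak


def leading_edge(ranked: RankedGeneList, members, es: float, peak_index: int) -> list[str]:
    """Members on the peak side of the walk, in rank order.

    For ES > 0: members at ranks <= peak_index; for ES < 0: members at
    ranks >= peak_index.  ES == 0 yields an empty subset with a warning.
    """
    if es == 0:
        logger.warning("leading_edge: ES is 0; returning empty subset")
        return []
    pos = ranked.position()
    member_pos = sorted((pos[g], g) for g in set(members) if g in pos)
    if es > 0:
        return [g for p, g in member_pos if p <= peak_index]
    return [g for p, g in member_pos if p >= peak_index]


def _permutation_es(
    scores: np.ndarray, k: int, n_perm: int, weight: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """ES of ``n_perm`` random k-member sets, vectorized over permutations.

    Candidate extrema of the running sum occur only immediately after a hit
    (local maxima) or immediately before one (local minima), so only hit
    positions are needed.
    """
    n = len(scores)
    # random k-subsets per row: k smallest of a uniform row
    u = rng.random((n_perm, n))
    hit = np.sort(np.argpartition(u, k - 1, axis=1)[:, :k], axis=1)
    w = np.abs(scores[hit]) ** weight
    totals = w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    h_cum = np.cumsum(w / totals, axis=1)
    miss = 1.0 / (n - k)
    j = np.arange(k)[None, :]
    after = h_cum - (hit - j) * miss          # value just after each hit
    before = after - w / totals               # value just before each hit
    cand = np.concatenate([after, before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_perm), idx]


def preranked_gsea(
    ranked: RankedGeneList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    weight: float = 1.0,
    min_size: int = 2,
) -> list[EnrichmentResult]:
    """Pre-ranked GSEA over a collection with gene-permutation inference.

    Sets are intersected with the ranked universe; sets smaller than
    ``min_size`` (or covering the universe) after intersection are skipped
    with a log entry.  Deterministic under a fixed seed.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    universe = set(ranked.genes)
    n = len(ranked)

    raw: list[EnrichmentResult] = []
    for name in collection.names():
        members = [g for g in collection[name] if g in universe]
        if len(set(members)) < min_size or len(set(members)) >= n:
            logger.info("preranked_gsea: skipping %r (size %d after universe "
                        "intersection)", name, len(set(members)))
            continue
        es, peak = enrichment_score(ranked, members, weight)
        perm = _permutation_es(ranked.scores, len(set(members)), n_perm, weight, rng)
        if es == 0:
            raw.append(EnrichmentResult(name, len(set(members)), 0.0, 0.0,
                                        1.0, 1.0, "up", []))
            continue
        same_sign = perm[np.sign(perm) == np.sign(es)]
        extreme = int(np.sum(np.abs(same_sign) >= abs(es)))
        pvalue = (1 + extreme) / (1 + len(same_sign))
        nes = es / np.mean(np.abs(same_sign)) if len(same_sign) else np.nan
        raw.append(EnrichmentResult(
            name, len(set(members)), es, float(nes), float(pvalue), np.nan,
            "up" if es > 0 else "down",
            leading_edge(ranked, members, es, peak),
        ))

    if raw:
        padj = multipletests([r.pvalue for r in raw], method="fdr_bh")[1]
        for r, q in zip(raw, padj):
            r.padj = float(q)
    return raw


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flatten results to the interoperable enrichment table layout."""
    return pd.DataFrame({
        "pathway": [r.name for r in results],
        "size": [r.size for r in results],
        "ES": [r.es for r in results],
        "NES": [r.nes for r in results],
        "pval": [r.pvalue for r in results],
        "padj": [r.padj for r in results],
        "leadingEdge": [",".join(r.leading_edge) for r in results],
    })


def frame_to_results(frame: pd.DataFrame) -> list[EnrichmentResult]:
    out = []
    for row in frame.itertuples(index=False):
        le = [] if (not isinstance(row.leadingEdge, str) or not row.leadingEdge) \
            else row.leadingEdge.split(",")
        out.append(EnrichmentResult(
            row.pathway, int(row.size), float(row.ES), float(row.NES),
            float(row.pval), float(row.padj),
            "up" if row.ES > 0 else "down", le,
        ))
    return out


def ora_hypergeometric(query, collection: GeneSetCollection, universe) -> pd.DataFrame:
    """Over-representation of a gene list in each set: exact upper
    hypergeometric tail of the observed overlap, BH-adjusted."""
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValidationError("query gene set is empty")
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    n_universe = len(universe)
    rows = []
    for name in collection.names():
        members = set(collection[name]) & universe
        if not members:
            continue
        overlap = len(query & members)
        p = stats.hypergeom.sf(overlap - 1, n_universe, len(members), len(query))
        rows.append((name, overlap, len(members), float(p)))
    table = pd.DataFrame(rows, columns=["set", "overlap", "size", "p"])
    if len(table):
        table["padj"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["padj"] = []
    return table
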