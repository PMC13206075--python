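"""Cross-dataset consensus pathways and core leading-edge genes.

A pathway becomes a *consensus pathway* when it is significantly enriched
(p < alpha) with the same direction of regulation in at least a stated
fraction of the K datasets (the >=50% rule gives a minimum support of
ceil(0.5 * K), e.g. 4 of 7).  Within the datasets where a consensus
pathway was significant, each leading-edge gene's occurrence frequency is
computed; genes exceeding 0.5 (strictly) for any consensus pathway are the
*core leading-edge genes*.  Aggregation is by counting only — no
effect-size meta-analysis is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .containers import ValidationError
from .enrichment import EnrichmentResult

logger = logging.getLogger(__name__)


@dataclass
class ConsensusPathway:
    name: str
    direction: str  # "up" | "down"
    support: int
    n_datasets: int
    contributing_datasets: list[str]


def min_support(n_datasets: int, min_frac: float) -> int:
    """Minimum number of supporting datasets for the 'at least min_frac'
    rule: ceil(min_frac * K)."""
    return math.ceil(min_frac * n_datasets)


def consensus_pathways(
    results: dict[str, list[EnrichmentResult]],
    alpha: float = 0.05,
    min_frac: float = 0.5,
) -> list[ConsensusPathway]:
    """Pathways significant with a consistent direction in enough datasets.

    ``results`` maps dataset name -> enrichment results.  For each pathway
    and direction the number of datasets with p < alpha and that NES sign
    is counted; a (pathway, direction) is emitted when the count reaches
    ``ceil(min_frac * K)``.  A pathway is never emitted in both directions:
    the direction with the larger count wins, and an exact tie emits
    neither (logged).
    """
    if not results:
        raise ValidationError("no enrichment results supplied")
    k = len(results)
    threshold = min_support(k, min_frac)

    support: dict[tuple[str, str], list[str]] = {}
    for dataset, res in results.items():
        for r in res:
            if r.pvalue < alpha and r.es != 0:
                support.setdefault((r.name, r.direction), []).append(dataset)

    out: list[ConsensusPathway] = []
    for name in sorted({name for name, _ in support}):
        up = support.get((name, "up"), [])
        down = support.get((name, "down"), [])
        if len(up) == len(down) and len(up) >= threshold:
            logger.warning("consensus_pathways: %r tied %d up vs %d down; "
                           "emitting neither", name, len(up), len(down))
            continue
        direction, datasets = max((("up", up), ("down", down)),
                                  key=lambda t: len(t[1]))
        if len(datasets) >= threshold:
            out.append(ConsensusPathway(name, direction, len(datasets), k,
                                        sorted(datasets)))
    return out


def leading_edge_frequency(
    consensus: list[ConsensusPathway],
    results: dict[str, list[EnrichmentResult]],
) -> pd.DataFrame:
    """Occurrence frequency of each leading-edge gene.

    For each (consensus pathway, gene): frequency = number of contributing
    datasets where the gene is in that pathway's leading edge, divided by
    the number of datasets where the pathway was significant in the
    consensus direction.  Per gene the maximum frequency over its pathways
    is reported (a gene is core if core for ANY consensus pathway); all
    source pathways are listed.
    """
    if not consensus:
        raise ValidationError("consensus pathway list is empty")
    by_dataset = {
        d: {r.name: r for r in res} for d, res in results.items()
    }
    per_gene: dict[str, dict] = {}
    for cp in consensus:
        counts: dict[str, int] = {}
        for d in cp.contributing_datasets:
            r = by_dataset[d].get(cp.name)
            if r is None:
                continue
            for g in r.leading_edge:
                counts[g] = counts.get(g, 0) + 1
        denom = len(cp.contributing_datasets)
        for g, c in counts.items():
            freq = c / denom
            rec = per_gene.setdefault(
                g, {"frequency": 0.0, "n_contributing": 0, "pathways": []})
            rec["pathways"].append(cp.name)
            if freq > rec["frequency"]:
                rec["frequency"] = freq
                rec["n_contributing"] = c

    rows = [
        (g, rec["frequency"], rec["n_contributing"], ",".join(sorted(rec["pathways"])))
        for g, rec in sorted(per_gene.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "frequency", "n_contributing",
                                       "pathways"]).set_index("gene", drop=False).rename_axis(None)


def core_leading_edge_genes(table: pd.DataFrame, min_freq: float = 0.5) -> set[str]:
    """Genes with occurrence frequency strictly greater than ``min_freq``."""
    return set(table.loc[table["frequency"] > min_freq, "gene"])


def consensus_to_frame(consensus: list[ConsensusPathway]) -> pd.DataFrame:
    return pd.DataFrame({
        "pathway": [c.name for c in consensus],
        "direction": [c.direction for c in consensus],
        "support": [c.support for c in consensus],
        "K": [c.n_datasets for c in consensus],
        "datasets": [",".join(c.contributing_datasets) for c in consensus],
    })
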