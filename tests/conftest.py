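import numpy as np
import pandas as pd
import pytest

from dedtarget import CountMatrix, SimulationConfig


@pytest.fixture
def toy_counts() -> CountMatrix:
    """4 genes x 4 samples with hand-set counts, 2 per group."""
    counts = pd.DataFrame(
        [[10, 20, 30, 40],
         [100, 200, 300, 400],
         [5, 10, 15, 20],
         [50, 100, 150, 200]],
        index=["GA", "GB", "GC", "GD"],
        columns=["c1", "c2", "t1", "t2"],
    )
    groups = {"c1": "control", "c2": "control",
              "t1": "treatment", "t2": "treatment"}
    return CountMatrix(counts, groups)


@pytest.fixture
def small_config() -> SimulationConfig:
    """Desk-scale simulation: 3 datasets, 400 genes, 4 planted sets."""
    return SimulationConfig(n_datasets=3, n_genes=400, n_gene_sets=12,
                            n_active_sets=4, consensus_support=2, seed=42)


@pytest.fixture
def docking_rows() -> pd.DataFrame:
    """The published teriflunomide docking affinities, written out here
    independently of the packaged copy."""
    return pd.DataFrame({
        "target": ["CTSS", "STAT1", "PTGS1", "TOP2A", "PSMB9", "CDK1"],
        "affinity_kcal_mol": [-8.77, -7.59, -6.62, -6.00, -5.34, -4.97],
    })


def running_sum_walk(genes, scores, members, weight=1.0):
    """Independent step-by-step running-sum oracle for the enrichment
    score: literal walk down the list, no vectorization tricks."""
    members = set(members) & set(genes)
    n_hit = len(members)
    n = len(genes)
    norm = sum(abs(s) ** weight for g, s in zip(genes, scores) if g in members)
    value, best, best_i = 0.0, 0.0, 0
    for i, (g, s) in enumerate(zip(genes, scores)):
        if g in members:
            value += (abs(s) ** weight / norm) if norm > 0 else 1.0 / n_hit
        else:
            value -= 1.0 / (n - n_hit)
        if abs(value) > abs(best) + 1e-12:
            best, best_i = value, i
    return best, best_i
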