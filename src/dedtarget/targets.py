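"""Drug-target triage: symbol harmonization, intersection with core genes,
and docking-affinity filtering.

Predicted drug targets (e.g. from a reverse-docking server) and core
leading-edge genes may come from different species conventions (mouse
``Ctss`` vs human ``CTSS``); symbols are harmonized to an uppercase
canonical form before intersection.  Docked targets are triaged with a
strict binding-energy cutoff (default < -6.5 kcal/mol, a common moderate
virtual-screening threshold).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ValidationError

logger = logging.getLogger(__name__)


def harmonize_symbols(genes) -> tuple[list[str], dict[str, str]]:
    """Uppercase-canonical symbols, preserving input order.

    Returns the unique canonical list plus a sidecar map from canonical to
    the first original casing seen.  Duplicates after harmonization are
    collapsed with a warning.  No orthology mapping is attempted — casing
    only.
    """
    canonical: list[str] = []
    sidecar: dict[str, str] = {}
    for g in genes:
        up = str(g).upper()
        if up in sidecar:
            logger.warning("harmonize_symbols: %r collapses onto %r", g,
                           sidecar[up])
            continue
        canonical.append(up)
        sidecar[up] = str(g)
    return canonical, sidecar


def intersect_targets(targets, core_genes) -> list[str]:
    """Predicted targets that are also core leading-edge genes.

    Both inputs are expected harmonized; the intersection is returned in
    deterministic lexicographic order.  An empty intersection is a valid
    (logged) outcome, not an error.
    """
    result = sorted(set(targets) & set(core_genes))
    if not result:
        logger.info("intersect_targets: empty intersection")
    return result


def filter_by_affinity(table: pd.DataFrame, threshold: float = -6.5) -> pd.DataFrame:
    """Docked targets with binding affinity strictly below ``threshold``
    kcal/mol, sorted ascending (strongest binder first).

    ``table`` needs columns ``target`` and ``affinity_kcal_mol``.
    """
    if table.empty:
        raise ValidationError("docking table is empty")
    for col in ("target", "affinity_kcal_mol"):
        if col not in table.columns:
            raise ValidationError(f"docking table lacks column {col!r}")
    aff = pd.to_numeric(table["affinity_kcal_mol"])
    if not np.isfinite(aff).all():
        raise ValidationError("affinities must be finite")
    if table["target"].duplicated().any():
        raise ValidationError("docking table has duplicate targets")
    kept = table.loc[aff < threshold].copy()
    kept["affinity_kcal_mol"] = aff[aff < threshold]
    return kept.sort_values("affinity_kcal_mol", kind="mergesort").reset_index(drop=True)


def read_target_list(path) -> list[str]:
    """One symbol per line (or first TSV column); blank lines ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            sym = line.strip().split("\t")[0]
            if sym and sym.lower() not in ("gene", "target", "symbol"):
                out.append(sym)
    if not out:
        raise ValidationError(f"{path}: no symbols found")
    return out


def read_docking_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if "affinity_kcal_mol" not in table.columns and len(table.columns) == 2:
        table.columns = ["target", "affinity_kcal_mol"]
    return table
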