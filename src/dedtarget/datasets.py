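"""Small published input tables shipped with the package.

These are *inputs* consumed by the triage stage (as produced upstream by a
docking engine), not quantities this package computes.
"""

from __future__ import annotations

import pandas as pd


def teriflunomide_docking_table() -> pd.DataFrame:
    """AutoDock-Vina binding affinities (kcal/mol) of teriflunomide against
    the six core dry-eye-disease target proteins."""
    return pd.DataFrame({
        "target": ["CTSS", "STAT1", "PTGS1", "TOP2A", "PSMB9", "CDK1"],
        "affinity_kcal_mol": [-8.77, -7.59, -6.62, -6.00, -5.34, -4.97],
    })
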