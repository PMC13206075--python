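"""Core data containers shared across the pipeline.

The unit of one transcriptomic dataset is a :class:`CountMatrix`: an integer
gene-by-sample count table plus a two-level group factor (control vs
treatment).  Counts are stored as a :class:`pandas.DataFrame` so the rest of
the pipeline can lean on pandas alignment semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
TREATMENT = "treatment"


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class CountMatrix:
    """Integer gene x sample counts with a two-level group factor.

    Parameters
    ----------
    counts
        DataFrame indexed by unique gene identifiers, columns are unique
        sample identifiers, values are non-negative integers.
    groups
        Mapping ``sample -> {"control", "treatment"}`` covering every column.
    name
        Optional dataset label (used in logs and multi-dataset outputs).
    """

    counts: pd.DataFrame
    groups: dict[str, str]
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.groups = dict(self.groups)
        self.validate()

    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError("gene identifiers must be unique")
        if c.columns.has_duplicates:
            raise ValidationError("sample identifiers must be unique")
        arr = c.to_numpy()
        if arr.size == 0:
            raise ValidationError("count matrix is empty")
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integral")
        missing = [s for s in c.columns if s not in self.groups]
        if missing:
            raise ValidationError(f"samples missing a group label: {missing}")
        levels = {self.groups[s] for s in c.columns}
        if not levels <= {CONTROL, TREATMENT}:
            raise ValidationError(
                f"group labels must be '{CONTROL}' or '{TREATMENT}', got {levels}"
            )
        for level in (CONTROL, TREATMENT):
            if len(self.samples_in(level)) < 2:
                raise ValidationError(
                    f"group '{level}' needs at least 2 samples"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, level: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == level]

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.groups, self.name)

    # ------------------------------------------------------------------ IO
    def to_tsv(self, counts_path, groups_path) -> None:
        """Write counts as gene x sample TSV and a two-column group sidecar."""
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        pd.Series(
            {s: self.groups[s] for s in self.counts.columns}, name="group"
        ).rename_axis("sample").to_csv(groups_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, groups_path, name: str = "dataset") -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"].to_dict()
        return cls(counts, groups, name=name)


@dataclass
class PerturbationProfile:
    """Genome-wide log2 fold-change response to one perturbation.

    ``label`` is ``"drug"`` for the drug-treatment profile or ``"KD:<gene>"``
    for a single-gene knockdown.  Values are finite log2FCs over a fixed gene
    universe; profiles that are compared must share that universe.
    """

    label: str
    log2fc: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.log2fc = pd.Series(self.log2fc, dtype=float)
        if self.log2fc.index.has_duplicates:
            raise ValidationError(f"profile {self.label!r}: duplicate genes")
        if not np.isfinite(self.log2fc.to_numpy()).all():
            raise ValidationError(f"profile {self.label!r}: non-finite log2FC")

    @property
    def genes(self) -> pd.Index:
        return self.log2fc.index

    def to_tsv(self, path) -> None:
        self.log2fc.rename("log2FC").rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, label: str) -> "PerturbationProfile":
        s = pd.read_csv(path, sep="\t", index_col=0)["log2FC"]
        return cls(label, s)
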