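"""Core domain records shared across the pipeline.

Coordinates are uniformly 0-based half-open (BED convention) in memory;
format converters in :mod:`teboot.io` handle 1-based inclusive GFF3/GTF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The four transposable-element classes distinguished by the analysis.
TE_CLASSES = ("DNA", "ERV/LTR", "LINE", "SINE")

#: TE age groups: species-specific (recent, high identity) vs non-species-specific.
AGE_GROUPS = ("ss", "ns")

#: Percent-identity threshold above which (inclusive) an insertion counts as
#: species-specific / recently active.
SS_IDENTITY_THRESHOLD = 94.0


class ValidationError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(ValidationError):
    """Invalid configuration value; the message names the offending field."""


@dataclass(frozen=True)
class GeneModel:
    """One gene's genomic extent: the unit of intersection and sampling."""

    gene_id: str
    species: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "."  # '+', '-', or '.' for unknown
    is_ortholog: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TEInsertion:
    """One TE interval with class and percent identity to its consensus."""

    chrom: str
    start: int
    end: int
    te_class: str
    percent_identity: float
    species: str
    family: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"TE on {self.chrom}: start {self.start} >= end {self.end}"
            )
        if self.te_class not in TE_CLASSES:
            raise ValidationError(
                f"unknown TE class {self.te_class!r}; expected one of {TE_CLASSES}"
            )
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )


def validate_genes(genes: list[GeneModel]) -> None:
    """Reject duplicate gene IDs within a species."""
    seen: set[tuple[str, str]] = set()
    for g in genes:
        key = (g.species, g.gene_id)
        if key in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r} in {g.species}")
        seen.add(key)


@dataclass
class ExpressionTable:
    """Genes x samples TPM matrix with per-sample (species, tissue) metadata.

    ``values`` rows are gene IDs, columns are sample IDs. Entries may be NaN
    for genes not assayed in a sample (e.g. a gene of another species in a
    multi-species table); present values must be non-negative TPM.
    ``sample_meta`` is indexed by sample ID with at least ``species`` and
    ``tissue`` columns (``study`` optional).
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    flagged_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample IDs in expression matrix")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate gene IDs in expression matrix")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(
                f"samples missing from metadata: {sorted(missing)}"
            )
        for col in ("species", "tissue"):
            if col not in self.sample_meta.columns:
                raise ValidationError(f"sample metadata lacks a {col!r} column")
            if self.sample_meta[col].isna().any():
                raise ValidationError(f"sample metadata has missing {col!r} values")
        vals = self.values.to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0:
            raise ValidationError("negative TPM values in expression matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, species: str, tissue: str) -> list[str]:
        """Sample IDs measured in a given species and tissue."""
        meta = self.sample_meta
        mask = (meta["species"] == species) & (meta["tissue"] == tissue)
        return [s for s in self.values.columns if s in meta.index[mask]]

    def column(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.columns:
            raise ValidationError(f"unknown sample {sample_id!r}")
        return self.values[sample_id]


@dataclass
class OrthologTable:
    """Single-copy ortholog groups: one gene per species per group.

    ``table`` is indexed by group ID with one column per species holding the
    member gene ID (NaN when the species is missing from the group — the
    group is kept but flagged incomplete).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate ortholog group IDs")
        for sp in self.table.columns:
            members = self.table[sp].dropna()
            if members.duplicated().any():
                dup = members[members.duplicated()].iloc[0]
                raise ValidationError(
                    f"gene {dup!r} appears in more than one group for {sp}"
                )

    @property
    def species(self) -> list[str]:
        return list(self.table.columns)

    @property
    def group_ids(self) -> list[str]:
        return list(self.table.index)

    def incomplete_groups(self) -> list[str]:
        """Groups missing one or more species."""
        mask = self.table.isna().any(axis=1)
        return list(self.table.index[mask])

    def genes_of(self, species: str) -> set[str]:
        if species not in self.table.columns:
            return set()
        return set(self.table[species].dropna())
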