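"""Gene-TE intersection and per-gene TE composition profiles.

Genes are extended by a symmetric flank (1 kb by default, covering the
upstream and downstream regulatory neighbourhood), intersected with TE
insertions under half-open ≥1 bp overlap semantics, and each insertion is
age-classified as species-specific (ss, percent identity at or above the
threshold) or non-species-specific (ns). The result is one
:class:`GeneTEProfile` per gene: presence and counts per (TE class, age
group), a gene-length decile bin, and a canonical composition key — the
covariate record that drives the matched bootstrap sampling weights.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .models import (
    AGE_GROUPS,
    SS_IDENTITY_THRESHOLD,
    TE_CLASSES,
    GeneModel,
    TEInsertion,
    ValidationError,
)

GeneInterval = namedtuple("GeneInterval", ["gene_id", "chrom", "start", "end"])

#: All (class, age) element keys, in canonical order.
ELEMENT_KEYS: tuple[tuple[str, str], ...] = tuple(
    (c, a) for c in TE_CLASSES for a in AGE_GROUPS
)


def classify_te_age(
    te: TEInsertion, threshold: float = SS_IDENTITY_THRESHOLD
) -> str:
    """Age-classify an insertion: 'ss' iff identity >= threshold, else 'ns'."""
    return "ss" if te.percent_identity >= threshold else "ns"


def flank_genes(genes: list[GeneModel], flank: int = 1000) -> list[GeneInterval]:
    """Extend every gene by ``flank`` bp on both sides, clipping at zero.

    Flanking is strand-agnostic: upstream and downstream extensions are the
    same length so the symmetric interval covers both readings.
    """
    if flank < 0:
        raise ValidationError(f"flank must be >= 0, got {flank}")
    return [
        GeneInterval(g.gene_id, g.chrom, max(0, g.start - flank), g.end + flank)
        for g in genes
    ]


def intersect(
    gene_intervals: list[GeneInterval], tes: list[TEInsertion]
) -> dict[str, list[TEInsertion]]:
    """Map each gene to the TE insertions overlapping its (flanked) extent.

    Overlap requires >= 1 shared bp under half-open semantics
    (``te.start < gene.end and gene.start < te.end``) on the same
    chromosome; one TE may hit several overlapping genes. TE chromosomes
    with no annotated gene raise a warning, not an error.
    """
    trees: dict[str, IntervalTree] = {}
    result: dict[str, list[TEInsertion]] = {gi.gene_id: [] for gi in gene_intervals}
    for gi in gene_intervals:
        trees.setdefault(gi.chrom, IntervalTree()).addi(gi.start, gi.end, gi.gene_id)
    orphan_chroms = set()
    for te in tes:
        tree = trees.get(te.chrom)
        if tree is None:
            orphan_chroms.add(te.chrom)
            continue
        for hit in tree.overlap(te.start, te.end):
            result[hit.data].append(te)
    if orphan_chroms:
        warnings.warn(
            f"TE chromosomes absent from gene annotation: {sorted(orphan_chroms)}",
            stacklevel=2,
        )
    return result


def assign_length_bins(genes: list[GeneModel], n_bins: int = 10) -> dict[str, int]:
    """Equal-frequency gene-length bins (deciles for the default 10).

    Genes are ranked by (length, gene_id) — the ID breaks ties stably — and
    split into ``n_bins`` contiguous rank groups of near-equal size. With all
    lengths identical the notion of a length decile collapses: every gene is
    assigned bin 1 and a warning is emitted.
    """
    if not genes:
        raise ValidationError("cannot bin an empty gene list")
    if n_bins < 1:
        raise ValidationError(f"n_bins must be >= 1, got {n_bins}")
    lengths = {g.gene_id: g.length for g in genes}
    if len(set(lengths.values())) == 1:
        warnings.warn("all gene lengths equal; a single length bin is used",
                      stacklevel=2)
        return {gid: 1 for gid in lengths}
    order = sorted(lengths, key=lambda gid: (lengths[gid], gid))
    n = len(order)
    return {gid: int(rank * n_bins // n) + 1 for rank, gid in enumerate(order)}


@dataclass
class GeneTEProfile:
    """Per-gene TE composition: the covariate record for matched sampling."""

    gene_id: str
    species: str
    gene_length: int  # flanks excluded
    length_bin: int
    te_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    is_ortholog: bool = False

    @property
    def presence(self) -> dict[tuple[str, str], bool]:
        return {k: self.te_counts.get(k, 0) >= 1 for k in ELEMENT_KEYS}

    def has(self, element: tuple[str, str]) -> bool:
        return self.te_counts.get(element, 0) >= 1

    @property
    def is_te_free(self) -> bool:
        return not any(v >= 1 for v in self.te_counts.values())

    def composition_key(self, exclude: tuple[str, str] | None = None) -> str:
        """Canonical string for the set of elements present plus length bin.

        ``exclude`` removes the focal element so that test and reference
        genes are compared on their *other* TE content.
        """
        parts = sorted(
            f"{c}:{a}"
            for (c, a), n in self.te_counts.items()
            if n >= 1 and (c, a) != exclude
        )
        return ("+".join(parts) if parts else "-") + f"|bin{self.length_bin:02d}"

    def matching_key(self, focal: tuple[str, str]) -> str:
        """Covariate stratum for the weighted bootstrap: the combination of
        co-occurring TE types plus the length bin.

        Co-occurrence is recorded per TE class (any age) for the classes
        other than the focal one; for the focal class itself, presence at
        the *other* age group is kept as a covariate (it is exactly the
        old-vs-recent confound the comparison must not absorb). This is
        deliberately coarser than :meth:`composition_key`: matching on full
        age-resolved multisets fragments realistic pools into hundreds of
        sparse strata and starves the weighted draw.
        """
        focal_class, focal_age = focal
        parts = []
        for c in TE_CLASSES:
            if c == focal_class:
                other = "ns" if focal_age == "ss" else "ss"
                if self.te_counts.get((c, other), 0) >= 1:
                    parts.append(f"{c}:{other}")
            else:
                if any(self.te_counts.get((c, a), 0) >= 1 for a in AGE_GROUPS):
                    parts.append(c)
        return ("+".join(sorted(parts)) if parts else "-") + \
            f"|bin{self.length_bin:02d}"


def build_profiles(
    genes: list[GeneModel],
    te_map: dict[str, list[TEInsertion]],
    n_bins: int = 10,
    identity_threshold: float = SS_IDENTITY_THRESHOLD,
) -> list[GeneTEProfile]:
    """One profile per gene; genes with no overlapping TE get empty presence."""
    bins = assign_length_bins(genes, n_bins=n_bins)
    profiles = []
    for g in genes:
        counts: dict[tuple[str, str], int] = {}
        for te in te_map.get(g.gene_id, []):
            key = (te.te_class, classify_te_age(te, identity_threshold))
            counts[key] = counts.get(key, 0) + 1
        profiles.append(
            GeneTEProfile(
                gene_id=g.gene_id,
                species=g.species,
                gene_length=g.length,
                length_bin=bins[g.gene_id],
                te_counts=counts,
                is_ortholog=g.is_ortholog,
            )
        )
    return profiles


@dataclass
class GeneSetPair:
    """Test pool (genes carrying the focal element) vs reference pool (genes
    lacking it) within one gene universe of one species.

    A gene carrying the focal class at *both* ages belongs to the test pool
    of either age's comparison: the reference is "all genes without that
    (class, age) element", mirroring a ssTE-vs-(nsTE + TE-free) contrast.
    """

    focal: tuple[str, str]
    species: str
    universe: str  # 'ortholog' or 'non_ortholog'
    test_pool: list[GeneTEProfile]
    reference_pool: list[GeneTEProfile]
    usable: bool = True

    @property
    def n_test(self) -> int:
        return len(self.test_pool)

    @property
    def n_reference(self) -> int:
        return len(self.reference_pool)


def build_gene_set_pair(
    profiles: list[GeneTEProfile],
    focal: tuple[str, str],
    universe: str,
) -> GeneSetPair:
    """Split a universe's profiles by presence of the focal (class, age).

    ``profiles`` must already be restricted to one species and one universe
    (ortholog or non-ortholog genes).
    """
    if focal[0] not in TE_CLASSES or focal[1] not in AGE_GROUPS:
        raise ValidationError(f"bad focal element {focal!r}")
    species = profiles[0].species if profiles else "unknown"
    test = [p for p in profiles if p.has(focal)]
    ref = [p for p in profiles if not p.has(focal)]
    return GeneSetPair(
        focal=focal,
        species=species,
        universe=universe,
        test_pool=test,
        reference_pool=ref,
        usable=bool(test),
    )


# ---------------------------------------------------------------------------
# Tabular form
# ---------------------------------------------------------------------------

def profiles_to_frame(profiles: list[GeneTEProfile]) -> pd.DataFrame:
    """Flatten profiles to a TSV-ready table: one 0/1 presence column and one
    count column per (class, age) element."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "gene_id": p.gene_id,
            "species": p.species,
            "gene_length": p.gene_length,
            "length_bin": p.length_bin,
            "is_ortholog": int(p.is_ortholog),
        }
        for c, a in ELEMENT_KEYS:
            tag = f"{c.replace('/', '_')}_{a}"
            row[f"has_{tag}"] = int(p.has((c, a)))
            row[f"n_{tag}"] = p.te_counts.get((c, a), 0)
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_from_frame(df: pd.DataFrame) -> list[GeneTEProfile]:
    profiles = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        counts = {}
        for c, a in ELEMENT_KEYS:
            n = int(d.get(f"n_{c.replace('/', '_')}_{a}", 0))
            if n:
                counts[(c, a)] = n
        profiles.append(
            GeneTEProfile(
                gene_id=str(d["gene_id"]),
                species=str(d["species"]),
                gene_length=int(d["gene_length"]),
                length_bin=int(d["length_bin"]),
                te_counts=counts,
                is_ortholog=bool(d["is_ortholog"]),
            )
        )
    return profiles
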