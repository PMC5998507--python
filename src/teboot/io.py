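"""Readers and writers for gene annotations, TE annotations, expression and
ortholog tables.

All readers validate on load and return the in-memory records of
:mod:`teboot.models` with 0-based half-open coordinates. GFF3/GTF input
(1-based inclusive) is converted on read and back-converted on write; BED is
taken as-is. Every tabular reader accepts gzip-compressed files.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pyranges as pr
import yaml

from .models import (
    TE_CLASSES,
    ExpressionTable,
    GeneModel,
    OrthologTable,
    TEInsertion,
    ValidationError,
    validate_genes,
)

# Mapping from common repeat-annotation labels to the four analysis classes.
# Users can extend/override it with a YAML alias file (label -> class).
DEFAULT_TE_ALIASES: dict[str, str] = {
    "DNA": "DNA",
    "DNA transposon": "DNA",
    "TIR": "DNA",
    "ERV": "ERV/LTR",
    "LTR": "ERV/LTR",
    "ERV/LTR": "ERV/LTR",
    "LINE": "LINE",
    "L1": "LINE",
    "L2": "LINE",
    "CR1": "LINE",
    "SINE": "SINE",
    "Alu": "SINE",
    "MIR": "SINE",
    "Retroposon": "SINE",
}

_TE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "family",
    "score",
    "strand",
    "te_class",
    "percent_identity",
]


def load_alias_table(path: str | Path) -> dict[str, str]:
    """Load a user-supplied TE-class alias table (YAML mapping label -> class)."""
    with open(path) as fh:
        aliases = yaml.safe_load(fh) or {}
    if not isinstance(aliases, dict):
        raise ValidationError(f"alias table {path} is not a mapping")
    bad = {v for v in aliases.values() if v not in TE_CLASSES}
    if bad:
        raise ValidationError(f"alias table maps to unknown TE classes: {sorted(bad)}")
    return {**DEFAULT_TE_ALIASES, **aliases}


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

def read_genes(
    path: str | Path,
    format: str = "gff3",
    species: str = "unknown",
    ortholog_ids: set[str] | None = None,
) -> list[GeneModel]:
    """Read gene models from GFF3, GTF or BED.

    GFF3/GTF: only features of type ``gene`` are kept; the gene ID is taken
    from the ``ID`` (GFF3) or ``gene_id`` (GTF) attribute. Coordinates are
    converted to 0-based half-open. ``ortholog_ids``, if given, flags genes
    that belong to the ortholog universe.
    """
    path = Path(path)
    fmt = format.lower()
    try:
        if fmt == "gff3":
            df = pr.read_gff3(str(path)).df
            if not df.empty:
                df = df[df["Feature"] == "gene"]
            id_col = "ID"
        elif fmt == "gtf":
            df = pr.read_gtf(str(path)).df
            if not df.empty:
                df = df[df["Feature"] == "gene"]
            id_col = "gene_id"
        elif fmt == "bed":
            df = pr.read_bed(str(path)).df
            id_col = "Name"
        else:
            raise ValidationError(f"unknown gene annotation format {format!r}")
    except ValidationError:
        raise
    except Exception as exc:  # pyranges/pandas parse failure
        raise ValidationError(f"cannot parse {path} as {format}: {exc}") from exc
    if df.empty:
        return []
    if id_col not in df.columns:
        raise ValidationError(f"{path}: no {id_col!r} attribute on gene features")
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        start, end = int(d["Start"]), int(d["End"])
        if end <= start:
            raise ValidationError(f"{path} record {i}: end {end} <= start {start}")
        gid = str(d[id_col])
        genes.append(
            GeneModel(
                gene_id=gid,
                species=species,
                chrom=str(d["Chromosome"]),
                start=start,
                end=end,
                strand=d.get("Strand", ".") if d.get("Strand") in ("+", "-") else ".",
                is_ortholog=bool(ortholog_ids and gid in ortholog_ids),
            )
        )
    validate_genes(genes)
    # pyranges does not preserve file order; return a deterministic sort
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


def write_genes_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tteboot\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand if g.strand in '+-' else '.'}\t.\tID={g.gene_id}\n"
            )


def write_genes_bed(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as BED6 (0-based half-open)."""
    rows = [
        (g.chrom, g.start, g.end, g.gene_id, 0, g.strand if g.strand in "+-" else ".")
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# TE annotations
# ---------------------------------------------------------------------------

def read_te_annotation(
    path: str | Path,
    species: str = "unknown",
    aliases: dict[str, str] | None = None,
) -> list[TEInsertion]:
    """Read TE insertions from a BED6+2 TSV.

    Columns: chrom, start, end, family, score, strand, te_class,
    percent_identity (headerless, 0-based half-open). Class labels outside
    the four-class set are mapped through ``aliases`` (merged over the
    built-in defaults); unmappable labels are rejected.
    """
    alias_map = {**DEFAULT_TE_ALIASES, **(aliases or {})}
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_TE_COLUMNS,
                         comment="#", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return []
    except Exception as exc:
        raise ValidationError(f"cannot parse TE annotation {path}: {exc}") from exc
    tes = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        label = str(row.te_class)
        te_class = alias_map.get(label)
        if te_class is None:
            raise ValidationError(
                f"{path} line {i}: TE class {label!r} not in {TE_CLASSES} "
                "and no alias maps it"
            )
        ident = float(row.percent_identity)
        if not (0.0 <= ident <= 100.0):
            raise ValidationError(
                f"{path} line {i}: percent identity {ident} outside [0, 100]"
            )
        tes.append(
            TEInsertion(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                te_class=te_class,
                percent_identity=ident,
                species=species,
                family=str(row.family),
            )
        )
    return tes


def write_te_annotation(tes: list[TEInsertion], path: str | Path) -> None:
    rows = [
        (t.chrom, t.start, t.end, t.family, 0, ".", t.te_class, t.percent_identity)
        for t in tes
    ]
    pd.DataFrame(rows, columns=_TE_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    meta_path: str | Path,
    known_genes: set[str] | None = None,
) -> ExpressionTable:
    """Read a TPM matrix (first column gene_id) and its sample metadata TSV.

    Genes absent from ``known_genes`` (if given) are retained but listed in
    ``flagged_genes``. Missing entries (empty cells) are allowed and kept as
    NaN; present values must be non-negative.
    """
    try:
        values = pd.read_csv(path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise ValidationError(f"cannot parse expression input: {exc}") from exc
    values.index = values.index.astype(str)
    flagged = (
        [g for g in values.index if g not in known_genes] if known_genes else []
    )
    if flagged:
        warnings.warn(
            f"{len(flagged)} expression genes absent from the gene annotation",
            stacklevel=2,
        )
    return ExpressionTable(values=values.astype(float), sample_meta=meta,
                           flagged_genes=flagged)


def write_expression(expr: ExpressionTable, path: str | Path,
                     meta_path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")
    expr.sample_meta.to_csv(meta_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Orthologs
# ---------------------------------------------------------------------------

def read_orthologs(path: str | Path) -> OrthologTable:
    """Read an ortholog table TSV (first column group_id, one column per species)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:
        raise ValidationError(f"cannot parse ortholog table {path}: {exc}") from exc
    table = OrthologTable(table=df)
    incomplete = table.incomplete_groups()
    if incomplete:
        warnings.warn(
            f"{len(incomplete)} ortholog groups missing one or more species",
            stacklevel=2,
        )
    return table


def write_orthologs(orthologs: OrthologTable, path: str | Path) -> None:
    orthologs.table.to_csv(path, sep="\t", index_label="group_id")


# ---------------------------------------------------------------------------
# Profiles and results (tabular pipeline interchange)
# ---------------------------------------------------------------------------

def write_profiles(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "species", "gene_length", "length_bin", "is_ortholog"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"profile table {path} lacks columns {sorted(missing)}")
    return df


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
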