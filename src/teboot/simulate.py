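"""Synthetic multi-species gene/TE/expression datasets with planted effects.

The generator emulates the structure the downstream analysis assumes:

* genes with a broad (log-normal) length distribution laid out without
  overlap on a handful of chromosomes, separated by intergenic gaps wide
  enough that 1 kb flanks of neighbours never touch;
* TE insertions of the four classes (DNA, ERV/LTR, LINE, SINE) dropped into
  gene bodies ± flank, with per-insertion percent identity straddling the
  94% species-specificity boundary, plus intergenic background insertions;
* strong co-occurrence of TE classes within genes, via a per-gene gamma
  frailty multiplying all class rates — most genes carry several TEs, only
  a minority exactly one, very few none;
* log-normal-like TPM expression per (species, tissue) sample with shared
  per-gene baselines and tissue effects (so samples cluster by tissue),
  exact zeros at a dropout rate, and optional planted additive shifts on
  log2(TPM) for genes carrying a chosen (TE class, age group) element.

The planted truth is recorded per gene so recovery can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from .intersect import build_profiles, flank_genes, intersect
from .models import (
    AGE_GROUPS,
    TE_CLASSES,
    ConfigurationError,
    ExpressionTable,
    GeneModel,
    OrthologTable,
    TEInsertion,
)

# TE insertion length ranges (bp) per class: SINEs short, LINEs long and
# often 5'-truncated, LTR/DNA elements in between.
TE_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "DNA": (200, 1500),
    "ERV/LTR": (300, 3000),
    "LINE": (500, 6000),
    "SINE": (100, 400),
}


@dataclass(frozen=True)
class PlantedEffect:
    """Additive shift ``delta`` on log2(TPM) for genes of ``species`` carrying
    the (te_class, age_group) element, applied in ``tissue``."""

    species: str
    tissue: str
    te_class: str
    age_group: str
    delta: float


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 6000
    n_chromosomes: int = 5
    # log-normal gene length parameters (of log length in bp)
    gene_length_mean_log: float = 9.2
    gene_length_sd_log: float = 0.9
    te_class_rates: dict[str, float] = field(
        default_factory=lambda: {"DNA": 0.6, "ERV/LTR": 1.0, "LINE": 1.8,
                                 "SINE": 1.6}
    )
    ss_fraction: float = 0.3
    identity_range_ss: tuple[float, float] = (94.0, 100.0)
    identity_range_ns: tuple[float, float] = (50.0, 94.0)
    cooccurrence_dispersion: float = 1.5  # variance/mean of per-gene TE counts
    intergenic_te_rate: float = 1.0  # background insertions per gene equivalent
    tissues: tuple[str, ...] = ("brain", "heart", "kidney", "liver", "testis",
                                "ovary")
    species: tuple[str, ...] = ("chicken", "anole", "pogona", "platypus",
                                "opossum", "human")
    baseline_log2tpm_mean: float = 3.0
    baseline_log2tpm_sd: float = 2.0
    tissue_effect_sd: float = 1.0
    species_effect_sd: float = 0.5
    noise_sd: float = 0.5
    zero_rate: float = 0.1
    ortholog_fraction: float = 0.7
    flank: int = 1000
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        if not (0.0 <= self.ss_fraction <= 1.0):
            raise ConfigurationError(
                f"ss_fraction must be in [0, 1], got {self.ss_fraction}")
        if not (0.0 <= self.zero_rate < 1.0):
            raise ConfigurationError(
                f"zero_rate must be in [0, 1), got {self.zero_rate}")
        for cls, rate in self.te_class_rates.items():
            if cls not in TE_CLASSES:
                raise ConfigurationError(f"te_class_rates: unknown class {cls!r}")
            if rate < 0:
                raise ConfigurationError(f"te_class_rates[{cls!r}] must be >= 0")
        if self.identity_range_ss[0] < 94.0 or self.identity_range_ss[1] > 100.0:
            raise ConfigurationError("identity_range_ss must lie within [94, 100]")
        if self.identity_range_ns[1] > 94.0 or self.identity_range_ns[0] < 0.0:
            raise ConfigurationError("identity_range_ns must lie within [0, 94)")
        if self.cooccurrence_dispersion < 1.0:
            raise ConfigurationError("cooccurrence_dispersion must be >= 1")
        if not (0.0 <= self.ortholog_fraction <= 1.0):
            raise ConfigurationError("ortholog_fraction must be in [0, 1]")
        if self.intergenic_te_rate < 0:
            raise ConfigurationError("intergenic_te_rate must be >= 0")
        if self.flank < 0:
            raise ConfigurationError("flank must be >= 0")
        for eff in self.planted_effects:
            if eff.te_class not in TE_CLASSES or eff.age_group not in AGE_GROUPS:
                raise ConfigurationError(f"planted_effects: bad element {eff}")
            if eff.species not in self.species or eff.tissue not in self.tissues:
                raise ConfigurationError(
                    f"planted_effects: unknown species/tissue in {eff}")


@dataclass
class SyntheticDataset:
    genes: list[GeneModel]
    te_insertions: list[TEInsertion]
    expression: ExpressionTable
    ortholog_table: OrthologTable
    truth: pd.DataFrame  # species, tissue, te_class, age_group, gene_id, delta
    config: SimulationConfig | None = None


def _gene_layout(cfg: SimulationConfig, rng: np.random.Generator,
                 species: str, ortholog_idx: set[int]) -> list[GeneModel]:
    """Place genes without overlap; gaps keep neighbouring flanks disjoint."""
    lengths = np.maximum(
        rng.lognormal(cfg.gene_length_mean_log, cfg.gene_length_sd_log,
                      cfg.n_genes).astype(np.int64),
        200,
    )
    chroms = np.arange(cfg.n_genes) % cfg.n_chromosomes
    gaps = rng.integers(2 * cfg.flank + 3000, 2 * cfg.flank + 18000,
                        size=cfg.n_genes)
    genes: list[GeneModel] = []
    cursor = {c: int(cfg.flank) + 2000 for c in range(cfg.n_chromosomes)}
    strands = rng.choice(["+", "-"], size=cfg.n_genes)
    for i in range(cfg.n_genes):
        c = int(chroms[i])
        start = cursor[c]
        end = start + int(lengths[i])
        cursor[c] = end + int(gaps[i])
        genes.append(
            GeneModel(
                gene_id=f"{species}_g{i:05d}",
                species=species,
                chrom=f"chr{c + 1}",
                start=start,
                end=end,
                strand=str(strands[i]),
                is_ortholog=i in ortholog_idx,
            )
        )
    return genes


def _draw_identity(cfg: SimulationConfig, rng: np.random.Generator) -> float:
    if rng.random() < cfg.ss_fraction:
        lo, hi = cfg.identity_range_ss
    else:
        lo, hi = cfg.identity_range_ns
    return float(rng.uniform(lo, hi))


def _place_tes(cfg: SimulationConfig, rng: np.random.Generator,
               genes: list[GeneModel], species: str) -> list[TEInsertion]:
    tes: list[TEInsertion] = []
    classes = [c for c in TE_CLASSES if cfg.te_class_rates.get(c, 0.0) > 0]
    rates = np.array([cfg.te_class_rates[c] for c in classes])
    # shared gamma frailty: mean 1, variance (dispersion - 1)
    d = cfg.cooccurrence_dispersion
    if d > 1.0:
        frailty = rng.gamma(1.0 / (d - 1.0), d - 1.0, size=len(genes))
    else:
        frailty = np.ones(len(genes))
    if classes:
        counts = rng.poisson(frailty[:, None] * rates[None, :])
        for gi, g in enumerate(genes):
            lo_pos, hi_pos = g.start - cfg.flank, g.end + cfg.flank
            for ci, c in enumerate(classes):
                for _ in range(int(counts[gi, ci])):
                    length = int(rng.integers(*TE_LENGTH_RANGES[c]))
                    start = int(rng.integers(max(0, lo_pos), hi_pos))
                    tes.append(
                        TEInsertion(
                            chrom=g.chrom, start=start, end=start + length,
                            te_class=c, percent_identity=_draw_identity(cfg, rng),
                            species=species, family=f"{c.replace('/', '_')}_fam",
                        )
                    )
    # intergenic background: placed strictly between flanked gene extents
    total_rate = float(rates.sum())
    if total_rate > 0 and cfg.intergenic_te_rate > 0:
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        gaps = []
        for glist in by_chrom.values():
            for a, b in zip(glist, glist[1:]):
                lo = a.end + cfg.flank + 1
                hi = b.start - cfg.flank - 1
                if hi - lo > 300:
                    gaps.append((a.chrom, lo, hi))
        n_bg = rng.poisson(cfg.intergenic_te_rate * len(genes))
        if gaps and n_bg:
            pick = rng.integers(0, len(gaps), size=n_bg)
            cls_pick = rng.choice(len(classes), size=n_bg, p=rates / total_rate)
            for gap_i, cls_i in zip(pick, cls_pick):
                chrom, lo, hi = gaps[gap_i]
                c = classes[cls_i]
                length = min(int(rng.integers(*TE_LENGTH_RANGES[c])), hi - lo - 1)
                start = int(rng.integers(lo, hi - length))
                tes.append(
                    TEInsertion(
                        chrom=chrom, start=start, end=start + length,
                        te_class=c, percent_identity=_draw_identity(cfg, rng),
                        species=species, family=f"{c.replace('/', '_')}_fam",
                    )
                )
    return tes


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset; same config (incl. seed) gives
    byte-identical output."""
    rng = np.random.default_rng(cfg.seed)
    n_ortho = int(round(cfg.ortholog_fraction * cfg.n_genes))
    ortho_positions = np.sort(
        rng.choice(cfg.n_genes, size=n_ortho, replace=False))
    ortho_set = set(int(i) for i in ortho_positions)

    all_genes: list[GeneModel] = []
    all_tes: list[TEInsertion] = []
    presence_by_species: dict[str, dict[tuple[str, str], np.ndarray]] = {}
    for species in cfg.species:
        genes = _gene_layout(cfg, rng, species, ortho_set)
        tes = _place_tes(cfg, rng, genes, species)
        all_genes.extend(genes)
        all_tes.extend(tes)
        # presence per (class, age), via the same flank/intersection rules
        # the pipeline applies, so the planted truth matches what the
        # analysis will see
        te_map = intersect(flank_genes(genes, cfg.flank), tes)
        profs = build_profiles(genes, te_map)
        presence_by_species[species] = {
            key: np.array([p.has(key) for p in profs])
            for key in [(c, a) for c in TE_CLASSES for a in AGE_GROUPS]
        }

    # shared per-gene structure: baselines and tissue effects are tied to the
    # gene index, which also defines orthology across species
    baseline = rng.normal(cfg.baseline_log2tpm_mean, cfg.baseline_log2tpm_sd,
                          cfg.n_genes)
    tissue_eff = rng.normal(0.0, cfg.tissue_effect_sd,
                            (cfg.n_genes, len(cfg.tissues)))
    species_eff = {
        sp: rng.normal(0.0, cfg.species_effect_sd, cfg.n_genes)
        for sp in cfg.species
    }

    sample_ids = [f"{sp}_{t}" for sp in cfg.species for t in cfg.tissues]
    meta = pd.DataFrame(
        {
            "species": [s.rsplit("_", 1)[0] for s in sample_ids],
            "tissue": [s.rsplit("_", 1)[1] for s in sample_ids],
            "study": "synthetic",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    gene_index = pd.Index([g.gene_id for g in all_genes], name="gene_id")
    values = pd.DataFrame(np.nan, index=gene_index, columns=sample_ids)

    truth_rows = []
    for sp in cfg.species:
        sp_gene_ids = [f"{sp}_g{i:05d}" for i in range(cfg.n_genes)]
        log2 = (
            baseline[:, None]
            + tissue_eff
            + species_eff[sp][:, None]
            + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, len(cfg.tissues)))
        )
        for eff in cfg.planted_effects:
            if eff.species != sp:
                continue
            carriers = presence_by_species[sp][(eff.te_class, eff.age_group)]
            t_idx = cfg.tissues.index(eff.tissue)
            log2[carriers, t_idx] += eff.delta
            for i in np.nonzero(carriers)[0]:
                truth_rows.append(
                    (sp, eff.tissue, eff.te_class, eff.age_group,
                     sp_gene_ids[i], eff.delta)
                )
        tpm = np.exp2(log2)
        if cfg.zero_rate > 0:
            tpm[rng.random(tpm.shape) < cfg.zero_rate] = 0.0
        cols = [f"{sp}_{t}" for t in cfg.tissues]
        values.loc[sp_gene_ids, cols] = tpm

    truth = pd.DataFrame(
        truth_rows,
        columns=["species", "tissue", "te_class", "age_group", "gene_id",
                 "delta"],
    )
    ortho_table = pd.DataFrame(
        {
            sp: [f"{sp}_g{i:05d}" for i in ortho_positions]
            for sp in cfg.species
        },
        index=pd.Index([f"OG{j:06d}" for j in range(n_ortho)],
                       name="group_id"),
    )
    return SyntheticDataset(
        genes=all_genes,
        te_insertions=all_tes,
        expression=ExpressionTable(values=values, sample_meta=meta),
        ortholog_table=OrthologTable(table=ortho_table),
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# On-disk form
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as GFF3/BED/TSV files; returns the file manifest.

    Output round-trips losslessly through the :mod:`teboot.io` readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    species_list = sorted({g.species for g in ds.genes}) or ["none"]
    for sp in species_list:
        sp_genes = [g for g in ds.genes if g.species == sp]
        sp_tes = [t for t in ds.te_insertions if t.species == sp]
        gff = out / f"genes_{sp}.gff3"
        bed = out / f"genes_{sp}.bed"
        tebed = out / f"tes_{sp}.tsv"
        tio.write_genes_gff3(sp_genes, gff)
        tio.write_genes_bed(sp_genes, bed)
        tio.write_te_annotation(sp_tes, tebed)
        manifest[f"genes_gff3_{sp}"] = gff
        manifest[f"genes_bed_{sp}"] = bed
        manifest[f"tes_{sp}"] = tebed
    manifest["expression"] = out / "expression.tsv"
    manifest["samples"] = out / "samples.tsv"
    tio.write_expression(ds.expression, manifest["expression"],
                         manifest["samples"])
    manifest["orthologs"] = out / "orthologs.tsv"
    tio.write_orthologs(ds.ortholog_table, manifest["orthologs"])
    manifest["truth"] = out / "truth.tsv"
    ds.truth.to_csv(manifest["truth"], sep="\t", index=False)
    return manifest


def read_dataset(out_dir: str | Path) -> SyntheticDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    out = Path(out_dir)
    orthologs = tio.read_orthologs(out / "orthologs.tsv")
    genes: list[GeneModel] = []
    tes: list[TEInsertion] = []
    for gff in sorted(out.glob("genes_*.gff3")):
        sp = gff.stem.removeprefix("genes_")
        genes.extend(
            tio.read_genes(gff, format="gff3", species=sp,
                           ortholog_ids=orthologs.genes_of(sp))
        )
        tes.extend(tio.read_te_annotation(out / f"tes_{sp}.tsv", species=sp))
    expr = tio.read_expression(out / "expression.tsv", out / "samples.tsv",
                               known_genes={g.gene_id for g in genes})
    truth = pd.read_csv(out / "truth.tsv", sep="\t")
    return SyntheticDataset(
        genes=genes, te_insertions=tes, expression=expr,
        ortholog_table=orthologs, truth=truth,
    )
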