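"""Composition- and length-matched weighted bootstrap of expression differences.

The question: does carrying a particular TE element — a (class, age-group)
pair such as a species-specific SINE — associate with a shift in gene
expression? Genes carry many co-occurring TE classes, so a naive
carrier-vs-non-carrier comparison conflates them. The weighted bootstrap
isolates one element:

* the *test* set is drawn uniformly with replacement from genes carrying the
  focal element;
* the *reference* set is drawn with replacement from genes lacking it, with
  per-gene weights chosen so that the reference draw reproduces the test
  pool's joint distribution of *other* TE elements and gene-length decile.

Each of B iterations yields two statistics: the difference in median
log2(TPM) among expressed genes (zero-TPM genes omitted), and the difference
in the proportion of genes detected as expressed (zeros kept). Percentile
confidence intervals are taken at level 1 - alpha/m, where m is the number
of tests in the family (tissues x elements), so that the family-wise error
rate is controlled at alpha. Two-sided p-values are the smallest percentile
level at which the interval touches zero, and Benjamini-Hochberg FDR is
computed across each family's p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .intersect import GeneSetPair, GeneTEProfile, build_gene_set_pair
from .models import (
    AGE_GROUPS,
    TE_CLASSES,
    ConfigurationError,
    ExpressionTable,
    ValidationError,
)

STATISTICS = ("median_diff", "prop_diff")


@dataclass(frozen=True)
class BootstrapConfig:
    """Tuning knobs of the weighted bootstrap.

    Defaults follow the standard protocol: sets of 1000 genes, a 600-gene
    minimum pool, 5000 iterations, alpha = 0.05 with m = tissues x elements
    tests per family.
    """

    n_genes_per_set: int = 1000
    min_pool: int = 600
    n_iterations: int = 5000
    alpha: float = 0.05
    m: int | None = None  # tests in the family; computed by the sweep if None
    expressed_threshold: float = 0.0  # TPM strictly above this counts as expressed
    seed: int = 0
    with_replacement: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.min_pool > self.n_genes_per_set:
            raise ConfigurationError(
                f"min_pool ({self.min_pool}) exceeds n_genes_per_set "
                f"({self.n_genes_per_set})"
            )
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        if self.m is not None and self.m < 1:
            raise ConfigurationError("m must be >= 1")


@dataclass
class StatisticSummary:
    """Bootstrap summary of one statistic."""

    estimate: float  # mean of iteration statistics
    estimate_median: float  # median of iteration statistics
    ci_low: float
    ci_high: float
    p_value: float
    n_iter_used: int


@dataclass
class BootstrapResult:
    """Outcome of one (species, tissue, element, universe) test."""

    focal: tuple[str, str]
    species: str
    tissue: str
    universe: str
    status: str  # 'ok' or 'skipped_small_pool'
    n_test_pool: int
    n_ref_pool: int
    n_sampled: int = 0
    statistics: dict[str, StatisticSummary] = field(default_factory=dict)
    fdr: dict[str, float] = field(default_factory=dict)
    dropped_strata: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Sampling weights
# ---------------------------------------------------------------------------

def compute_sampling_weights(
    test_pool: list[GeneTEProfile],
    reference_pool: list[GeneTEProfile],
    focal: tuple[str, str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Per-gene reference weights matching the test pool's covariate strata.

    A stratum is the combination of co-occurring TE types (see
    :meth:`GeneTEProfile.matching_key`) and gene-length bin. A reference
    gene in stratum ``s`` gets weight
    proportional to ``f_test(s) / f_ref(s)`` — the ratio of stratum
    frequencies — so that weighted reference draws reproduce the test pool's
    stratum distribution in expectation. Strata present in the test pool but
    absent from the reference cannot be matched: they are dropped from the
    target distribution (which is renormalized) and returned for logging.
    Reference genes in strata no test gene occupies get weight zero.

    Returns weights aligned with ``reference_pool`` order, summing to 1.
    """
    if not reference_pool:
        raise ValidationError("reference pool is empty")
    if not test_pool:
        raise ValidationError("test pool is empty")
    if focal is None:
        raise ValidationError("a focal element is required to define strata")
    test_keys = [p.matching_key(focal) for p in test_pool]
    ref_keys = [p.matching_key(focal) for p in reference_pool]
    f_test = pd.Series(test_keys).value_counts(normalize=True)
    n_ref = pd.Series(ref_keys).value_counts()
    dropped = sorted(set(f_test.index) - set(n_ref.index))
    matchable = f_test.drop(index=dropped)
    if matchable.empty:
        raise ValidationError("no matchable strata between test and reference pools")
    # weight of one gene in stratum s: f_test(s) / n_ref(s); per-stratum mass
    # then sums to f_test(s), and normalization renormalizes over dropped strata.
    per_gene = (matchable / n_ref.reindex(matchable.index)).to_dict()
    weights = np.array([per_gene.get(k, 0.0) for k in ref_keys], dtype=float)
    weights /= weights.sum()
    return weights, dropped


class _AliasSampler:
    """Walker alias method: O(1) vectorized draws from a discrete distribution."""

    def __init__(self, weights: np.ndarray):
        p = np.asarray(weights, dtype=float)
        if p.min() < 0 or not np.isclose(p.sum(), 1.0):
            p = p / p.sum()
        K = len(p)
        q = p * K
        alias = np.zeros(K, dtype=np.int64)
        small = [i for i in range(K) if q[i] < 1.0]
        large = [i for i in range(K) if q[i] >= 1.0]
        while small and large:
            s, l = small.pop(), large.pop()
            alias[s] = l
            q[l] -= 1.0 - q[s]
            (small if q[l] < 1.0 else large).append(l)
        self.K, self.q, self.alias = K, np.clip(q, 0.0, 1.0), alias

    def draw(self, rng: np.random.Generator, size) -> np.ndarray:
        k = rng.integers(0, self.K, size=size)
        u = rng.random(size=size)
        return np.where(u < self.q[k], k, self.alias[k])


def _draw_indices(
    rng: np.random.Generator,
    n_pool: int,
    shape: tuple[int, int],
    weights: np.ndarray | None,
    with_replacement: bool,
) -> np.ndarray:
    if with_replacement:
        if weights is None:
            return rng.integers(0, n_pool, size=shape)
        return _AliasSampler(weights).draw(rng, shape)
    # Efraimidis-Spirakis exponential-key sampling without replacement.
    B, n = shape
    w = np.ones(n_pool) if weights is None else np.asarray(weights, dtype=float)
    keys = rng.exponential(size=(B, n_pool)) / np.where(w > 0, w, np.nan)
    return np.argpartition(keys, n - 1, axis=1)[:, :n]


def draw_matched_sets(
    pair: GeneSetPair,
    weights: np.ndarray,
    cfg: BootstrapConfig,
    rng: np.random.Generator,
) -> tuple[list[str], list[str]] | None:
    """One bootstrap draw: (test gene IDs, matched reference gene IDs).

    Both sets have size ``min(cfg.n_genes_per_set, pool sizes)``; the test
    set is drawn uniformly, the reference set with the matching weights.
    Returns None (a skip signal, not an exception) when either pool is
    smaller than ``cfg.min_pool``.
    """
    if min(pair.n_test, pair.n_reference) < cfg.min_pool:
        return None
    n = min(cfg.n_genes_per_set, pair.n_test, pair.n_reference)
    ti = _draw_indices(rng, pair.n_test, (1, n), None, cfg.with_replacement)[0]
    ri = _draw_indices(rng, pair.n_reference, (1, n), weights, cfg.with_replacement)[0]
    return (
        [pair.test_pool[i].gene_id for i in ti],
        [pair.reference_pool[i].gene_id for i in ri],
    )


# ---------------------------------------------------------------------------
# Iteration statistics
# ---------------------------------------------------------------------------

def _pool_tpm(expr: ExpressionTable, sample_id: str, gene_ids: list[str]) -> np.ndarray:
    col = expr.column(sample_id)
    vals = col.reindex(gene_ids).to_numpy(dtype=float)
    if np.isnan(vals).any():
        missing = [g for g, v in zip(gene_ids, vals) if np.isnan(v)]
        raise ValidationError(
            f"sample {sample_id!r} lacks expression for {len(missing)} pool genes "
            f"(e.g. {missing[:3]})"
        )
    return vals


def iteration_statistics(
    test_sample: list[str],
    reference_sample: list[str],
    expr: ExpressionTable,
    sample_id: str,
    cfg: BootstrapConfig,
) -> tuple[float, float]:
    """(median log2(TPM) difference, proportion-expressed difference).

    The median difference omits zero-TPM genes from each set independently
    (NaN if a whole set is unexpressed); the proportion difference keeps all
    sampled genes. Both are test minus reference.
    """
    t = _pool_tpm(expr, sample_id, test_sample)
    r = _pool_tpm(expr, sample_id, reference_sample)
    med = _median_log2_positive(t[None, :])[0] - _median_log2_positive(r[None, :])[0]
    thr = cfg.expressed_threshold
    prop = float((t > thr).mean() - (r > thr).mean())
    return float(med), prop


def _median_log2_positive(V: np.ndarray) -> np.ndarray:
    """Row-wise median of log2(TPM) over strictly positive entries.

    Rows with no positive entry give NaN. Vectorized via a sort with +inf
    placeholders, equivalent to ``np.nanmedian`` but faster on wide arrays.
    """
    logs = np.where(V > 0, V, np.nan)
    np.log2(logs, out=logs, where=~np.isnan(logs))
    k = (~np.isnan(logs)).sum(axis=1)
    S = np.sort(np.where(np.isnan(logs), np.inf, logs), axis=1)
    med = np.full(V.shape[0], np.nan)
    ok = np.nonzero(k > 0)[0]
    lo, hi = (k[ok] - 1) // 2, k[ok] // 2
    med[ok] = 0.5 * (S[ok, lo] + S[ok, hi])
    return med


# ---------------------------------------------------------------------------
# Interval estimation and p-values
# ---------------------------------------------------------------------------

def ci_from_bootstrap(
    stats: np.ndarray, alpha: float, m: int
) -> tuple[float, float]:
    """Percentile CI at level 1 - alpha/m: empirical quantiles at alpha/(2m)
    and 1 - alpha/(2m), with linear interpolation between order statistics.

    With fewer than 1/(alpha/(2m)) usable values the tail quantile is beyond
    the sample and the CI degenerates to (min, max); a width warning is
    raised for the caller's log.
    """
    vals = np.asarray(stats, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ValidationError("need at least 2 non-missing bootstrap statistics")
    tail = alpha / (2.0 * m)
    if len(vals) < 1.0 / tail:
        import warnings

        warnings.warn(
            f"only {len(vals)} bootstrap values for tail level {tail:.2e}; "
            "CI truncated to the sample range",
            stacklevel=2,
        )
        return float(vals.min()), float(vals.max())
    lo, hi = np.quantile(vals, [tail, 1.0 - tail])
    return float(lo), float(hi)


def pvalue_from_bootstrap(stats: np.ndarray) -> float:
    """Two-sided p: the smallest percentile level at which the CI crosses zero.

    Computed as ``2 * min((#{<=0}+1, #{>=0}+1)) / (B+1)``, capped at 1; the
    add-one continuity correction keeps p strictly positive. Ties at exactly
    zero count on both sides.
    """
    vals = np.asarray(stats, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValidationError("no non-missing bootstrap statistics")
    B = len(vals)
    n_le = int((vals <= 0).sum())
    n_ge = int((vals >= 0).sum())
    p = 2.0 * min(n_le + 1, n_ge + 1) / (B + 1)
    return float(min(p, 1.0))


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def log2_change_to_percent(d: float) -> float:
    """Convert a log2 expression change into a percent change: 100*(2^d - 1)."""
    return 100.0 * (2.0 ** d - 1.0)


# ---------------------------------------------------------------------------
# The bootstrap proper
# ---------------------------------------------------------------------------

def run_bootstrap(
    pair: GeneSetPair,
    expr: ExpressionTable,
    sample_id: str,
    cfg: BootstrapConfig,
    rng: np.random.Generator | None = None,
    weights: np.ndarray | None = None,
    dropped_strata: list[str] | None = None,
    tissue: str | None = None,
) -> BootstrapResult:
    """Run B matched bootstrap iterations for one test.

    Skips (status ``skipped_small_pool``, no statistics) when either pool is
    below ``cfg.min_pool``. Deterministic given ``cfg.seed`` (or a caller
    rng). ``weights`` may be precomputed once per gene-set pair and shared
    across tissues.
    """
    if tissue is None:
        tissue = str(expr.sample_meta.loc[sample_id, "tissue"]) \
            if sample_id in expr.sample_meta.index else "unknown"
    base = BootstrapResult(
        focal=pair.focal,
        species=pair.species,
        tissue=tissue,
        universe=pair.universe,
        status="skipped_small_pool",
        n_test_pool=pair.n_test,
        n_ref_pool=pair.n_reference,
    )
    if min(pair.n_test, pair.n_reference) < cfg.min_pool:
        return base
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if weights is None:
        weights, dropped_strata = compute_sampling_weights(
            pair.test_pool, pair.reference_pool, focal=pair.focal
        )
    m = cfg.m if cfg.m is not None else 1
    B = cfg.n_iterations
    n = min(cfg.n_genes_per_set, pair.n_test, pair.n_reference)

    test_vals = _pool_tpm(expr, sample_id, [p.gene_id for p in pair.test_pool])
    ref_vals = _pool_tpm(expr, sample_id, [p.gene_id for p in pair.reference_pool])

    ti = _draw_indices(rng, pair.n_test, (B, n), None, cfg.with_replacement)
    ri = _draw_indices(rng, pair.n_reference, (B, n), weights, cfg.with_replacement)
    TV, RV = test_vals[ti], ref_vals[ri]

    med_diff = _median_log2_positive(TV) - _median_log2_positive(RV)
    thr = cfg.expressed_threshold
    prop_diff = (TV > thr).mean(axis=1) - (RV > thr).mean(axis=1)

    base.status = "ok"
    base.n_sampled = n
    base.dropped_strata = list(dropped_strata or [])
    for name, vals in (("median_diff", med_diff), ("prop_diff", prop_diff)):
        usable = vals[~np.isnan(vals)]
        lo, hi = ci_from_bootstrap(usable, cfg.alpha, m)
        base.statistics[name] = StatisticSummary(
            estimate=float(usable.mean()),
            estimate_median=float(np.median(usable)),
            ci_low=lo,
            ci_high=hi,
            p_value=pvalue_from_bootstrap(usable),
            n_iter_used=int(len(usable)),
        )
    return base


def _mean_tpm_column(expr: ExpressionTable, species: str, tissue: str) -> str | None:
    """Pick the sample for (species, tissue); average replicates if several."""
    samples = expr.samples_for(species, tissue)
    if not samples:
        return None
    if len(samples) == 1:
        return samples[0]
    pooled = f"__pooled__{species}__{tissue}"
    if pooled not in expr.values.columns:
        expr.values[pooled] = expr.values[samples].mean(axis=1)
        expr.sample_meta.loc[pooled] = expr.sample_meta.loc[samples[0]]
    return pooled


def run_family(
    profiles: list[GeneTEProfile],
    expr: ExpressionTable,
    species: str,
    universe: str,
    age_group: str,
    cfg: BootstrapConfig,
    te_classes: tuple[str, ...] = TE_CLASSES,
    tissues: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> list[BootstrapResult]:
    """All tests of one family: every (TE class, tissue) at a fixed species,
    universe and age group, with m = n_tissues * n_classes and BH-FDR across
    the family's p-values (per statistic).
    """
    if age_group not in AGE_GROUPS:
        raise ConfigurationError(f"age_group must be one of {AGE_GROUPS}")
    if tissues is None:
        meta = expr.sample_meta
        tissues = sorted(meta.loc[meta["species"] == species, "tissue"].unique())
    if not tissues:
        return []
    m = cfg.m if cfg.m is not None else len(tissues) * len(te_classes)
    fam_cfg = replace(cfg, m=m)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    results: list[BootstrapResult] = []
    for te_class in te_classes:
        pair = build_gene_set_pair(profiles, (te_class, age_group), universe)
        weights = dropped = None
        if min(pair.n_test, pair.n_reference) >= cfg.min_pool:
            weights, dropped = compute_sampling_weights(
                pair.test_pool, pair.reference_pool, focal=pair.focal
            )
        for tissue in tissues:
            sample_id = _mean_tpm_column(expr, species, tissue)
            if sample_id is None:
                results.append(
                    BootstrapResult(
                        focal=pair.focal, species=species, tissue=tissue,
                        universe=universe, status="skipped_no_sample",
                        n_test_pool=pair.n_test, n_ref_pool=pair.n_reference,
                    )
                )
                continue
            results.append(
                run_bootstrap(pair, expr, sample_id, fam_cfg, rng=rng,
                              weights=weights, dropped_strata=dropped,
                              tissue=tissue)
            )
    _attach_fdr(results)
    return results


def _attach_fdr(results: list[BootstrapResult]) -> None:
    ok = [r for r in results if r.status == "ok"]
    for stat in STATISTICS:
        q = adjust_bh([r.statistics[stat].p_value for r in ok])
        for r, qi in zip(ok, q):
            r.fdr[stat] = float(qi)


def run_all(
    profiles: list[GeneTEProfile],
    expr: ExpressionTable,
    cfg: BootstrapConfig,
    universes: tuple[str, ...] = ("ortholog", "non_ortholog"),
    age_groups: tuple[str, ...] = AGE_GROUPS,
) -> pd.DataFrame:
    """Full sweep over species x universe x age group families.

    Child RNG streams are derived deterministically per family from
    ``cfg.seed`` so the sweep is reproducible and order-independent.
    """
    all_species = sorted({p.species for p in profiles})
    results: list[BootstrapResult] = []
    for si, species in enumerate(all_species):
        sp_profiles = [p for p in profiles if p.species == species]
        for ui, universe in enumerate(universes):
            subset = [
                p for p in sp_profiles
                if p.is_ortholog == (universe == "ortholog")
            ]
            for ai, age in enumerate(age_groups):
                child = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=cfg.seed, spawn_key=(si, ui, ai)
                    )
                )
                if not subset:
                    continue
                results.extend(
                    run_family(subset, expr, species, universe, age, cfg,
                               rng=child)
                )
    return results_to_frame(results)


def results_to_frame(results: list[BootstrapResult]) -> pd.DataFrame:
    """Flatten results: one row per test per statistic."""
    rows = []
    for r in results:
        for stat in STATISTICS:
            row = {
                "species": r.species,
                "tissue": r.tissue,
                "universe": r.universe,
                "te_class": r.focal[0],
                "age_group": r.focal[1],
                "statistic": stat,
                "status": r.status,
                "n_test": r.n_test_pool,
                "n_ref": r.n_ref_pool,
                "n_sampled": r.n_sampled,
            }
            s = r.statistics.get(stat)
            row.update(
                estimate=s.estimate if s else np.nan,
                estimate_median=s.estimate_median if s else np.nan,
                ci_low=s.ci_low if s else np.nan,
                ci_high=s.ci_high if s else np.nan,
                p=s.p_value if s else np.nan,
                fdr=r.fdr.get(stat, np.nan),
                n_iter_used=s.n_iter_used if s else 0,
                n_dropped_strata=len(r.dropped_strata),
            )
            rows.append(row)
    return pd.DataFrame(rows)
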