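"""Significance heatmap and clustering figures.

The heatmap summarizes every (species, tissue, TE class, age) comparison of
one gene universe: red cells mark significantly increased expression in
carrier genes, blue significantly decreased, white not significant, grey
comparisons that were skipped (pool below the minimum, or no sample).
Significance defaults to the family-wise CI rule (the 1 - alpha/m interval
excludes zero); an FDR-threshold rule is available instead.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from matplotlib.colors import ListedColormap  # noqa: E402
from matplotlib.patches import Patch  # noqa: E402
from scipy.cluster import hierarchy  # noqa: E402

from .models import ValidationError  # noqa: E402

#: cell codes
UP, DOWN, NOT_SIG = 1, -1, 0  # skipped cells are NaN


def significance_grid(
    results: pd.DataFrame,
    statistic: str = "median_diff",
    universe: str = "ortholog",
    rule: str = "ci",
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Code each comparison cell: +1 up / -1 down / 0 ns / NaN skipped.

    Rows are tissues; columns are (species, te_class, age_group). ``rule``
    is ``ci`` (CI excludes zero at the family-wise level) or ``fdr``
    (BH-adjusted p below ``fdr_threshold``, direction from the estimate).
    """
    df = results[
        (results["statistic"] == statistic) & (results["universe"] == universe)
    ].copy()
    if df.empty:
        raise ValidationError(f"no results for {statistic!r} / {universe!r}")

    def code(row) -> float:
        if row["status"] != "ok":
            return np.nan
        if rule == "ci":
            if row["ci_low"] > 0:
                return UP
            if row["ci_high"] < 0:
                return DOWN
            return NOT_SIG
        if rule == "fdr":
            if row["fdr"] < fdr_threshold:
                return UP if row["estimate"] > 0 else DOWN
            return NOT_SIG
        raise ValidationError(f"unknown significance rule {rule!r}")

    df["code"] = df.apply(code, axis=1)
    grid = df.pivot_table(
        index="tissue",
        columns=["species", "te_class", "age_group"],
        values="code",
        dropna=False,
        aggfunc="first",
    )
    return grid


def render_heatmap(
    results: pd.DataFrame,
    statistic: str = "median_diff",
    universe: str = "ortholog",
    rule: str = "ci",
    fdr_threshold: float = 0.05,
    ax: plt.Axes | None = None,
) -> plt.Figure:
    """Render the significance grid as a colored cell matrix."""
    grid = significance_grid(results, statistic=statistic, universe=universe,
                             rule=rule, fdr_threshold=fdr_threshold)
    if ax is None:
        fig, ax = plt.subplots(
            figsize=(max(4.0, 0.45 * grid.shape[1] + 2), 0.5 * grid.shape[0] + 2)
        )
    else:
        fig = ax.figure
    data = grid.to_numpy(dtype=float)
    # -1 -> blue, 0 -> white, 1 -> red; NaN (skipped) -> grey
    cmap = ListedColormap(["#2166ac", "#ffffff", "#b2182b"])
    cmap.set_bad("#bdbdbd")
    ax.imshow(np.ma.masked_invalid(data), cmap=cmap, vmin=-1, vmax=1,
              aspect="auto", interpolation="none")
    ax.set_xticks(range(grid.shape[1]))
    ax.set_xticklabels(
        ["\n".join(map(str, c)) for c in grid.columns], fontsize=7, rotation=90
    )
    ax.set_yticks(range(grid.shape[0]))
    ax.set_yticklabels(grid.index, fontsize=8)
    ax.set_title(f"{universe} genes: {statistic} ({rule} rule)")
    ax.legend(
        handles=[
            Patch(color="#b2182b", label="significant increase"),
            Patch(color="#2166ac", label="significant decrease"),
            Patch(color="#ffffff", ec="#999999", label="not significant"),
            Patch(color="#bdbdbd", label="no comparison"),
        ],
        loc="upper left",
        bbox_to_anchor=(1.01, 1.0),
        fontsize=7,
    )
    fig.tight_layout()
    return fig


def render_dendrogram(result, sample_ids: list[str]) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(max(4.0, 0.3 * len(sample_ids)), 4))
    hierarchy.dendrogram(result.linkage, labels=sample_ids, ax=ax,
                         leaf_font_size=7)
    ax.set_title(f"{result.method} (k = {result.k})")
    ax.set_ylabel("height")
    fig.tight_layout()
    return fig


def render_pca(coords: pd.DataFrame, variance_fractions,
               meta: pd.DataFrame | None = None) -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 5))
    if meta is not None and "tissue" in meta.columns:
        for tissue, sub in coords.groupby(meta.loc[coords.index, "tissue"]):
            ax.scatter(sub["PC1"], sub["PC2"], label=tissue, s=30)
        ax.legend(fontsize=7)
    else:
        ax.scatter(coords["PC1"], coords["PC2"], s=30)
    ax.set_xlabel(f"PC1 ({100 * variance_fractions[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * variance_fractions[1]:.1f}%)"
                  if len(variance_fractions) > 1 else "PC2")
    fig.tight_layout()
    return fig
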