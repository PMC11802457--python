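"""Normalization, variable-gene selection, module scoring and marker ranking.

The module score is the per-cell mean log-normalized expression of a gene
set minus the mean over expression-bin-matched control genes: genes are cut
into equal-frequency bins by mean expression, and each set gene draws its
controls from its own bin, so the score is centred at zero for a set with no
signal beyond its expression level.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, GeneSet, ParameterError

__all__ = [
    "ModuleScoreResult",
    "log_normalize",
    "select_hvgs",
    "module_score",
    "rank_markers",
    "pseudobulk_by_group",
]

log = logging.getLogger("nichetrack")


def log_normalize(m: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Attach the lognorm layer: ``ln(1 + count * scale_factor / cell_total)``.

    Cells with zero total counts get an all-zero column and a warning.
    Returns ``m`` (modified in place) for chaining.
    """
    counts = m.counts
    totals = np.asarray(counts.sum(axis=0)).ravel()
    zero = totals == 0
    if zero.any():
        log.warning("%d cells have zero total counts; lognorm set to 0", int(zero.sum()))
    safe = np.where(zero, 1.0, totals)
    dense = counts.toarray().astype(float)
    m.lognorm = np.log1p(dense * (scale_factor / safe)[None, :])
    return m


def _expected_log_variance(log_mean: np.ndarray, log_var: np.ndarray, span: float) -> np.ndarray:
    """Lowess trend of log10 variance on log10 mean, evaluated per gene."""
    if np.unique(log_mean).size < 2:
        return np.full_like(log_var, log_var.mean())
    fitted = lowess(
        log_var, log_mean, frac=span, it=2, return_sorted=False
    )
    # lowess can emit NaN at extreme x when weights vanish; fall back to nearest
    if np.isnan(fitted).any():
        order = np.argsort(log_mean)
        good = ~np.isnan(fitted)
        fitted[~good] = np.interp(
            log_mean[~good], log_mean[order][good[order]], fitted[order][good[order]]
        )
    return fitted


def select_hvgs(m: ExpressionMatrix, n: int, span: float = 0.3) -> list[str]:
    """Top-``n`` highly variable genes by clipped standardized variance.

    The expected variance at a gene's mean comes from a lowess fit of log10
    variance on log10 mean over the raw counts; standardized values are
    clipped at ``sqrt(n_cells)`` before the variance is recomputed (the
    variance-stabilizing selection used for 5,000-gene panels). Constant
    genes score 0 and rank last; ties break by gene id. If ``n`` is at least
    the number of genes, all genes are returned in rank order.
    """
    if m.n_cells < 2:
        raise ParameterError("need at least 2 cells to select variable genes")
    if n < 1:
        raise ParameterError("n must be >= 1")
    X = m.counts.toarray().astype(float)
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    score = np.zeros(m.n_genes)
    informative = (var > 0) & (mean > 0)
    if informative.any():
        lm = np.log10(mean[informative])
        lv = np.log10(var[informative])
        exp_sd = np.sqrt(10.0 ** _expected_log_variance(lm, lv, span))
        clip = np.sqrt(m.n_cells)
        Z = (X[informative] - mean[informative][:, None]) / exp_sd[:, None]
        Z = np.clip(Z, -clip, clip)
        score[informative] = (Z**2).sum(axis=1) / (m.n_cells - 1)
    order = sorted(range(m.n_genes), key=lambda i: (-score[i], m.gene_ids[i]))
    return [m.gene_ids[i] for i in order[: min(n, m.n_genes)]]


@dataclass
class ModuleScoreResult:
    """Per-cell module score with the control-gene assignment that produced it."""

    scores: pd.Series  # indexed by cell id
    gene_set: str
    controls: dict[str, list[str]]  # set gene -> sampled control genes
    n_bins: int
    seed: int


def module_score(
    m: ExpressionMatrix,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Binned-control module score per cell.

    Protocol (deterministic given the seed, invariant to gene/cell order):

    1. Rank all genes by (mean lognorm across cells, gene id) and cut the
       ranking into ``n_bins`` equal-frequency bins.
    2. For each set gene present in the matrix, in sorted gene-id order,
       draw ``n_ctrl`` controls from its bin excluding the gene itself —
       without replacement when the bin is large enough, with replacement
       otherwise.
    3. score(cell) = mean lognorm over set genes - mean lognorm over the
       pooled control draws (with multiplicity).
    """
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    ln = m.require_lognorm()
    gene_pos = {g: i for i, g in enumerate(m.gene_ids)}
    present = sorted(g for g in gene_set.genes if g in gene_pos)
    if not present:
        raise ParameterError(f"no gene of set {gene_set.name!r} present in the matrix")

    means = ln.mean(axis=1)
    ranked = sorted(range(m.n_genes), key=lambda i: (means[i], m.gene_ids[i]))
    bin_of = np.empty(m.n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(np.asarray(ranked), n_bins)):
        bin_of[chunk] = b
    bins: dict[int, list[int]] = {}
    for i in ranked:
        bins.setdefault(bin_of[i], []).append(i)

    rng = np.random.default_rng(seed)
    controls: dict[str, list[str]] = {}
    ctrl_rows: list[int] = []
    for g in present:
        gi = gene_pos[g]
        pool = [j for j in bins[bin_of[gi]] if j != gi]
        if not pool:
            raise ParameterError(
                f"bin of gene {g!r} holds no control candidates; lower n_bins"
            )
        replace = len(pool) < n_ctrl
        draw = rng.choice(len(pool), size=n_ctrl, replace=replace)
        chosen = [pool[int(k)] for k in draw]
        controls[g] = [m.gene_ids[j] for j in chosen]
        ctrl_rows.extend(chosen)

    set_mean = ln[[gene_pos[g] for g in present], :].mean(axis=0)
    ctrl_mean = ln[ctrl_rows, :].mean(axis=0)
    scores = pd.Series(set_mean - ctrl_mean, index=pd.Index(m.cell_ids, name="cell_id"))
    return ModuleScoreResult(
        scores=scores, gene_set=gene_set.name, controls=controls, n_bins=n_bins, seed=seed
    )


def rank_markers(
    m: ExpressionMatrix,
    labels,
    alpha: float = 0.05,
    lfc_min: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest rank-sum marker table, BH-corrected within each group.

    ``labels`` is a per-cell label vector or the name of a ``cell_meta``
    column. ``avg_log2fc = log2((mean expm1 in + 1) / (mean expm1 out + 1))``;
    only rows with ``p_adj < alpha`` and ``avg_log2fc > lfc_min`` are kept,
    ordered by avg_log2fc descending within group.
    """
    ln = m.require_lognorm()
    if isinstance(labels, str):
        labels = m.cell_meta[labels]
    labels = np.asarray(labels, dtype=object)
    groups = sorted(set(labels))
    if len(groups) < 2:
        raise ParameterError("need at least 2 groups for marker ranking")
    small = [g for g in groups if (labels == g).sum() < 3]
    if small:
        raise ParameterError(f"groups with fewer than 3 cells: {small}")

    expm1 = np.expm1(ln)
    rows = []
    for g in groups:
        mask = labels == g
        x_in, x_out = ln[:, mask], ln[:, ~mask]
        res = stats.mannwhitneyu(
            x_in, x_out, axis=1, alternative="two-sided", method="asymptotic"
        )
        p = np.asarray(res.pvalue)
        constant = ln.min(axis=1) == ln.max(axis=1)
        p[constant] = 1.0
        p_adj = multipletests(p, method="fdr_bh")[1]
        lfc = np.log2((expm1[:, mask].mean(axis=1) + 1) / (expm1[:, ~mask].mean(axis=1) + 1))
        keep = (p_adj < alpha) & (lfc > lfc_min)
        sub = pd.DataFrame(
            {
                "gene": np.asarray(m.gene_ids)[keep],
                "group": g,
                "avg_log2fc": lfc[keep],
                "p": p[keep],
                "p_adj": p_adj[keep],
            }
        ).sort_values("avg_log2fc", ascending=False)
        rows.append(sub)
    return pd.concat(rows, ignore_index=True)


def pseudobulk_by_group(m: ExpressionMatrix, group_key) -> pd.DataFrame:
    """Arithmetic mean of the lognorm layer per group: group x gene matrix."""
    ln = m.require_lognorm()
    if isinstance(group_key, str):
        labels = m.cell_meta[group_key]
    else:
        labels = pd.Series(np.asarray(group_key, dtype=object), index=m.cell_ids)
    if labels.isna().any():
        raise ParameterError("group labels contain missing values")
    if isinstance(labels.dtype, pd.CategoricalDtype):
        empty = [c for c in labels.cat.categories if (labels == c).sum() == 0]
        if empty:
            raise ParameterError(f"empty groups: {empty}")
    out = {}
    for g, idx in pd.Series(range(m.n_cells), index=labels.to_numpy()).groupby(level=0):
        cols = idx.to_numpy()
        if cols.size == 0:
            raise ParameterError(f"empty group {g!r}")
        out[g] = ln[:, cols].mean(axis=1)
    df = pd.DataFrame(out, index=m.gene_index).T
    df.index.name = "group"
    return df
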