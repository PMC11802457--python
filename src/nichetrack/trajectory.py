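"""PCA, principal-curve pseudotime, and pseudotime-ordered gene modules.

One single-branch trajectory engine serves every ordering in the pipeline:
the neurogenic lineage, the qNSC pseudo-activation axis, and the
inside-out pseudo-spatial axis over inflammatory spot neighborhoods. The
curve is fitted with the Hastie-Stuetzle alternation: project points onto
the current curve, then smooth each coordinate against arc length, until
the mean squared projection distance stabilizes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_lsq_spline
from sklearn.cluster import KMeans

from .datatypes import ExpressionMatrix, ParameterError

__all__ = [
    "PCAResult",
    "PseudotimeResult",
    "ModuleAssignment",
    "compute_pca",
    "fit_principal_curve",
    "orient_pseudotime",
    "pseudotime_modules",
]

log = logging.getLogger("nichetrack")

_CURVE_GRID = 200  # arc-length resolution of the fitted curve
_PROFILE_GRID = 100  # pseudotime grid for gene profiles
_SPLINE_DF = 6  # cubic smoothing basis dimension


@dataclass
class PCAResult:
    """Cell scores, gene loadings and explained variance of a seeded PCA."""

    scores: np.ndarray  # cells x PCs
    loadings: np.ndarray  # genes x PCs
    explained_variance: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]


def compute_pca(m: ExpressionMatrix, n_pcs: int, genes: list[str] | None = None) -> PCAResult:
    """PCA of the lognorm layer over ``genes`` (default all).

    Genes are centered and unit-scaled before decomposition (constant genes
    contribute zeros). Deterministic sign convention: the largest-magnitude
    loading of each component is positive.
    """
    ln = m.require_lognorm()
    use = list(genes) if genes is not None else list(m.gene_ids)
    pos = {g: i for i, g in enumerate(m.gene_ids)}
    missing = [g for g in use if g not in pos]
    if missing:
        raise ParameterError(f"genes absent from matrix: {missing[:5]}")
    X = ln[[pos[g] for g in use], :].T.astype(float)  # cells x genes
    limit = min(X.shape[0], X.shape[1]) - 1
    if n_pcs > limit or n_pcs < 1:
        raise ParameterError(f"n_pcs must lie in [1, {limit}]")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U * S
    loadings = Vt.T
    # sign convention
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    explained = S**2 / (X.shape[0] - 1)
    return PCAResult(
        scores=scores[:, :n_pcs],
        loadings=loadings[:, :n_pcs],
        explained_variance=explained[:n_pcs],
        gene_ids=use,
        cell_ids=list(m.cell_ids),
    )


def _spline_fit(x: np.ndarray, y: np.ndarray, grid: np.ndarray, df: int = _SPLINE_DF) -> np.ndarray:
    """Least-squares cubic B-spline regression of y on x, evaluated on grid.

    The basis has ``df`` functions (interior knots at quantiles); falls back
    to a linear fit when x has too few distinct values. Exactly reproduces
    data that is linear in x (lines lie in the spline span).
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    # collapse duplicate abscissae to their mean response
    xu, inv = np.unique(xs, return_inverse=True)
    if xu.size < df + 2:
        if xu.size < 2:
            return np.full(grid.shape, ys.mean())
        a, b = np.polyfit(xs, ys, 1)
        return a * grid + b
    yu = np.bincount(inv, weights=ys) / np.bincount(inv)
    k = 3
    n_interior = df - k - 1
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.unique(np.quantile(xu, qs))
    interior = interior[(interior > xu[0]) & (interior < xu[-1])]
    t = np.r_[[xu[0]] * (k + 1), interior, [xu[-1]] * (k + 1)]
    try:
        spl = make_lsq_spline(xu, yu, t, k=k)
    except Exception:  # Schoenberg-Whitney failure on clumped data
        a, b = np.polyfit(xs, ys, 1)
        return a * grid + b
    return spl(np.clip(grid, xu[0], xu[-1]))


def _project_to_polyline(X: np.ndarray, curve: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project each row of X onto the polyline; return (arc position, sq dist)."""
    A = curve[:-1]  # segment starts
    B = curve[1:]
    AB = B - A
    seg_len2 = (AB**2).sum(axis=1)
    seg_len2[seg_len2 == 0] = 1e-300
    # t parameter per (point, segment)
    diff = X[:, None, :] - A[None, :, :]
    t = np.clip((diff * AB[None, :, :]).sum(axis=2) / seg_len2[None, :], 0.0, 1.0)
    proj = A[None, :, :] + t[:, :, None] * AB[None, :, :]
    d2 = ((X[:, None, :] - proj) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(np.sqrt(seg_len2))])
    lam = arc[best] + t[np.arange(X.shape[0]), best] * np.sqrt(seg_len2[best])
    return lam, d2[np.arange(X.shape[0]), best]


@dataclass
class PseudotimeResult:
    """Principal-curve ordering: per-cell t in [0, 1] plus the fitted curve."""

    t: pd.Series  # indexed by cell id
    curve_points: np.ndarray  # arc-length-ordered samples in PC space
    projection_distance: pd.Series
    n_pcs: int
    msd_trace: list[float]


def fit_principal_curve(
    pca: PCAResult,
    n_pcs: int,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> PseudotimeResult:
    """Fit a 1-D principal curve through the first ``n_pcs`` PC scores.

    Initialization is the projection onto PC1; each iteration smooths every
    coordinate against the current arc-length position and re-projects the
    points onto the refreshed curve. Iterations are accepted only while the
    mean squared projection distance decreases; convergence when the
    improvement falls below ``tol``.
    """
    if pca.scores.shape[1] < n_pcs:
        raise ParameterError(f"PCA holds only {pca.scores.shape[1]} components")
    X = pca.scores[:, :n_pcs].astype(float)
    if X.shape[0] < 10:
        raise ParameterError("need at least 10 cells for a principal curve")
    if np.allclose(X, X[0], atol=1e-12):
        raise ParameterError("degenerate input: all points identical")

    lam = X[:, 0].copy()  # PC1 projection
    grid01 = np.linspace(0.0, 1.0, _CURVE_GRID)

    def build_curve(lam_now: np.ndarray) -> np.ndarray:
        lo, hi = lam_now.min(), lam_now.max()
        if hi - lo < 1e-12:
            raise ParameterError("degenerate ordering while fitting curve")
        g = lo + grid01 * (hi - lo)
        return np.column_stack([_spline_fit(lam_now, X[:, j], g) for j in range(n_pcs)])

    curve = build_curve(lam)
    lam, d2 = _project_to_polyline(X, curve)
    msd = float(d2.mean())
    trace = [msd]
    for _ in range(max_iter):
        new_curve = build_curve(lam)
        new_lam, new_d2 = _project_to_polyline(X, new_curve)
        new_msd = float(new_d2.mean())
        if new_msd < msd:
            curve, lam, d2 = new_curve, new_lam, new_d2
            improved = msd - new_msd
            msd = new_msd
            trace.append(msd)
            if improved < tol:
                break
        else:
            break

    span = lam.max() - lam.min()
    t = (lam - lam.min()) / (span if span > 0 else 1.0)
    idx = pd.Index(pca.cell_ids, name="cell_id")
    return PseudotimeResult(
        t=pd.Series(t, index=idx),
        curve_points=curve,
        projection_distance=pd.Series(np.sqrt(d2), index=idx),
        n_pcs=n_pcs,
        msd_trace=trace,
    )


def orient_pseudotime(res: PseudotimeResult, root_mask) -> PseudotimeResult:
    """Flip t (and the curve) so the root group sits at low pseudotime."""
    root = np.asarray(root_mask, dtype=bool)
    if root.sum() == 0 or root.all():
        raise ParameterError("root mask must select a proper subset of cells")
    if res.t.to_numpy()[root].mean() > res.t.to_numpy()[~root].mean():
        log.info("pseudotime orientation flipped so the root group is low")
        res.t = 1.0 - res.t
        res.curve_points = res.curve_points[::-1].copy()
    return res


@dataclass
class ModuleAssignment:
    """Gene -> module id (1..K, numbered by profile peak position along t)."""

    module: pd.Series  # indexed by gene, int module ids
    profiles: pd.DataFrame  # gene x grid z-scored smoothed profiles
    peak_position: pd.Series  # grid position in [0, 1] of each gene's peak
    unassigned: list[str]

    def genes_of(self, module_ids) -> list[str]:
        ids = {module_ids} if np.isscalar(module_ids) else set(module_ids)
        return [g for g, k in self.module.items() if k in ids]


def pseudotime_modules(
    m: ExpressionMatrix,
    t: PseudotimeResult | pd.Series,
    n_modules: int = 4,
    genes: list[str] | None = None,
    seed: int = 0,
) -> ModuleAssignment:
    """Cluster smoothed pseudotime expression profiles into ordered modules.

    Each gene's lognorm is regressed on t with a cubic smoothing basis and
    evaluated on a 100-point grid; z-scored profiles are clustered by
    seeded k-means (10 restarts) and modules renumbered so module 1 peaks
    earliest. Constant genes are reported unassigned.
    """
    if n_modules < 2:
        raise ParameterError("n_modules must be >= 2")
    tv = t.t if isinstance(t, PseudotimeResult) else t
    tv = tv.reindex(m.cell_ids)
    if tv.isna().any():
        raise ParameterError("pseudotime missing for some cells")
    ln = m.require_lognorm()
    use = list(genes) if genes is not None else list(m.gene_ids)
    pos = {g: i for i, g in enumerate(m.gene_ids)}
    missing = [g for g in use if g not in pos]
    if missing:
        raise ParameterError(f"genes absent from matrix: {missing[:5]}")

    grid = np.linspace(0.0, 1.0, _PROFILE_GRID)
    x = tv.to_numpy(float)
    profiles, kept, dropped = [], [], []
    for g in use:
        y = ln[pos[g], :]
        prof = _spline_fit(x, y, grid)
        sd = prof.std()
        if y.min() == y.max() or sd < 1e-10:
            dropped.append(g)
            continue
        profiles.append((prof - prof.mean()) / sd)
        kept.append(g)
    if dropped:
        log.info("%d constant/flat genes left unassigned", len(dropped))
    if len(kept) < n_modules:
        raise ParameterError("fewer informative genes than modules")
    P = np.vstack(profiles)
    km = KMeans(n_clusters=n_modules, n_init=10, random_state=seed).fit(P)
    raw = km.labels_
    peak = grid[P.argmax(axis=1)]
    order = np.argsort(
        [peak[raw == k].mean() for k in range(n_modules)], kind="stable"
    )
    renumber = {int(old): i + 1 for i, old in enumerate(order)}
    module = pd.Series([renumber[int(k)] for k in raw], index=pd.Index(kept, name="gene"))
    return ModuleAssignment(
        module=module,
        profiles=pd.DataFrame(P, index=kept, columns=grid),
        peak_position=pd.Series(peak, index=kept),
        unassigned=dropped,
    )
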