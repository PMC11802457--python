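"""Real-time age-trend detection and aging-signature construction.

Genes are summarized as mean log-normalized expression per age group
(young, middle, old), row-standardized, and soft-clustered with fuzzy
c-means. Clusters whose centers rise (fall) strictly with age define the
up- (down-) regulation trend sets. Two signatures are assembled from these:

* NAS (Neurogenic Aging Signature): real-time trend genes that also fall in
  designated pseudotime modules of the qNSC pseudo-activation trajectory
  (up with the quiescence-enriched module, down with the fate-committed
  modules).
* CAS (Core Aging Signature): genes trending in the whole-niche spatial
  pseudobulk and shared by at least ``min_shared`` niche cell populations.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import kmeans_plusplus

from .datatypes import AGE_ORDER, ExpressionMatrix, ParameterError
from .trajectory import ModuleAssignment

__all__ = [
    "AgeProfileMatrix",
    "FuzzyClustering",
    "TrendSets",
    "SignaturePair",
    "age_profiles",
    "fuzzy_cmeans",
    "monotone_trend_sets",
    "build_nas",
    "build_cas",
]

log = logging.getLogger("nichetrack")


@dataclass
class AgeProfileMatrix:
    """Gene x age matrix of row-standardized mean expression."""

    z: pd.DataFrame  # genes x ages, each non-constant row standardized
    excluded: list[str]  # constant genes, flagged and dropped
    population: str


def age_profiles(
    m: ExpressionMatrix,
    population_filter=None,
    hvgs: list[str] | None = None,
    ddof: int = 0,
    flat_alpha: float | None = 0.05,
) -> AgeProfileMatrix:
    """Mean lognorm per age on the selected genes, z-scored per gene.

    ``population_filter`` restricts cells by cell_type (a string, list of
    strings, or boolean mask); all three age groups must be present in the
    filtered cells. Constant genes are excluded and flagged, as are genes
    whose variation across ages is indistinguishable from sampling noise
    (one-way ANOVA p >= ``flat_alpha``; pass ``None`` to keep them):
    row standardization erases amplitude, so flat genes would otherwise
    enter the soft clustering as pure noise profiles.
    """
    meta = m.cell_meta
    if population_filter is None:
        mask = np.ones(m.n_cells, dtype=bool)
        pop = "all"
    elif isinstance(population_filter, str):
        mask = (meta["cell_type"] == population_filter).to_numpy()
        pop = population_filter
    elif isinstance(population_filter, (list, tuple, set)):
        mask = meta["cell_type"].isin(list(population_filter)).to_numpy()
        pop = "+".join(sorted(population_filter))
    else:
        mask = np.asarray(population_filter, dtype=bool)
        pop = "custom"
    sub = m.subset_cells(mask)
    ages = set(sub.cell_meta["age"])
    missing = [a for a in AGE_ORDER if a not in ages]
    if missing:
        raise ParameterError(f"age groups missing from population {pop!r}: {missing}")

    ln = sub.require_lognorm()
    use = list(hvgs) if hvgs is not None else list(sub.gene_ids)
    pos = {g: i for i, g in enumerate(sub.gene_ids)}
    rows = [pos[g] for g in use]
    age_arr = sub.cell_meta["age"].to_numpy()
    means = np.column_stack(
        [ln[np.asarray(rows)][:, age_arr == a].mean(axis=1) for a in AGE_ORDER]
    )
    sd = means.std(axis=1, ddof=ddof)
    constant = sd == 0
    z = (means - means.mean(axis=1, keepdims=True)) / np.where(constant, 1.0, sd)[:, None]
    flat = constant.copy()
    if flat_alpha is not None:
        groups = [ln[np.asarray(rows)][:, age_arr == a] for a in AGE_ORDER]
        with np.errstate(divide="ignore", invalid="ignore"):
            p = stats.f_oneway(*groups, axis=1).pvalue
        flat |= ~(np.asarray(p) < flat_alpha)  # NaN p (constant gene) -> flat
    excluded = [g for g, c in zip(use, flat) if c]
    if excluded:
        log.info("%d constant/flat genes excluded from age profiles", len(excluded))
    keep = ~flat
    frame = pd.DataFrame(
        z[keep], index=pd.Index(np.asarray(use)[keep], name="gene"), columns=list(AGE_ORDER)
    )
    return AgeProfileMatrix(z=frame, excluded=excluded, population=pop)


@dataclass
class FuzzyClustering:
    """Fuzzy c-means fit: centers, soft memberships, objective trace."""

    centers: pd.DataFrame  # clusters x ages
    membership: pd.DataFrame  # genes x clusters, rows sum to 1
    fuzzifier: float
    objective_trace: list[float]


def fuzzy_cmeans(
    profiles: AgeProfileMatrix,
    c: int = 8,
    m_fuzzifier: float = 1.25,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> FuzzyClustering:
    """Soft c-means clustering of age profiles.

    Minimizes ``sum_ij u_ij^m ||x_i - c_j||^2`` by the standard alternation;
    centers are initialized with seeded k-means++. Profiles at zero distance
    from one or more centers split their membership equally among those
    clusters. Converges when the largest membership change drops below
    ``tol`` (or after ``max_iter`` sweeps); the objective trace is recorded
    and is non-increasing.
    """
    if c < 2:
        raise ParameterError("need at least 2 clusters")
    if m_fuzzifier <= 1.0:
        raise ParameterError("fuzzifier must be > 1")
    X = profiles.z.to_numpy(float)
    n = X.shape[0]
    if n < c:
        raise ParameterError(f"only {n} profiles for {c} clusters")

    centers, _ = kmeans_plusplus(X, n_clusters=c, random_state=seed)
    expo = 2.0 / (m_fuzzifier - 1.0)

    def memberships(cent: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        zero = d2 <= 1e-300
        u = np.empty_like(d2)
        any_zero = zero.any(axis=1)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            # overflow to inf for very distant clusters is benign: 1/inf -> 0
            ratio = (d2[:, :, None] / d2[:, None, :]) ** (expo / 2.0)
            u = 1.0 / ratio.sum(axis=2)
        u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
        return u, d2

    u, d2 = memberships(centers)
    trace = [float((u**m_fuzzifier * d2).sum())]
    for _ in range(max_iter):
        w = u**m_fuzzifier
        centers = (w.T @ X) / w.sum(axis=0)[:, None]
        new_u, d2 = memberships(centers)
        trace.append(float((new_u**m_fuzzifier * d2).sum()))
        delta = np.abs(new_u - u).max()
        u = new_u
        if delta < tol:
            break

    return FuzzyClustering(
        centers=pd.DataFrame(centers, columns=profiles.z.columns),
        membership=pd.DataFrame(
            u, index=profiles.z.index, columns=[f"cluster_{j}" for j in range(c)]
        ),
        fuzzifier=m_fuzzifier,
        objective_trace=trace,
    )


@dataclass
class TrendSets:
    """Genes assigned to strictly age-increasing / decreasing clusters."""

    up_genes: list[str]
    down_genes: list[str]
    max_membership: pd.Series
    cluster_direction: dict[str, str]  # cluster -> up | down | neither


def monotone_trend_sets(
    clust: FuzzyClustering, membership_threshold: float = 0.5
) -> TrendSets:
    """Split genes by the monotone direction of their best cluster's center.

    A cluster is "up" when its center rises strictly young < middle < old,
    "down" when it falls strictly, otherwise "neither". A gene joins its
    argmax-membership cluster's set only when that membership reaches the
    threshold. Empty sets are allowed.
    """
    centers = clust.centers.to_numpy()
    direction = {}
    for j, name in enumerate(clust.membership.columns):
        row = centers[j]
        if np.all(np.diff(row) > 0):
            direction[name] = "up"
        elif np.all(np.diff(row) < 0):
            direction[name] = "down"
        else:
            direction[name] = "neither"
    u = clust.membership.to_numpy()
    best = u.argmax(axis=1)
    best_u = u[np.arange(u.shape[0]), best]
    up, down = [], []
    for gene, j, val in zip(clust.membership.index, best, best_u):
        if val < membership_threshold:
            continue
        d = direction[clust.membership.columns[j]]
        if d == "up":
            up.append(gene)
        elif d == "down":
            down.append(gene)
    return TrendSets(
        up_genes=up,
        down_genes=down,
        max_membership=pd.Series(best_u, index=clust.membership.index),
        cluster_direction=direction,
    )


@dataclass
class SignaturePair:
    """Up/down gene signature with per-gene provenance tags."""

    name: str
    up: list[str]
    down: list[str]
    provenance: dict[str, list[str]]

    def __post_init__(self):
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ParameterError(f"up/down overlap in {self.name}: {sorted(overlap)[:5]}")


def build_nas(
    realtime: TrendSets,
    modules: ModuleAssignment,
    up_module_ids=(1,),
    down_module_ids=(3, 4),
) -> SignaturePair:
    """Neurogenic Aging Signature: real-time trends intersected with
    pseudotime modules of the qNSC pseudo-activation trajectory.

    Up = real-time up genes in the quiescence-enriched module(s); down =
    real-time down genes in the fate-committed module(s). Disjoint inputs
    yield an empty signature with a warning.
    """
    up_pool = set(modules.genes_of(list(up_module_ids)))
    down_pool = set(modules.genes_of(list(down_module_ids)))
    up = sorted(set(realtime.up_genes) & up_pool)
    down = sorted(set(realtime.down_genes) & down_pool)
    if not up and not down:
        log.warning("NAS: real-time trends and pseudotime modules do not overlap")
    prov = {g: ["realtime_up", f"module_{sorted(up_module_ids)}"] for g in up}
    prov.update({g: ["realtime_down", f"module_{sorted(down_module_ids)}"] for g in down})
    return SignaturePair(name="NAS", up=up, down=down, provenance=prov)


def build_cas(
    celltype_trends: dict[str, TrendSets],
    st_trend: TrendSets,
    min_shared: int = 2,
) -> SignaturePair:
    """Core Aging Signature: whole-niche spatial trend genes shared by at
    least ``min_shared`` niche cell populations, with per-gene provenance."""
    if min_shared > len(celltype_trends):
        raise ParameterError(
            f"min_shared={min_shared} exceeds {len(celltype_trends)} populations"
        )
    prov: dict[str, list[str]] = {}

    def shared(st_genes: list[str], attr: str) -> list[str]:
        out = []
        for g in sorted(set(st_genes)):
            pops = sorted(
                p for p, tr in celltype_trends.items() if g in getattr(tr, attr)
            )
            if len(pops) >= min_shared:
                out.append(g)
                prov[g] = ["spatial_" + attr.replace("_genes", "")] + pops
        return out

    up = shared(st_trend.up_genes, "up_genes")
    down = shared(st_trend.down_genes, "down_genes")
    return SignaturePair(name="CAS", up=up, down=down, provenance=prov)
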