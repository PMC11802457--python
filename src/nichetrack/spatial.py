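"""Inflammatory-spot calling, hexagonal neighbor rings, pseudo-spatial axis.

Spots scoring above zero on an IFN-gamma-response module are inflammatory
spots (IS). Breadth-first expansion over the hexagonal lattice defines
their nearest-neighbor spots (NNS) and two rings of extended neighbor
spots (ENS1, ENS2); the remaining spots in the analyzed region are
"other". A principal curve over spot PCs gives the inside-out
pseudo-spatial ordering and its gene modules.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .datatypes import ParameterError, SpotGrid
from .scoring import ModuleScoreResult
from . import trajectory

__all__ = [
    "SpotHierarchy",
    "PseudoSpace",
    "call_inflammatory_spots",
    "hex_adjacency",
    "build_spot_hierarchy",
    "pseudospatial_modules",
]

log = logging.getLogger("nichetrack")

HIERARCHY_CLASSES = ("IS", "NNS", "ENS1", "ENS2", "other")

#: hexagonal neighbor offsets in Visium array coordinates
_HEX_OFFSETS = ((0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1))


def call_inflammatory_spots(scores: ModuleScoreResult, threshold: float = 0.0) -> pd.Series:
    """Boolean IS mask: module score strictly greater than the threshold."""
    return scores.scores > threshold


def hex_adjacency(grid: SpotGrid) -> dict[str, list[str]]:
    """Adjacency list on array coordinates: neighbors of (r, c) are the
    occupied spots among (r, c +/- 2) and (r +/- 1, c +/- 1); symmetric."""
    by_coord = {
        (int(r), int(c)): s
        for s, r, c in zip(grid.spot_ids, grid.array_row, grid.array_col)
    }
    adj: dict[str, list[str]] = {}
    for s, r, c in zip(grid.spot_ids, grid.array_row, grid.array_col):
        adj[s] = [
            by_coord[(r + dr, c + dc)]
            for dr, dc in _HEX_OFFSETS
            if (r + dr, c + dc) in by_coord
        ]
    return adj


def pixel_adjacency(grid: SpotGrid, factor: float = 1.2) -> dict[str, list[str]]:
    """Fallback adjacency for irregular grids: spots within ``factor`` times
    the minimum center spacing are neighbors."""
    xy = grid.pixel_xy
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    cutoff = factor * d.min()
    adj = {}
    for i, s in enumerate(grid.spot_ids):
        adj[s] = [grid.spot_ids[j] for j in np.flatnonzero(d[i] <= cutoff)]
    return adj


@dataclass
class SpotHierarchy:
    """Per-spot class in {IS, NNS, ENS1, ENS2, other} over the masked region."""

    classes: pd.Series  # indexed by spot id; classes partition masked spots
    adjacency: dict[str, list[str]]
    region_mask: pd.Series

    def spots_of(self, cls: str) -> list[str]:
        return self.classes.index[self.classes == cls].tolist()


def build_spot_hierarchy(
    is_mask: pd.Series,
    adjacency: dict[str, list[str]],
    region_mask: pd.Series | None = None,
    n_ens_layers: int = 2,
) -> SpotHierarchy:
    """Breadth-first ring expansion from the inflammatory spots.

    Ring 1 = NNS, rings 2..(1+n_ens_layers) = ENS1, ENS2, ...; every other
    masked spot is "other". Expansion stays inside the region mask. With no
    IS at all, every masked spot is "other" (warned).
    """
    spots = list(is_mask.index)
    if region_mask is None:
        region_mask = pd.Series(True, index=is_mask.index)
    region_mask = region_mask.reindex(spots).fillna(False).astype(bool)
    masked = [s for s in spots if region_mask[s]]
    classes = pd.Series("other", index=pd.Index(masked, name="spot_id"), dtype=object)

    frontier = [s for s in masked if is_mask.get(s, False)]
    classes[frontier] = "IS"
    if not frontier:
        log.warning("no inflammatory spots in the masked region; all spots 'other'")
    ring_names = ["NNS"] + [f"ENS{i + 1}" for i in range(n_ens_layers)]
    visited = set(frontier)
    for name in ring_names:
        nxt = sorted(
            {
                nb
                for s in frontier
                for nb in adjacency.get(s, [])
                if nb not in visited and region_mask.get(nb, False)
            }
        )
        classes[nxt] = name
        visited.update(nxt)
        frontier = nxt
        if not frontier:
            break
    return SpotHierarchy(classes=classes, adjacency=adjacency, region_mask=region_mask)


@dataclass
class PseudoSpace:
    """Inside-out ordering of masked spots with its gene modules."""

    s: pd.Series  # per-spot ordering value, IS low
    modules: trajectory.ModuleAssignment
    class_summary: pd.DataFrame  # per hierarchy class: mean/sem/count of s


def pseudospatial_modules(
    grid: SpotGrid,
    hierarchy: SpotHierarchy,
    n_modules: int = 4,
    cfg: PipelineConfig | None = None,
) -> PseudoSpace:
    """Principal-curve ordering of masked spots, oriented inside-out.

    The curve is fitted over the first ``n_pcs_curve`` spot PCs (on the
    masked spots only) and oriented so inflammatory spots sit at low s and
    the outermost ring at high s; gene modules along s are numbered
    inside-out (module 1 peaks at the IS end).
    """
    cfg = cfg or PipelineConfig()
    expr = grid.as_expression()
    masked_ids = hierarchy.classes.index.tolist()
    if len(masked_ids) < 20:
        raise ParameterError("need at least 20 masked spots for a pseudo-spatial axis")
    keep = np.asarray([s in set(masked_ids) for s in expr.cell_ids])
    sub = expr.subset_cells(keep)
    sub.require_lognorm()

    n_pcs = min(cfg.n_pcs_curve, min(sub.n_genes, sub.n_cells) - 1)
    pca = trajectory.compute_pca(sub, n_pcs=max(n_pcs, 2))
    if pca.explained_variance[0] <= 1e-10:
        raise ParameterError("degenerate expression: no variance across masked spots")
    curve = trajectory.fit_principal_curve(pca, n_pcs=max(n_pcs, 2))

    cls = hierarchy.classes.reindex(sub.cell_ids)
    is_mask = (cls == "IS").to_numpy()
    outer = f"ENS{len([c for c in cls.unique() if str(c).startswith('ENS')])}"
    outer_mask = (cls == (outer if (cls == outer).any() else "other")).to_numpy()
    if is_mask.any() and outer_mask.any():
        if curve.t.to_numpy()[is_mask].mean() > curve.t.to_numpy()[outer_mask].mean():
            curve.t = 1.0 - curve.t
            curve.curve_points = curve.curve_points[::-1].copy()
            log.info("pseudo-spatial axis flipped: IS oriented low")
    s = curve.t.rename("pseudo_space")

    modules = trajectory.pseudotime_modules(
        sub, s, n_modules=n_modules, seed=cfg.seed
    )
    summary = (
        pd.DataFrame({"s": s, "class": cls})
        .groupby("class")["s"]
        .agg(["mean", "sem", "count"])
    )
    return PseudoSpace(s=s, modules=modules, class_summary=summary)
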