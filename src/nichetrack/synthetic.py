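"""Synthetic data with planted ground truth for every downstream stage.

Three generators emulate the study's three data modalities:

* :func:`simulate_lineage_atlas` — a 3-stage neurogenic lineage
  (qNSC -> aNSPC -> NB/IMN) sampled at three ages, with per-type marker
  blocks, monotone age-regulated gene programs, and lineage gene modules
  driven by a latent differentiation coordinate.
* :func:`simulate_spot_grid` — a hexagonal Visium-style lattice with
  localized inflammatory hotspots whose signal decays exponentially with
  distance.
* :func:`simulate_tissue_cells` — 2-D point patterns with independent,
  mutually exclusive, or attractive binary cell labels.

Counts are negative-binomial: for cell ``c`` and gene ``g`` the mean is
``libsize_c * rate_gc / sum_g rate_gc`` with shared per-block dispersion
``theta``; ages act multiplicatively (log-linearly) on rates. Ground truth
(latent coordinates, block memberships, hotspot distances) is always emitted
so recovery tests never re-derive it.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import AGE_ORDER, ExpressionMatrix, ParameterError, SpotGrid

__all__ = [
    "LineageSimParams",
    "SpotSimParams",
    "TissueSimParams",
    "simulate_lineage_atlas",
    "simulate_spot_grid",
    "simulate_tissue_cells",
    "sgz_polyline",
    "write_lineage_outputs",
]

LINEAGE_TYPES = ("qNSC", "aNSPC", "NB/IMN")

#: latent differentiation coordinate per type: quiescent low, committed high
_LATENT_MEAN = {"qNSC": 0.15, "aNSPC": 0.50, "NB/IMN": 0.85}
_LATENT_SD = 0.07

#: logistic windows giving the sequential module structure along latent time;
#: (rise midpoint, fall midpoint); None = open-ended
_MODULE_WINDOWS = [(None, 0.30), (0.30, 0.55), (0.55, 0.80), (0.80, None)]
_MODULE_STEEPNESS = 0.07


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _window(t, rise, fall, s=_MODULE_STEEPNESS):
    act = np.ones_like(t)
    if rise is not None:
        act = act * _sigmoid((t - rise) / s)
    if fall is not None:
        act = act * (1.0 - _sigmoid((t - fall) / s))
    return act


@dataclass
class LineageSimParams:
    """Study conditions for the lineage atlas generator.

    ``n_cells_per_group`` is per (cell type, age) — the default 100 gives
    300 cells per age across the three lineage stages. Effect sizes are on
    the natural-log rate scale: ``marker_logfc`` for type markers,
    ``module_logfc`` for lineage modules, and ``aging_delta`` per age step
    for the monotone aging programs. ``qnsc_age_drift`` shifts the qNSC
    latent activation mean downward per age step (older qNSCs sit deeper in
    quiescence).
    """

    n_cells_per_group: int | dict = 100
    n_genes: int = 800
    n_marker_genes: int = 40
    n_aging_genes: int = 60
    n_module_genes: int = 40
    marker_logfc: float = 1.5
    module_logfc: float = 1.5
    aging_delta: float = 0.5
    balance_aging: bool = True  # redistribute rate so aging blocks stay compositionally neutral
    qnsc_age_drift: float = 0.05
    libsize_mu: float = math.log(5_000.0)
    libsize_sigma: float = 0.3
    theta: float = 10.0
    gene_blocks: dict | None = None  # optional explicit {block: [gene indices]}

    def n_cells(self, cell_type: str, age: str) -> int:
        if isinstance(self.n_cells_per_group, dict):
            return int(self.n_cells_per_group[(cell_type, age)])
        return int(self.n_cells_per_group)

    def __post_init__(self):
        if self.aging_delta < 0:
            raise ParameterError("aging_delta must be >= 0")
        if self.theta <= 0:
            raise ParameterError("dispersion theta must be > 0")


def _default_blocks(p: LineageSimParams) -> dict[str, np.ndarray]:
    sizes = (
        [("marker_" + t, p.n_marker_genes) for t in LINEAGE_TYPES]
        + [("aging_up", p.n_aging_genes), ("aging_down", p.n_aging_genes)]
        + [(f"lineage_m{i + 1}", p.n_module_genes) for i in range(len(_MODULE_WINDOWS))]
    )
    need = sum(s for _, s in sizes)
    if need > p.n_genes:
        raise ParameterError(f"n_genes={p.n_genes} too small for gene blocks ({need})")
    blocks, start = {}, 0
    for name, size in sizes:
        blocks[name] = np.arange(start, start + size)
        start += size
    return blocks


def _check_disjoint(blocks: dict[str, np.ndarray], n_genes: int) -> None:
    seen = np.zeros(n_genes, dtype=int)
    for idx in blocks.values():
        idx = np.asarray(idx)
        if idx.size and (idx.min() < 0 or idx.max() >= n_genes):
            raise ParameterError("gene block index out of range")
        seen[idx] += 1
    if (seen > 1).any():
        raise ParameterError("gene blocks must be pairwise disjoint")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


def simulate_lineage_atlas(
    params: LineageSimParams | None = None, seed: int = 0
) -> tuple[ExpressionMatrix, dict]:
    """Simulate the 3-type x 3-age lineage atlas; returns (matrix, truth).

    ``truth`` holds ``cells`` (cell_id, cell_type, age, latent_t), ``genes``
    (gene_id, block) and the parameters used. Same seed, same output.
    """
    p = params or LineageSimParams()
    rng = np.random.default_rng(seed)
    blocks = (
        {k: np.asarray(v) for k, v in p.gene_blocks.items()}
        if p.gene_blocks is not None
        else _default_blocks(p)
    )
    _check_disjoint(blocks, p.n_genes)

    gene_ids = [f"g{i:04d}" for i in range(p.n_genes)]
    block_of = np.full(p.n_genes, "null", dtype=object)
    for name, idx in blocks.items():
        block_of[np.asarray(idx)] = name

    cell_type, age, latent = [], [], []
    for t in LINEAGE_TYPES:
        for ai, a in enumerate(AGE_ORDER):
            n = p.n_cells(t, a)
            mu = _LATENT_MEAN[t]
            if t == "qNSC":
                mu = mu - p.qnsc_age_drift * ai
            latent.append(np.clip(rng.normal(mu, _LATENT_SD, n), 0.01, 0.99))
            cell_type += [t] * n
            age += [a] * n
    latent = np.concatenate(latent)
    n_cells = latent.size
    age_idx = np.array([AGE_ORDER.index(a) for a in age])
    type_arr = np.array(cell_type, dtype=object)

    baseline = np.exp(rng.normal(0.0, 1.0, p.n_genes))
    log_rate = np.log(baseline)[:, None] + np.zeros((p.n_genes, n_cells))
    for t in LINEAGE_TYPES:
        key = "marker_" + t
        if key in blocks:
            log_rate[np.ix_(blocks[key], np.flatnonzero(type_arr == t))] += p.marker_logfc
    # Age shifts are compositionally balanced: the up/down blocks jointly
    # redistribute rate rather than inflating the per-cell total, so
    # library-size normalization does not leak a spurious trend into
    # unregulated genes.
    up_idx = blocks.get("aging_up", np.array([], dtype=int))
    dn_idx = blocks.get("aging_down", np.array([], dtype=int))
    if up_idx.size or dn_idx.size:
        w_up = baseline[up_idx].sum()
        w_dn = baseline[dn_idx].sum()
        for ai in range(len(AGE_ORDER)):
            cells_ai = np.flatnonzero(age_idx == ai)
            gain = math.exp(p.aging_delta * ai)
            total = w_up * gain + w_dn / gain
            balance = math.log((w_up + w_dn) / total) if (p.balance_aging and total > 0) else 0.0
            if up_idx.size:
                log_rate[np.ix_(up_idx, cells_ai)] += p.aging_delta * ai + balance
            if dn_idx.size:
                log_rate[np.ix_(dn_idx, cells_ai)] += -p.aging_delta * ai + balance
    for i, (rise, fall) in enumerate(_MODULE_WINDOWS):
        key = f"lineage_m{i + 1}"
        if key in blocks:
            log_rate[blocks[key], :] += p.module_logfc * _window(latent, rise, fall)[None, :]

    rate = np.exp(log_rate)
    rate /= rate.sum(axis=0, keepdims=True)
    libsize = np.exp(rng.normal(p.libsize_mu, p.libsize_sigma, n_cells))
    counts = _nb_counts(rng, rate * libsize[None, :], p.theta)

    cell_ids = [f"c{i:05d}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {"cell_type": type_arr, "age": age}, index=pd.Index(cell_ids, name="cell_id")
    )
    m = ExpressionMatrix(
        gene_ids=gene_ids, cell_ids=cell_ids, counts=sp.csr_matrix(counts), cell_meta=meta
    )
    truth = {
        "cells": pd.DataFrame(
            {"cell_id": cell_ids, "cell_type": type_arr, "age": age, "latent_t": latent}
        ),
        "genes": pd.DataFrame({"gene_id": gene_ids, "block": block_of}),
        "params": p,
        "seed": seed,
    }
    return m, truth


# ---------------------------------------------------------------------------
# spot lattice with inflammatory hotspots
# ---------------------------------------------------------------------------


@dataclass
class SpotSimParams:
    """Hex lattice with hotspots: inflammatory-block rates are multiplied by
    ``1 + amplitude * exp(-d / decay_um)`` where ``d`` is the distance (um)
    to the nearest hotspot center; all other genes are flat."""

    n_rows: int = 20
    n_cols: int = 20  # occupied spots per row
    pitch_um: float = 100.0
    hotspot_centers: list = field(
        default_factory=lambda: [(4, 6), (7, 14), (10, 20), (12, 26), (15, 30), (17, 35)]
    )
    decay_um: float = 250.0  # gradient stays structured through both extended rings
    amplitude: float = 2.0
    n_genes: int = 300
    n_inflammatory_genes: int = 60
    libsize_mu: float = math.log(20_000.0)  # typical Visium per-spot depth
    libsize_sigma: float = 0.25
    theta: float = 50.0  # spots are ~10-cell pseudobulk, so low overdispersion
    region_label: str = "hippocampus"

    def __post_init__(self):
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ParameterError("empty lattice")
        if self.decay_um <= 0:
            raise ParameterError("decay length must be > 0")


def _hex_xy(row: np.ndarray, col: np.ndarray, pitch: float) -> np.ndarray:
    # Visium convention: columns advance by 2 within a row; neighbor distance = pitch
    x = col * pitch / 2.0
    y = row * pitch * math.sqrt(3.0) / 2.0
    return np.column_stack([x, y])


def simulate_spot_grid(
    params: SpotSimParams | None = None, seed: int = 0
) -> tuple[SpotGrid, dict]:
    """Simulate a hotspot-bearing spot lattice; returns (grid, truth).

    ``truth`` holds the per-spot distance field to the nearest hotspot center
    and the inflammatory-gene block.
    """
    p = params or SpotSimParams()
    rng = np.random.default_rng(seed)

    rows, cols = [], []
    for r in range(p.n_rows):
        for k in range(p.n_cols):
            rows.append(r)
            cols.append(r % 2 + 2 * k)
    row = np.array(rows)
    col = np.array(cols)
    xy = _hex_xy(row, col, p.pitch_um)

    centers = np.asarray(p.hotspot_centers, dtype=float)
    if centers.size == 0:
        raise ParameterError("at least one hotspot center required")
    if centers[:, 0].max() >= p.n_rows or centers[:, 1].max() >= p.n_cols * 2 + 1:
        raise ParameterError("hotspot centers must lie inside the lattice")
    center_xy = _hex_xy(centers[:, 0], centers[:, 1], p.pitch_um)
    d = np.min(
        np.linalg.norm(xy[:, None, :] - center_xy[None, :, :], axis=2), axis=1
    )

    if p.n_inflammatory_genes >= p.n_genes:
        raise ParameterError("n_inflammatory_genes must be < n_genes")
    inflam = np.arange(p.n_inflammatory_genes)
    gene_ids = [f"s{i:04d}" for i in range(p.n_genes)]
    baseline = np.exp(rng.normal(0.0, 0.5, p.n_genes))
    rate = np.tile(baseline[:, None], (1, row.size))
    rate[inflam, :] *= 1.0 + p.amplitude * np.exp(-d / p.decay_um)[None, :]
    rate /= rate.sum(axis=0, keepdims=True)
    libsize = np.exp(rng.normal(p.libsize_mu, p.libsize_sigma, row.size))
    counts = _nb_counts(rng, rate * libsize[None, :], p.theta)

    spot_ids = [f"spot{r:03d}x{c:03d}" for r, c in zip(row, col)]
    grid = SpotGrid(
        spot_ids=spot_ids,
        array_row=row,
        array_col=col,
        pixel_xy=xy,
        gene_ids=gene_ids,
        counts=sp.csr_matrix(counts),
        region=np.full(row.size, p.region_label, dtype=object),
    )
    truth = {
        "spots": pd.DataFrame({"spot_id": spot_ids, "dist_to_hotspot_um": d}),
        "genes": pd.DataFrame(
            {
                "gene_id": gene_ids,
                "block": ["inflammatory" if i in set(inflam) else "null" for i in range(p.n_genes)],
            }
        ),
        "params": p,
        "seed": seed,
    }
    return grid, truth


# ---------------------------------------------------------------------------
# tissue point patterns
# ---------------------------------------------------------------------------


@dataclass
class TissueSimParams:
    """2-D point pattern with two binary labels (e.g., Ki67+ and STAT1+).

    Regimes: ``independent`` labels are i.i.d. Bernoulli; ``exclusive``
    thins B labels within ``strength_um`` of any A-labeled cell;
    ``attractive`` boosts B-label odds near A-labeled cells.
    """

    window_um: tuple[float, float] = (1_000.0, 1_000.0)
    n_cells: int = 2_000
    p_a: float = 0.10
    p_b: float = 0.10
    regime: str = "independent"
    strength_um: float = 50.0

    def __post_init__(self):
        if not (0.0 < self.p_a < 1.0 and 0.0 < self.p_b < 1.0):
            raise ParameterError("label probabilities must lie in (0, 1)")
        if self.regime not in ("independent", "exclusive", "attractive"):
            raise ParameterError(f"unknown regime {self.regime!r}")
        if self.strength_um < 0:
            raise ParameterError("strength must be >= 0")


def simulate_tissue_cells(
    params: TissueSimParams | None = None, seed: int = 0
) -> pd.DataFrame:
    """Simulate a labeled point table with columns x, y, label_A, label_B."""
    p = params or TissueSimParams()
    rng = np.random.default_rng(seed)
    w, h = p.window_um
    for attempt in range(20):
        x = rng.uniform(0, w, p.n_cells)
        y = rng.uniform(0, h, p.n_cells)
        label_a = rng.random(p.n_cells) < p.p_a
        if p.regime == "independent":
            label_b = rng.random(p.n_cells) < p.p_b
        else:
            pts = np.column_stack([x, y])
            a_pts = pts[label_a]
            if a_pts.size:
                d_near = np.min(
                    np.linalg.norm(pts[:, None, :] - a_pts[None, :, :], axis=2), axis=1
                )
            else:
                d_near = np.full(p.n_cells, np.inf)
            if p.regime == "exclusive":
                candidate = (rng.random(p.n_cells) < p.p_b) & ~label_a
                label_b = candidate & (d_near >= p.strength_um)
                expected = p.p_b * p.n_cells
                if label_b.sum() == 0 and expected > 5:
                    continue  # window too crowded; retry placement
            else:  # attractive
                boost = 1.0 + 4.0 * np.exp(-d_near / max(p.strength_um, 1e-9))
                prob = np.clip(p.p_b * boost, 0.0, 1.0)
                label_b = rng.random(p.n_cells) < prob
        return pd.DataFrame(
            {
                "x": x,
                "y": y,
                "label_A": label_a.astype(int),
                "label_B": label_b.astype(int),
            }
        )
    raise ParameterError(
        "window too small to place B-labeled cells at the requested exclusion radius"
    )


def sgz_polyline(
    window_um: tuple[float, float] = (2_000.0, 2_000.0),
    n_rows: int = 10,
    margin_um: float = 100.0,
) -> np.ndarray:
    """A long snaking reference line through the window, standing in for the
    manually drawn subgranular-zone line along which microniches are tiled."""
    w, h = window_um
    pts = []
    for i, y in enumerate(np.linspace(margin_um, h - margin_um, n_rows)):
        xs = (margin_um, w - margin_um) if i % 2 == 0 else (w - margin_um, margin_um)
        pts += [(xs[0], y), (xs[1], y)]
    return np.array(pts)


def write_lineage_outputs(m: ExpressionMatrix, truth: dict, out_dir: str | Path) -> None:
    """Persist a simulated atlas: 10x triplet + ground-truth CSVs + manifest."""
    from . import io as nio  # deferred: avoid import cycle at module load

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nio.write_counts_10x(m, out_dir / "counts")
    truth["cells"].to_csv(out_dir / "truth_cells.csv", index=False)
    truth["genes"].to_csv(out_dir / "truth_genes.csv", index=False)
    params = truth["params"]
    manifest = {
        "seed": truth["seed"],
        "params": {
            k: (v if not isinstance(v, dict) else {str(kk): vv for kk, vv in v.items()})
            for k, v in vars(params).items()
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
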