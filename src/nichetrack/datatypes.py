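"""Core in-memory containers shared by all pipeline stages.

All expression matrices are oriented gene-major (genes x cells / genes x
spots); spot matrices are transposed into this orientation on load so the
scoring code has a single convention.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "AGE_ORDER",
    "AgeLabel",
    "ExpressionMatrix",
    "FormatError",
    "GeneSet",
    "ParameterError",
    "SpotGrid",
    "age_categorical",
]

#: Ordered age-group vocabulary: young (3 MO) < middle (9-11 MO) < old (16-21 MO).
AGE_ORDER = ("young", "middle", "old")


class FormatError(ValueError):
    """A file or table violates the declared format contract."""


class ParameterError(ValueError):
    """Invalid parameters passed to a pipeline operation."""


def age_categorical(values) -> pd.Categorical:
    """Coerce age labels to the ordered young < middle < old categorical."""
    cat = pd.Categorical(values, categories=list(AGE_ORDER), ordered=True)
    bad = pd.isna(cat) & ~pd.isna(np.asarray(values, dtype=object))
    if bad.any():
        raise ParameterError(
            f"unknown age labels: {sorted(set(np.asarray(values, dtype=object)[bad]))}; "
            f"expected one of {AGE_ORDER}"
        )
    return cat


@dataclass(frozen=True)
class AgeLabel:
    """One ordered age group; ``index`` is 0/1/2 for young/middle/old."""

    value: str

    def __post_init__(self):
        if self.value not in AGE_ORDER:
            raise ParameterError(f"unknown age label {self.value!r}")

    @property
    def index(self) -> int:
        return AGE_ORDER.index(self.value)

    def __lt__(self, other: "AgeLabel") -> bool:
        return self.index < other.index


@dataclass(frozen=True)
class GeneSet:
    """A named gene list (e.g., the hallmark IFN-gamma response set)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.genes)) != len(self.genes):
            raise FormatError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


def _check_unique(ids, what: str) -> None:
    ids = pd.Index(ids)
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()[:5]
        raise FormatError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Gene x cell counts with optional log-normalized layer and cell metadata.

    Parameters
    ----------
    gene_ids, cell_ids
        Unique identifiers for the rows / columns of ``counts``.
    counts
        Non-negative integer matrix, genes in rows, cells in columns.
        Stored sparse (CSR) regardless of the input container.
    lognorm
        Optional dense gene x cell log-normalized layer (see
        :func:`nichetrack.scoring.log_normalize`).
    cell_meta
        Per-cell table indexed by ``cell_ids``; guaranteed to carry at least
        ``cell_type`` and ``age`` columns (filled with "unknown" if absent).
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.spmatrix
    lognorm: np.ndarray | None = None
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self):
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("counts must be non-negative")
        if self.counts.nnz and np.any(self.counts.data != np.round(self.counts.data)):
            raise FormatError("counts must be integral")
        if self.lognorm is not None:
            self.lognorm = np.asarray(self.lognorm, dtype=float)
            if self.lognorm.shape != self.counts.shape:
                raise FormatError("lognorm layer shape does not match counts")
        meta = self.cell_meta
        if meta is None:
            meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id"))
        else:
            meta = meta.copy()
            meta.index = pd.Index([str(i) for i in meta.index], name="cell_id")
            if not meta.index.equals(pd.Index(self.cell_ids, name="cell_id")):
                meta = meta.reindex(self.cell_ids)
        for col in ("cell_type", "age"):
            if col not in meta.columns:
                meta[col] = "unknown"
            meta[col] = meta[col].fillna("unknown")
        self.cell_meta = meta

    # -- convenience -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def require_lognorm(self) -> np.ndarray:
        if self.lognorm is None:
            raise ParameterError(
                "log-normalized layer missing; run scoring.log_normalize first"
            )
        return self.lognorm

    def subset_cells(self, mask) -> "ExpressionMatrix":
        """Return a copy restricted to the boolean/positional cell selection."""
        idx = np.arange(self.n_cells)[np.asarray(mask)] if np.asarray(mask).dtype == bool else np.asarray(mask)
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            counts=self.counts[:, idx],
            lognorm=None if self.lognorm is None else self.lognorm[:, idx],
            cell_meta=self.cell_meta.iloc[idx],
        )

    def lognorm_frame(self, genes=None) -> pd.DataFrame:
        """Dense gene x cell DataFrame of the log-normalized layer."""
        ln = self.require_lognorm()
        df = pd.DataFrame(ln, index=self.gene_index, columns=self.cell_ids)
        return df if genes is None else df.loc[list(genes)]

    def to_anndata(self):
        """Optional bridge to an :class:`anndata.AnnData` (cells x genes)."""
        import anndata  # local import: optional convenience only

        ad = anndata.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=self.gene_index),
        )
        if self.lognorm is not None:
            ad.layers["lognorm"] = np.ascontiguousarray(self.lognorm.T)
        return ad


@dataclass
class SpotGrid:
    """Visium-style spot lattice with expression, internally gene-major.

    Array coordinates follow the Visium convention: within a row, occupied
    columns share the row's parity, so hexagonal neighbors of ``(r, c)`` are
    ``(r, c +/- 2)`` and ``(r +/- 1, c +/- 1)``.
    """

    spot_ids: list[str]
    array_row: np.ndarray
    array_col: np.ndarray
    pixel_xy: np.ndarray  # (n_spots, 2), micrometres or pixels
    gene_ids: list[str]
    counts: sp.spmatrix  # gene x spot
    lognorm: np.ndarray | None = None
    region: np.ndarray | None = None
    region_vocab: tuple[str, ...] | None = None

    def __post_init__(self):
        self.spot_ids = [str(s) for s in self.spot_ids]
        _check_unique(self.spot_ids, "spot ids")
        n = len(self.spot_ids)
        self.array_row = np.asarray(self.array_row, dtype=int)
        self.array_col = np.asarray(self.array_col, dtype=int)
        self.pixel_xy = np.asarray(self.pixel_xy, dtype=float).reshape(n, 2)
        if self.array_row.shape != (n,) or self.array_col.shape != (n,):
            raise FormatError("array coordinates do not match number of spots")
        pairs = list(zip(self.array_row.tolist(), self.array_col.tolist()))
        if len(set(pairs)) != n:
            raise FormatError("duplicate (array_row, array_col) pairs")
        for r in np.unique(self.array_row):
            cols = self.array_col[self.array_row == r]
            if np.unique((r + cols) % 2).size > 1:
                raise FormatError(f"inconsistent column parity in array row {r}")
        if self.region is None:
            self.region = np.full(n, "other", dtype=object)
        self.region = np.asarray(self.region, dtype=object)
        if self.region.shape != (n,):
            raise FormatError("region labels do not match number of spots")
        if self.region_vocab is not None:
            bad = set(self.region) - set(self.region_vocab)
            if bad:
                raise FormatError(f"region labels outside declared vocabulary: {sorted(bad)}")
        self._expr = ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            cell_ids=self.spot_ids,
            counts=self.counts,
            lognorm=self.lognorm,
            cell_meta=pd.DataFrame(
                {
                    "cell_type": "spot",
                    "region": self.region,
                    "array_row": self.array_row,
                    "array_col": self.array_col,
                },
                index=pd.Index(self.spot_ids, name="cell_id"),
            ),
        )
        self.gene_ids = self._expr.gene_ids
        self.counts = self._expr.counts

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def as_expression(self) -> ExpressionMatrix:
        """View of the grid as an ExpressionMatrix (spots play the cell role)."""
        self._expr.lognorm = self.lognorm
        return self._expr

    def set_lognorm(self, lognorm: np.ndarray) -> None:
        lognorm = np.asarray(lognorm, dtype=float)
        if lognorm.shape != (len(self.gene_ids), self.n_spots):
            raise FormatError("lognorm layer shape does not match counts")
        self.lognorm = lognorm

    def set_age(self, ages) -> None:
        """Attach a per-spot (per-section) age label used for temporal trends."""
        self._expr.cell_meta["age"] = np.asarray(ages, dtype=object)
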