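"""Readers and writers for the plain-text formats the pipeline consumes.

10x triplet (MatrixMarket + features/barcodes TSV, optionally gzipped),
Visium tissue-positions CSV, GMT gene sets, and cell/point tables. Every
reader/writer pair is a bit-exact round trip for integer counts and
coordinates.
"""
from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .datatypes import ExpressionMatrix, FormatError, GeneSet, SpotGrid

__all__ = [
    "read_counts_10x",
    "write_counts_10x",
    "read_spot_grid",
    "write_spot_grid",
    "read_gene_sets",
    "write_gene_sets",
    "read_point_table",
]

log = logging.getLogger("nichetrack")

_POSITION_COLS = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FormatError(f"missing {stem}(.gz) in {dir_path}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_tsv_column(path: Path, col: int = 0) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[col] for line in fh if line.strip()]


def read_counts_10x(dir_path: str | Path) -> ExpressionMatrix:
    """Load a 10x triplet directory into a gene x cell ExpressionMatrix.

    Expects ``matrix.mtx(.gz)``, ``features.tsv(.gz)`` and
    ``barcodes.tsv(.gz)``; an optional ``cell_meta.csv`` keyed by barcode
    supplies per-cell metadata (missing columns are filled with "unknown").
    Genes are keyed by feature id (first column of features.tsv).
    """
    dir_path = Path(dir_path)
    with _open_text(_find(dir_path, "matrix.mtx")) as fh:
        try:
            counts = scipy.io.mmread(fh)
        except Exception as exc:  # malformed MatrixMarket header/body
            raise FormatError(f"cannot parse matrix.mtx: {exc}") from exc
    counts = sp.csr_matrix(counts)
    genes = _read_tsv_column(_find(dir_path, "features.tsv"), col=0)
    barcodes = _read_tsv_column(_find(dir_path, "barcodes.tsv"), col=0)
    if counts.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"MTX header declares {counts.shape} but features/barcodes give "
            f"({len(genes)}, {len(barcodes)})"
        )
    if len(set(barcodes)) != len(barcodes):
        raise FormatError("duplicate barcodes in barcodes.tsv")
    if len(set(genes)) != len(genes):
        # feature-id collisions resolved by suffixing so ids stay unique keys
        seen: dict[str, int] = {}
        out = []
        for g in genes:
            k = seen.get(g, 0)
            out.append(g if k == 0 else f"{g}.{k}")
            seen[g] = k + 1
        genes = out
        log.warning("duplicate feature ids resolved by suffixing")
    meta = None
    meta_path = dir_path / "cell_meta.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, dtype={0: str}).set_index("barcode")
    return ExpressionMatrix(gene_ids=genes, cell_ids=barcodes, counts=counts, cell_meta=meta)


def write_counts_10x(m: ExpressionMatrix, dir_path: str | Path) -> None:
    """Write the counts of ``m`` as an uncompressed 10x triplet directory."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(dir_path / "matrix.mtx", sp.coo_matrix(m.counts.astype(int)), field="integer")
    with open(dir_path / "features.tsv", "w") as fh:
        for g in m.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(dir_path / "barcodes.tsv", "w") as fh:
        fh.write("".join(f"{b}\n" for b in m.cell_ids))
    meta = m.cell_meta.reset_index().rename(columns={"cell_id": "barcode"})
    meta.to_csv(dir_path / "cell_meta.csv", index=False)


def read_spot_grid(positions_csv: str | Path, counts_dir: str | Path) -> SpotGrid:
    """Load a Visium-style spot grid (tissue-positions CSV + 10x triplet counts).

    Only ``in_tissue == 1`` spots are retained; pixel coordinates pass through
    unchanged; an optional ``region`` column defaults to "other". The counts
    matrix is transposed into the package's gene-major orientation on load.
    """
    positions_csv = Path(positions_csv)
    with _open_text(positions_csv) as fh:
        first = fh.readline()
    has_header = first.split(",")[0].strip().lower() == "barcode"
    pos = pd.read_csv(
        positions_csv,
        header=0 if has_header else None,
        names=None if has_header else _POSITION_COLS,
        dtype={"barcode": str},
    )
    missing = [c for c in _POSITION_COLS if c not in pos.columns]
    if missing:
        raise FormatError(f"positions CSV missing columns {missing}")
    pos = pos[pos["in_tissue"] == 1].reset_index(drop=True)
    if pos.duplicated(["array_row", "array_col"]).any():
        raise FormatError("duplicate (array_row, array_col) pairs in positions file")
    expr = read_counts_10x(counts_dir)
    known = set(pos["barcode"])
    orphan = [b for b in expr.cell_ids if b not in known]
    if orphan:
        raise FormatError(f"barcodes in counts absent from positions: {orphan[:5]}")
    pos = pos.set_index("barcode").loc[expr.cell_ids]
    region = pos["region"].to_numpy(dtype=object) if "region" in pos.columns else None
    return SpotGrid(
        spot_ids=list(expr.cell_ids),
        array_row=pos["array_row"].to_numpy(),
        array_col=pos["array_col"].to_numpy(),
        pixel_xy=pos[["pxl_col", "pxl_row"]].to_numpy(float),
        gene_ids=list(expr.gene_ids),
        counts=expr.counts,
        region=region,
    )


def write_spot_grid(grid: SpotGrid, positions_csv: str | Path, counts_dir: str | Path) -> None:
    pos = pd.DataFrame(
        {
            "barcode": grid.spot_ids,
            "in_tissue": 1,
            "array_row": grid.array_row,
            "array_col": grid.array_col,
            "pxl_row": grid.pixel_xy[:, 1],
            "pxl_col": grid.pixel_xy[:, 0],
            "region": grid.region,
        }
    )
    pos.to_csv(positions_csv, index=False)
    write_counts_10x(grid.as_expression(), counts_dir)


def read_gene_sets(gmt_path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: name, description, then tab-separated genes.

    Duplicate genes within a line are de-duplicated preserving first
    occurrence; a line with fewer than three fields is a format error.
    """
    sets: list[GeneSet] = []
    with _open_text(Path(gmt_path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno} has fewer than 3 fields")
            name, _desc, *genes = parts
            sets.append(GeneSet(name=name, genes=tuple(dict.fromkeys(g for g in genes if g))))
    return sets


def write_gene_sets(sets: list[GeneSet], gmt_path: str | Path, description: str = "nichetrack") -> None:
    with open(gmt_path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *s.genes]) + "\n")


def read_point_table(csv_path: str | Path) -> pd.DataFrame:
    """Read a 2-D cell point table with columns x, y and binary label columns."""
    df = pd.read_csv(csv_path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise FormatError(f"point table missing column {col!r}")
    return df
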