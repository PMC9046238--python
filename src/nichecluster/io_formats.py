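"""Containers and file formats for multi-dataset single-cell count data.

The package works on a gene x cell integer count matrix plus per-cell
metadata (dataset of origin, optional reference label) and per-gene QC
flags (mitochondrial / immunoglobulin).  Counts are kept as integers so
that downstream rank tests see exact ties; normalized layers are float64.

Supported external formats
--------------------------
* 10x-style Matrix Market triplets (``matrix.mtx`` + ``features.tsv`` +
  ``barcodes.tsv``; genes as rows, 1-based indices).
* Dense CSV (genes as rows, cells as columns).
* Metadata / partition / report tables as TSV; reports also as JSON.
* YAML config files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger("nichecluster")

#: Default gene-symbol prefixes used to flag QC-relevant gene classes.
#: Mouse symbols are capitalised ("mt-Co1", "Ighm"); human are upper-case.
DEFAULT_MITO_PREFIXES = ("mt-", "MT-")
DEFAULT_IG_PREFIXES = ("Igh", "Igk", "Igl", "IGH", "IGK", "IGL")


def configure_logging(verbose: bool = False) -> None:
    """Send structured log lines to stderr; ``verbose`` lowers level to DEBUG."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Genes x cells counts with per-cell metadata and per-gene QC flags.

    Attributes
    ----------
    gene_ids, cell_ids
        Unique identifiers; row/column order of ``counts``.
    counts
        Non-negative integer matrix, genes x cells (CSR sparse).
    norm
        Optional normalized layer with identical shape/ordering (float64).
    cell_meta
        Per-cell table indexed by ``cell_ids``; must contain ``dataset_id``
        and may contain ``label``.
    gene_flags
        Per-gene booleans ``is_mito`` and ``is_ig`` indexed by ``gene_ids``.
    """

    gene_ids: list[str]
    cell_ids: list[str]
    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_flags: pd.DataFrame
    norm: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.norm is not None:
            self.norm = sp.csr_matrix(self.norm, dtype=np.float64)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        dup_g = _duplicates(self.gene_ids)
        if dup_g:
            raise ValidationError(f"duplicate gene ids: {sorted(dup_g)[:10]}")
        dup_c = _duplicates(self.cell_ids)
        if dup_c:
            raise ValidationError(f"duplicate cell barcodes: {sorted(dup_c)[:10]}")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.gene_ids)}, {len(self.cell_ids)})"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")
        if self.norm is not None and self.norm.shape != self.counts.shape:
            raise ValidationError("norm layer shape differs from counts")
        if len(self.cell_meta) != len(self.cell_ids):
            raise ValidationError("cell_meta row count != number of cells")
        if "dataset_id" not in self.cell_meta.columns:
            raise ValidationError("cell_meta lacks dataset_id column")
        for col in ("is_mito", "is_ig"):
            if col not in self.gene_flags.columns:
                raise ValidationError(f"gene_flags lacks {col} column")

    # -- convenience --------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def dataset_ids(self) -> np.ndarray:
        return self.cell_meta["dataset_id"].to_numpy()

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:10]}")
        return np.array([pos[g] for g in genes], dtype=int)

    def cell_index(self, cells: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        missing = [c for c in cells if c not in pos]
        if missing:
            raise KeyError(f"cells not in dataset: {missing[:10]}")
        return np.array([pos[c] for c in cells], dtype=int)

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionDataset":
        idx = self.cell_index(cells)
        return ExpressionDataset(
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in idx],
            counts=self.counts[:, idx],
            norm=None if self.norm is None else self.norm[:, idx],
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_flags=self.gene_flags,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        idx = self.gene_index(genes)
        return ExpressionDataset(
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=list(self.cell_ids),
            counts=self.counts[idx, :],
            norm=None if self.norm is None else self.norm[idx, :],
            cell_meta=self.cell_meta,
            gene_flags=self.gene_flags.iloc[idx],
        )

    def split_by_dataset(self) -> dict[str, "ExpressionDataset"]:
        out = {}
        for did in pd.unique(self.cell_meta["dataset_id"]):
            cells = [c for c, d in zip(self.cell_ids, self.dataset_ids) if d == did]
            out[str(did)] = self.subset_cells(cells)
        return out

    def norm_dense(self, gene_rows: np.ndarray | None = None) -> np.ndarray:
        if self.norm is None:
            raise ValidationError("normalized layer missing; run normalize() first")
        m = self.norm if gene_rows is None else self.norm[gene_rows, :]
        return np.asarray(m.todense(), dtype=np.float64)


@dataclass
class Partition:
    """A flat cluster assignment: one label per cell (dotted names allowed)."""

    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.cell_ids) != len(self.labels):
            raise ValidationError("cell_ids and labels differ in length")
        dup = _duplicates(self.cell_ids)
        if dup:
            raise ValidationError(f"duplicate cells in partition: {sorted(dup)[:10]}")

    def as_series(self) -> pd.Series:
        return pd.Series(list(self.labels), index=list(self.cell_ids), name="cluster")

    def cluster_names(self) -> list[str]:
        return sorted(set(self.labels))

    def members(self, name: str) -> list[str]:
        return [c for c, l in zip(self.cell_ids, self.labels) if l == name]

    def label_of(self) -> dict[str, str]:
        return dict(zip(self.cell_ids, self.labels))


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def compute_gene_flags(
    gene_ids: Sequence[str],
    mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
    ig_prefixes: Sequence[str] = DEFAULT_IG_PREFIXES,
) -> pd.DataFrame:
    """Flag mitochondrial / immunoglobulin genes by case-sensitive prefix."""
    is_mito = [any(g.startswith(p) for p in mito_prefixes) for g in gene_ids]
    is_ig = [any(g.startswith(p) for p in ig_prefixes) for g in gene_ids]
    return pd.DataFrame(
        {"is_mito": is_mito, "is_ig": is_ig}, index=list(gene_ids)
    )


def concat_datasets(datasets: Sequence[ExpressionDataset]) -> ExpressionDataset:
    """Column-concatenate datasets sharing an identical gene universe."""
    if not datasets:
        raise ValidationError("no datasets to concatenate")
    ref_genes = datasets[0].gene_ids
    for ds in datasets[1:]:
        if ds.gene_ids != ref_genes:
            raise ValidationError("datasets do not share an identical gene list")
    counts = sp.hstack([ds.counts for ds in datasets], format="csr")
    norms = [ds.norm for ds in datasets]
    norm = None
    if all(n is not None for n in norms):
        norm = sp.hstack(norms, format="csr")
    meta = pd.concat([ds.cell_meta for ds in datasets], axis=0)
    cell_ids = [c for ds in datasets for c in ds.cell_ids]
    return ExpressionDataset(
        gene_ids=list(ref_genes),
        cell_ids=cell_ids,
        counts=counts,
        norm=norm,
        cell_meta=meta,
        gene_flags=datasets[0].gene_flags,
    )


# ---------------------------------------------------------------------------
# Counts I/O
# ---------------------------------------------------------------------------

def read_counts(
    path: str | Path,
    fmt: str = "mtx10x",
    dataset_id: str = "dataset1",
    mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
    ig_prefixes: Sequence[str] = DEFAULT_IG_PREFIXES,
) -> ExpressionDataset:
    """Read a count matrix from disk.

    ``mtx10x``: *path* is a directory holding ``matrix.mtx`` (1-based
    Matrix Market triplets, genes as rows), ``features.tsv`` (one gene id
    per line, first column used) and ``barcodes.tsv``.
    ``csv``: *path* is a dense CSV with genes as rows (index) and cells as
    columns (header).
    """
    path = Path(path)
    if fmt == "mtx10x":
        if not path.is_dir():
            raise FileNotFoundError(f"mtx10x expects a directory: {path}")
        mtx = path / "matrix.mtx"
        feat = path / "features.tsv"
        barc = path / "barcodes.tsv"
        for f in (mtx, feat, barc):
            if not f.exists():
                raise FileNotFoundError(f"missing {f.name} in {path}")
        counts = sp.csr_matrix(scipy.io.mmread(mtx))
        features = pd.read_csv(feat, sep="\t", header=None)
        gene_ids = features.iloc[:, 0].astype(str).tolist()
        cell_ids = (
            pd.read_csv(barc, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
        )
    elif fmt == "csv":
        if not path.exists():
            raise FileNotFoundError(str(path))
        df = pd.read_csv(path, index_col=0)
        gene_ids = df.index.astype(str).tolist()
        cell_ids = df.columns.astype(str).tolist()
        counts = sp.csr_matrix(df.to_numpy())
    else:
        raise ValueError(f"unknown counts format: {fmt}")

    counts = counts.astype(np.int64)
    meta = pd.DataFrame({"dataset_id": dataset_id}, index=cell_ids)
    flags = compute_gene_flags(gene_ids, mito_prefixes, ig_prefixes)
    ds = ExpressionDataset(
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        counts=counts,
        cell_meta=meta,
        gene_flags=flags,
    )
    logger.debug("read %d genes x %d cells from %s (%s)", ds.n_genes, ds.n_cells, path, fmt)
    return ds


def write_counts(ds: ExpressionDataset, path: str | Path, fmt: str = "mtx10x") -> None:
    """Write counts in a format :func:`read_counts` reads back identically."""
    path = Path(path)
    if fmt == "mtx10x":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(ds.counts), field="integer")
        with open(path / "features.tsv", "w") as fh:
            for g in ds.gene_ids:
                fh.write(f"{g}\n")
        with open(path / "barcodes.tsv", "w") as fh:
            for c in ds.cell_ids:
                fh.write(f"{c}\n")
    elif fmt == "csv":
        df = pd.DataFrame(
            np.asarray(ds.counts.todense()), index=ds.gene_ids, columns=ds.cell_ids
        )
        df.to_csv(path)
    else:
        raise ValueError(f"unknown counts format: {fmt}")


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    """Read a per-cell metadata TSV (first column = cell id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_cell_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index_label="cell_id")


def read_partition(path: str | Path) -> Partition:
    """Read a 2-column TSV (cell_id, cluster) into a :class:`Partition`."""
    df = pd.read_csv(path, sep="\t")
    return Partition(
        cell_ids=df.iloc[:, 0].astype(str).tolist(),
        labels=df.iloc[:, 1].astype(str).tolist(),
    )


def write_partition(part: Partition, path: str | Path) -> None:
    pd.DataFrame({"cell_id": part.cell_ids, "cluster": part.labels}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Generic report I/O (TSV / JSON, floats at 6 significant digits)
# ---------------------------------------------------------------------------

def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_report(obj: Any, path: str | Path, fmt: str = "tsv") -> None:
    """Serialize a report object deterministically.

    TSV requires a DataFrame (or an object exposing ``to_frame()``); JSON
    accepts any dataclass / mapping / frame.  Floats are written at 6
    significant digits; key and column order is the object's own order.
    """
    path = Path(path)
    if fmt == "tsv":
        frame = obj
        if not isinstance(frame, pd.DataFrame):
            if hasattr(obj, "to_frame"):
                frame = obj.to_frame()
            else:
                raise TypeError(f"cannot write {type(obj).__name__} as TSV")
        frame = frame.copy()
        for col in frame.columns:
            if pd.api.types.is_float_dtype(frame[col]):
                frame[col] = frame[col].map(lambda v: _round_sig(float(v)))
        frame.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(_jsonable(obj), fh, indent=1, sort_keys=False)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format: {fmt}")


def load_config(path: str | Path) -> dict:
    """Load a YAML config file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
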