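"""Per-dataset quality filtering, normalization and variable-gene selection.

QC follows the two-species convention used for bone-marrow niche data:
mouse datasets drop cells outside the 10th/90th quantiles of detected
features and total counts and above 5% mitochondrial content; human
datasets additionally allow a 10% mitochondrial and a 10% immunoglobulin
ceiling (B-cell contamination guard).  Quantiles use linear interpolation
(type 7) and boundary cells are retained.

Normalization is library-size log-normalization,
``norm = log(1 + count * scale / total)``, exposed behind a pluggable
interface so an externally normalized layer can be attached instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import ExpressionDataset, ValidationError, logger


@dataclass
class QCThresholds:
    """Cell-level QC thresholds, applied per dataset of origin.

    q_low / q_high bound both the number of detected features and the
    total counts per cell (inclusive); mito_max / ig_max cap the fraction
    of counts in flagged gene classes.  ``ig_max=None`` disables the
    immunoglobulin filter (mouse default).
    """

    q_low: float = 0.10
    q_high: float = 0.90
    mito_max: float = 0.05
    ig_max: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_low < self.q_high <= 1.0):
            raise ValidationError("need 0 <= q_low < q_high <= 1")
        for v in (self.mito_max, self.ig_max):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError("fraction thresholds must lie in [0, 1]")

    @classmethod
    def mouse(cls) -> "QCThresholds":
        return cls(mito_max=0.05, ig_max=None)

    @classmethod
    def human(cls) -> "QCThresholds":
        return cls(mito_max=0.10, ig_max=0.10)


def cell_qc_metrics(ds: ExpressionDataset) -> pd.DataFrame:
    """Per-cell totals, detected features and flagged-class fractions."""
    counts = ds.counts.tocsc()
    total = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    n_feat = np.asarray((counts > 0).sum(axis=0)).ravel().astype(int)
    mito_rows = ds.gene_flags["is_mito"].to_numpy()
    ig_rows = ds.gene_flags["is_ig"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito = np.where(
            total > 0,
            np.asarray(counts[mito_rows, :].sum(axis=0)).ravel() / np.maximum(total, 1e-12),
            0.0,
        )
        ig = np.where(
            total > 0,
            np.asarray(counts[ig_rows, :].sum(axis=0)).ravel() / np.maximum(total, 1e-12),
            0.0,
        )
    return pd.DataFrame(
        {
            "cell_id": ds.cell_ids,
            "dataset_id": ds.dataset_ids,
            "total_counts": total,
            "n_features": n_feat,
            "pct_mito": mito,
            "pct_ig": ig,
        }
    )


def qc_filter(
    ds: ExpressionDataset, th: QCThresholds | None = None
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Filter cells per dataset; return (filtered dataset, QC table).

    A cell is retained iff, within its own dataset of origin, its number
    of detected features AND its total counts both lie inside the
    [q_low, q_high] quantile interval (inclusive), its mitochondrial
    fraction is <= mito_max, and (if configured) its immunoglobulin
    fraction is <= ig_max.  Both quantile filters are computed on the
    unfiltered dataset.
    """
    if ds.n_cells == 0:
        raise ValidationError("empty dataset")
    th = th or QCThresholds()
    qc = cell_qc_metrics(ds)

    keep = np.ones(ds.n_cells, dtype=bool)
    reasons = [[] for _ in range(ds.n_cells)]
    for did, grp in qc.groupby("dataset_id", sort=False):
        idx = grp.index.to_numpy()
        for col, tag in (("n_features", "features"), ("total_counts", "counts")):
            vals = grp[col].to_numpy(dtype=float)
            lo = np.quantile(vals, th.q_low)  # linear interpolation (type 7)
            hi = np.quantile(vals, th.q_high)
            bad = (vals < lo) | (vals > hi)
            for i in idx[bad]:
                reasons[i].append(f"{tag}_quantile")
            keep[idx] &= ~bad
    bad_mito = qc["pct_mito"].to_numpy() > th.mito_max
    for i in np.flatnonzero(bad_mito):
        reasons[i].append("mito")
    keep &= ~bad_mito
    if th.ig_max is not None:
        bad_ig = qc["pct_ig"].to_numpy() > th.ig_max
        for i in np.flatnonzero(bad_ig):
            reasons[i].append("ig")
        keep &= ~bad_ig

    qc["pass"] = keep
    qc["fail_reasons"] = [";".join(r) for r in reasons]
    kept_cells = [c for c, k in zip(ds.cell_ids, keep) if k]
    if not kept_cells:
        logger.warning("qc_filter removed every cell")
        out = ds.subset_cells([])
    else:
        out = ds.subset_cells(kept_cells)
    logger.info("qc_filter kept %d / %d cells", len(kept_cells), ds.n_cells)
    return out, qc


# ---------------------------------------------------------------------------
# Normalization (pluggable)
# ---------------------------------------------------------------------------

Normalizer = Callable[[ExpressionDataset], ExpressionDataset]


def normalize(ds: ExpressionDataset, scale: float = 10_000.0) -> ExpressionDataset:
    """Attach ``norm = log(1 + count * scale / total_counts_of_cell)``.

    Counts are left untouched.  Zero-total cells are an error (they carry
    no information and break the scaling); filter first.
    """
    total = np.asarray(ds.counts.sum(axis=0)).ravel().astype(float)
    zero = np.flatnonzero(total == 0)
    if zero.size:
        names = [ds.cell_ids[i] for i in zero[:10]]
        raise ValidationError(f"cells with zero total counts: {names}")
    csc = ds.counts.tocsc().astype(np.float64)
    # scale columns, then log1p; sparsity pattern is preserved
    inv = sp.diags(scale / total)
    norm = csc @ inv
    norm.data = np.log1p(norm.data)
    ds.norm = sp.csr_matrix(norm)
    return ds


def attach_norm(ds: ExpressionDataset, norm: sp.spmatrix | np.ndarray) -> ExpressionDataset:
    """Attach an externally computed normalized layer (same shape as counts)."""
    norm = sp.csr_matrix(norm, dtype=np.float64)
    if norm.shape != ds.counts.shape:
        raise ValidationError("norm layer shape differs from counts")
    ds.norm = norm
    return ds


# ---------------------------------------------------------------------------
# Most-variable genes
# ---------------------------------------------------------------------------

def select_mvg(
    ds: ExpressionDataset,
    n: int = 3000,
    n_bins: int = 20,
    exclude_flagged: bool = True,
) -> list[str]:
    """Top-``n`` genes by standardized dispersion of the normalized layer.

    Dispersion = variance / mean of ``norm`` per gene; genes are grouped
    into ``n_bins`` equal-frequency mean bins and the dispersion is
    z-scored within each bin, so highly expressed genes do not dominate.
    Zero-variance genes rank last; mitochondrial/immunoglobulin genes are
    excluded by default (their per-cell content is a technical covariate,
    not biology to cluster on).  ``n`` larger than the gene count returns
    every eligible gene, ordered.
    """
    if ds.norm is None:
        raise ValidationError("normalized layer missing; run normalize() first")
    if exclude_flagged:
        flagged = ds.gene_flags["is_mito"] | ds.gene_flags["is_ig"]
        if flagged.any():
            ds = ds.subset_genes([g for g, f in flagged.items() if not f])
    X = ds.norm.tocsr()
    n_cells = ds.n_cells
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * (n_cells / max(n_cells - 1, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    # equal-frequency mean bins; z-score dispersion within each bin
    order = np.argsort(mean, kind="stable")
    bins = np.empty(len(mean), dtype=int)
    bins[order] = np.minimum(
        (np.arange(len(mean)) * n_bins) // max(len(mean), 1), n_bins - 1
    )
    # robust within-bin standardization (median/MAD): a bin that happens to
    # contain many genuinely variable genes must not absorb its own signal
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        sel = bins == b
        d = disp[sel]
        med = np.median(d)
        mad = np.median(np.abs(d - med))
        scale = 1.4826 * mad if mad > 0 else (d.std() if d.std() > 0 else 1.0)
        z[sel] = (d - med) / scale
    z = np.where(var > 0, z, -np.inf)  # constant genes never selected

    ranked = np.argsort(-z, kind="stable")
    top = ranked[: min(n, ds.n_genes)]
    return [ds.gene_ids[i] for i in top]
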