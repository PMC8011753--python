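"""Transcriptome quality control and normalisation.

High-quality droplets are separated from ambient barcodes with a
barcode-rank knee rule: with n set to 1% of the expected recovered cell
count, every barcode whose total UMI count exceeds 10% of the n-th ranked
barcode is kept, so retained cells sit within an order of magnitude of the
top of the rank curve.  Retained cells are then screened for outliers on
three metrics (mitochondrial fraction, genes detected, total UMIs) at 3
median absolute deviations, and counts are depth-normalised and
log-transformed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import median_abs_deviation

from .io_formats import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Cells x genes log-normalised expression with its scale factor."""

    matrix: sparse.csr_matrix
    barcodes: list[str]
    features: list[str]
    scale_factor: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def gene_values(self, gene: str) -> np.ndarray:
        j = self.features.index(gene)
        return np.asarray(self.matrix[:, j].todense()).ravel()


def qc_metrics(cm: CountMatrix, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell totals, genes detected, and mitochondrial count fraction.

    Mitochondrial genes are identified by feature-name prefix (case
    insensitive; default the mouse convention ``mt-``).
    """
    totals = cm.row_totals()
    n_genes = np.asarray((cm.matrix > 0).sum(axis=1)).ravel()
    mito_mask = np.array(
        [f.lower().startswith(mito_prefix.lower()) for f in cm.features]
    )
    mito_counts = np.asarray(cm.matrix[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
    return pd.DataFrame(
        {
            "total_counts": totals,
            "n_genes": n_genes,
            "mito_frac": mito_frac,
        },
        index=pd.Index(cm.barcodes, name="cell_barcode"),
    )


def knee_filter(total_counts: pd.Series, expected_cells: int) -> pd.Index:
    """Barcode-rank knee rule for high-quality droplets.

    ``n = ceil(0.01 * expected_cells)``; the threshold is 10% of the
    n-th-ranked barcode's total and barcodes strictly above it are kept.
    Output order follows input order (the rule is order-invariant).
    """
    if expected_cells < 100:
        raise ValueError("expected_cells must be >= 100 so that n >= 1")
    totals = pd.Series(total_counts)
    n = math.ceil(0.01 * expected_cells)
    if len(totals) < n:
        raise ValueError(
            f"only {len(totals)} barcodes but the knee rule needs the "
            f"{n}-th ranked barcode"
        )
    nth = np.sort(totals.to_numpy())[::-1][n - 1]
    threshold = 0.1 * nth
    return totals.index[totals > threshold]


def mad_outlier_filter(
    metrics: pd.DataFrame,
    n_mads: float = 3.0,
) -> pd.Series:
    """Boolean keep-mask removing 3-MAD outliers on the QC metrics.

    A cell is removed when its mitochondrial fraction is high
    (``> median + n_mads * MAD``) or its log1p total counts or log1p genes
    detected are low (``< median - n_mads * MAD``).  MADs use the normal
    consistency constant 1.4826; a zero MAD disables that metric with a
    logged warning.
    """
    if len(metrics) < 10:
        raise ValueError("need at least 10 cells for MAD-based QC")
    keep = pd.Series(True, index=metrics.index)
    checks = [
        ("mito_frac", metrics["mito_frac"].to_numpy(float), "high"),
        ("total_counts", np.log1p(metrics["total_counts"].to_numpy(float)), "low"),
        ("n_genes", np.log1p(metrics["n_genes"].to_numpy(float)), "low"),
    ]
    for name, values, side in checks:
        med = float(np.median(values))
        mad = float(median_abs_deviation(values, scale="normal"))
        if mad == 0.0:
            logger.warning("mad_outlier_filter: MAD of %s is 0; metric skipped", name)
            continue
        if side == "high":
            bad = values > med + n_mads * mad
        else:
            bad = values < med - n_mads * mad
        keep &= ~bad
    return keep


def lognormalize(cm: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Depth-normalise and log-transform: ``ln(1 + count * scale / cell_total)``.

    Zero-total cells are an error; they should have been removed by QC.
    """
    totals = cm.row_totals().astype(float)
    if np.any(totals <= 0):
        raise ValueError("cells with zero total counts; run QC filtering first")
    mat = sparse.csr_matrix(cm.matrix, dtype=float, copy=True)
    scale = scale_factor / totals
    mat = sparse.diags(scale) @ mat
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(
        sparse.csr_matrix(mat), list(cm.barcodes), list(cm.features), scale_factor
    )
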