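"""Simulation-based power analysis for detecting cis-regulatory expression loss.

Given the log-normalised expression profile of an unperturbed control
population and a gRNA's expected monoallelic / biallelic loss fractions,
the framework predicts the p-value achievable when testing for loss of a
target gene's expression as a function of its baseline expression and the
number of treatment cells:

1. genes are divided into buckets (default 10) by mean log-normalised
   baseline expression;
2. for each bucket, a gene is drawn at random and a treatment population
   of ``n_treat`` cells is resampled from the control population, with a
   fraction ``f_full`` of cells set to zero expression (biallelic loss)
   and ``f_mono`` halved (monoallelic loss);
3. treatment is tested against the full control by two-sided Wilcoxon
   rank-sum; p-values are Bonferroni-adjusted either for all genes or,
   after independent filtering, only for genes whose mean baseline
   expression reaches the bucket's minimum;
4. the procedure is repeated (default 100 reps) and summarised (default
   median), yielding a bucket x n_treat p-value grid from which the
   minimum number of cells required for significance is read off.

Randomness is driven by one master seed with per-(rep, bucket) substreams;
within a rep, cell draws for larger ``n_treat`` extend those for smaller
ones (common random numbers), so grids are bit-reproducible and power is
monotone in ``n_treat`` up to Monte-Carlo noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .cell_qc import NormalizedMatrix
from .diffexp import rank_sum_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LossProfile:
    """Fractions of treatment cells with monoallelic (halved) and
    biallelic (zeroed) loss of target-gene expression."""

    f_mono: float
    f_full: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_mono <= 1.0 and 0.0 <= self.f_full <= 1.0):
            raise ValueError("loss fractions must be in [0, 1]")
        if self.f_mono + self.f_full > 1.0:
            raise ValueError("f_mono + f_full must not exceed 1")

    @property
    def expected_mean_ratio(self) -> float:
        """Expected treatment/control mean: 1 - f_full - f_mono/2."""
        return 1.0 - self.f_full - self.f_mono / 2.0


@dataclass
class ControlProfile:
    """Log-normalised cells x genes matrix of an unperturbed population."""

    matrix: np.ndarray
    genes: list[str]
    gene_means: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if sparse.issparse(self.matrix):
            self.matrix = np.asarray(self.matrix.todense(), dtype=float)
        else:
            self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.genes):
            raise ValueError("matrix must be cells x genes matching the gene list")
        if self.matrix.size and self.matrix.min() < 0:
            raise ValueError("log-normalised values must be nonnegative")
        self.gene_means = self.matrix.mean(axis=0)
        if not np.all(np.isfinite(self.gene_means)):
            raise ValueError("gene means must be finite")

    @classmethod
    def from_normalized(cls, norm: NormalizedMatrix) -> "ControlProfile":
        return cls(norm.matrix, list(norm.features))

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def gene_values(self, j: int) -> np.ndarray:
        return self.matrix[:, j]


@dataclass
class GeneBucket:
    index: int
    gene_indices: np.ndarray
    mean_range: tuple[float, float]
    min_gene_index: int  # lowest-expression gene in the bucket


def bucket_genes(
    control: ControlProfile,
    n_buckets: int = 10,
    mode: str = "quantile",
) -> list[GeneBucket]:
    """Partition genes into contiguous baseline-expression buckets.

    ``quantile`` (default) gives equal-count buckets; ``width`` gives
    equal-width intervals of mean expression, merging empty buckets into
    their lower neighbour with a logged warning.  Bucket 0 holds the
    lowest-expressed genes.
    """
    means = control.gene_means
    if (means > 0).sum() < n_buckets:
        raise ValueError(f"need at least {n_buckets} genes with nonzero mean")
    if len(np.unique(means)) == 1:
        logger.warning("bucket_genes: all gene means equal; single effective bucket")
    order = np.argsort(means, kind="stable")
    if mode == "quantile":
        groups = [g for g in np.array_split(order, n_buckets) if len(g)]
    elif mode == "width":
        edges = np.linspace(means.min(), means.max(), n_buckets + 1)
        labels = np.clip(np.digitize(means, edges[1:-1]), 0, n_buckets - 1)
        groups = []
        for b in range(n_buckets):
            idx = order[np.isin(order, np.flatnonzero(labels == b))]
            if len(idx) == 0:
                logger.warning("bucket_genes: empty width bucket %d merged", b)
                continue
            groups.append(idx)
    else:
        raise ValueError(f"unknown bucketing mode {mode!r}")
    buckets = []
    for b, idx in enumerate(groups):
        sub_means = means[idx]
        buckets.append(
            GeneBucket(
                index=b,
                gene_indices=np.asarray(idx),
                mean_range=(float(sub_means.min()), float(sub_means.max())),
                min_gene_index=int(idx[np.argmin(sub_means)]),
            )
        )
    return buckets


def filtered_test_count(control: ControlProfile, bucket: GeneBucket) -> int:
    """Independent-filtering family size m_b: genes whose mean baseline
    expression reaches the bucket's minimum-expression gene."""
    min_mean = control.gene_means[bucket.min_gene_index]
    return int(np.sum(control.gene_means >= min_mean))


def _apply_loss(values: np.ndarray, u: np.ndarray, loss: LossProfile) -> np.ndarray:
    out = values.astype(float).copy()
    full = u < loss.f_full
    mono = (~full) & (u < loss.f_full + loss.f_mono)
    out[full] = 0.0
    out[mono] *= 0.5
    return out


def simulate_loss(
    control_values: np.ndarray,
    n_treat: int,
    loss: LossProfile,
    rng: np.random.Generator,
) -> np.ndarray:
    """Resample ``n_treat`` cells with replacement and inject loss.

    Each sampled cell is independently labelled full-loss with probability
    ``f_full`` (expression zeroed), monoallelic with probability ``f_mono``
    (expression halved), and unchanged otherwise.
    """
    control_values = np.asarray(control_values, dtype=float)
    if n_treat < 1:
        raise ValueError("n_treat must be >= 1")
    if control_values.size == 0:
        raise ValueError("control_values must be non-empty")
    idx = rng.integers(0, control_values.size, size=n_treat)
    u = rng.random(n_treat)
    return _apply_loss(control_values[idx], u, loss)


@dataclass
class PowerGrid:
    """Bucket x treatment-size grid of summarised p-values.

    ``p_raw`` / ``p_adj_all`` / ``p_adj_filtered`` have shape
    (n_buckets, len(n_treat_grid)); ``rep_p_raw`` keeps the per-rep raw
    p-values (reps x buckets x grid) for diagnostics.
    """

    buckets: list[GeneBucket]
    n_treat_grid: np.ndarray
    p_raw: np.ndarray
    p_adj_all: np.ndarray
    p_adj_filtered: np.ndarray
    m_b: np.ndarray
    m_all: int
    reps: int
    summary: str
    rep_p_raw: np.ndarray
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for bi, bucket in enumerate(self.buckets):
            lo, hi = bucket.mean_range
            for ti, n_treat in enumerate(self.n_treat_grid):
                rows.append(
                    {
                        "bucket": bucket.index,
                        "bucket_mean_lo": lo,
                        "bucket_mean_hi": hi,
                        "n_treat": int(n_treat),
                        "p_raw": self.p_raw[bi, ti],
                        "p_adj_all": self.p_adj_all[bi, ti],
                        "p_adj_filtered": self.p_adj_filtered[bi, ti],
                        "m_b": int(self.m_b[bi]),
                    }
                )
        return pd.DataFrame(rows)


_SUMMARIES = {
    "median": lambda p, axis: np.median(p, axis=axis),
    "mean": lambda p, axis: np.mean(p, axis=axis),
    "rejection": lambda p, axis: np.mean(p < 0.05, axis=axis),
}


def power_curve(
    control: ControlProfile,
    loss: LossProfile,
    n_treat_grid: Sequence[int],
    *,
    n_buckets: int = 10,
    reps: int = 100,
    seed: int = 0,
    summary: str = "median",
    bucket_mode: str = "quantile",
) -> PowerGrid:
    """Run the full power simulation and summarise p-values over reps.

    For every (rep, bucket, n_treat): draw one gene uniformly from the
    bucket, resample the treatment population, inject loss, and rank-sum
    test it against the full control population for that gene.  Adjusted
    p-values multiply by the all-genes family size (``m_all``) or the
    bucket's independent-filtering family size (``m_b``), capped at 1.
    """
    grid = np.asarray(sorted(int(t) for t in n_treat_grid))
    if grid.min() < 3:
        raise ValueError("treatment sizes must be >= 3")
    if summary not in _SUMMARIES:
        raise ValueError(f"summary must be one of {sorted(_SUMMARIES)}")
    buckets = bucket_genes(control, n_buckets, bucket_mode)
    m_all = control.n_genes
    m_b = np.array([filtered_test_count(control, b) for b in buckets])
    max_n = int(grid.max())

    rep_p = np.ones((reps, len(buckets), len(grid)))
    for rep in range(reps):
        for bi, bucket in enumerate(buckets):
            rng = np.random.default_rng([seed, rep, bi])
            gene = int(rng.choice(bucket.gene_indices))
            ctrl_vals = control.gene_values(gene)
            idx = rng.integers(0, control.n_cells, size=max_n)
            u = rng.random(max_n)
            for ti, n_treat in enumerate(grid):
                treat = _apply_loss(ctrl_vals[idx[:n_treat]], u[:n_treat], loss)
                rep_p[rep, bi, ti] = rank_sum_test(treat, ctrl_vals)

    summarise = _SUMMARIES[summary]
    rep_adj_all = np.minimum(rep_p * m_all, 1.0)
    rep_adj_filt = np.minimum(rep_p * m_b[None, :, None], 1.0)
    return PowerGrid(
        buckets=buckets,
        n_treat_grid=grid,
        p_raw=summarise(rep_p, 0),
        p_adj_all=summarise(rep_adj_all, 0),
        p_adj_filtered=summarise(rep_adj_filt, 0),
        m_b=m_b,
        m_all=m_all,
        reps=reps,
        summary=summary,
        rep_p_raw=rep_p,
        seed=seed,
    )


def min_cells_required(
    grid: PowerGrid,
    alpha: float = 0.05,
    which: str = "all",
) -> dict[int, int | None]:
    """Smallest grid treatment size reaching significance per bucket.

    ``which`` selects the summarised surface: ``raw``, ``all`` (Bonferroni
    over all genes) or ``filtered`` (after independent filtering).  ``None``
    means no grid size achieves p < alpha (detection impossible on the
    tested range).
    """
    surfaces = {
        "raw": grid.p_raw,
        "all": grid.p_adj_all,
        "filtered": grid.p_adj_filtered,
    }
    if which not in surfaces:
        raise ValueError("which must be raw, all or filtered")
    surface = surfaces[which]
    out: dict[int, int | None] = {}
    for bi, bucket in enumerate(grid.buckets):
        hits = np.flatnonzero(surface[bi] < alpha)
        out[bucket.index] = int(grid.n_treat_grid[hits[0]]) if hits.size else None
    return out


def plot_power_grid(grid: PowerGrid, path=None, alpha: float = 0.05):
    """Contour-style heatmaps of the raw and adjusted p-value surfaces."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    surfaces = [
        ("raw", grid.p_raw),
        ("Bonferroni (all genes)", grid.p_adj_all),
        ("Bonferroni (filtered)", grid.p_adj_filtered),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(13, 4), sharey=True)
    mids = [np.mean(b.mean_range) for b in grid.buckets]
    for ax, (title, surface) in zip(axes, surfaces):
        with np.errstate(divide="ignore"):
            img = ax.pcolormesh(
                mids, grid.n_treat_grid, -np.log10(np.maximum(surface.T, 1e-300)),
                shading="nearest",
            )
        ax.contour(
            mids, grid.n_treat_grid, surface.T, levels=[alpha], colors="green",
            linestyles="dashed",
        )
        ax.set_title(title)
        ax.set_xlabel("bucket mean log-normalised expression")
        fig.colorbar(img, ax=ax, label="-log10 p")
    axes[0].set_ylabel("treatment cells")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
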