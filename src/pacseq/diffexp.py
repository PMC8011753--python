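"""Wilcoxon rank-sum differential expression with Bonferroni control.

Each gene is tested two-sided between a guide-bearing treatment population
and a control population on log-normalised values.  Small tie-free
problems (both groups below 8 cells) use the exact rank-sum distribution;
everything else uses the normal approximation with tie and continuity
corrections.  Family-wise error is controlled by Bonferroni at 0.05, and a
gene is "consistently differentially expressed" when it is significant
with the same direction across every population of gRNAs targeting the
same gene's cis-regulatory regions.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import mannwhitneyu

EXACT_MAX_N = 8  # exact enumeration up to this group size (tie-free only)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two samples.

    Exact when both groups have at most ``EXACT_MAX_N`` observations and
    the pooled values are tie-free; otherwise the tie-corrected normal
    approximation with continuity correction (worst-case error ~0.01 at
    the cross-over size, shrinking with n).  Fully tied pooled data yields
    p = 1 (no evidence of a shift).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    tie_free = len(np.unique(pooled)) == pooled.size
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    return float(
        mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True).pvalue
    )


def _to_dense(matrix) -> np.ndarray:
    if sparse.issparse(matrix):
        return np.asarray(matrix.todense(), dtype=float)
    return np.asarray(matrix, dtype=float)


def wilcoxon_de(
    treatment,
    control,
    genes: Sequence[str],
    *,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-gene two-sided rank-sum tests of treatment versus control.

    ``treatment`` and ``control`` are cells x genes matrices of
    log-normalised values over the same gene set.  Genes expressed in
    neither group are returned untested (``tested = False``, p-values NaN).
    Direction is the sign of the treatment-minus-control median shift
    (falling back to the mean shift when medians tie).
    """
    t = _to_dense(treatment)
    c = _to_dense(control)
    if t.shape[0] < min_cells or c.shape[0] < min_cells:
        raise ValueError(f"both groups need at least {min_cells} cells")
    if t.shape[1] != len(genes) or c.shape[1] != len(genes):
        raise ValueError("gene list does not match matrix width")
    rows = []
    for j, gene in enumerate(genes):
        tv, cv = t[:, j], c[:, j]
        if not (np.any(tv != 0) or np.any(cv != 0)):
            rows.append(
                {
                    "gene": gene,
                    "p_raw": np.nan,
                    "direction": 0,
                    "n_treatment": len(tv),
                    "n_control": len(cv),
                    "tested": False,
                }
            )
            continue
        shift = float(np.median(tv) - np.median(cv))
        if shift == 0.0:
            shift = float(np.mean(tv) - np.mean(cv))
        rows.append(
            {
                "gene": gene,
                "p_raw": rank_sum_test(tv, cv),
                "direction": int(np.sign(shift)),
                "n_treatment": len(tv),
                "n_control": len(cv),
                "tested": True,
            }
        )
    return pd.DataFrame(rows)


def bonferroni_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni family-wise adjustment: ``min(1, p * m)``.

    ``m`` defaults to the number of finite p-values but may be larger
    (e.g. all genes in the matrix including untested ones).
    """
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = int(np.sum(np.isfinite(p)))
    if m <= 0:
        raise ValueError("number of tests m must be positive")
    return np.minimum(p * m, 1.0)


def adjust_de_table(results: pd.DataFrame, m: int | None = None) -> pd.DataFrame:
    """Append a Bonferroni-adjusted column to a :func:`wilcoxon_de` table."""
    out = results.copy()
    if m is None:
        m = len(results)  # every gene in the matrix counts toward the family
    out["p_adj"] = bonferroni_adjust(out["p_raw"].to_numpy(), m)
    return out


def significant_genes(
    results: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Rows significant at Bonferroni-adjusted p <= alpha."""
    if "p_adj" not in results:
        raise ValueError("run adjust_de_table first")
    mask = results["tested"] & (results["p_adj"] <= alpha)
    return results.loc[mask]


def consistent_de(
    results_per_grna: Sequence[pd.DataFrame],
    alpha: float = 0.05,
    require_direction: bool = True,
) -> list[str]:
    """Genes significant in every gRNA population targeting the same gene.

    Intersection of the per-population significant sets; by default the
    direction of the shift must also agree across populations.
    """
    if len(results_per_grna) < 2:
        raise ValueError("need at least two gRNA populations")
    sig_sets = []
    directions: list[dict[str, int]] = []
    for res in results_per_grna:
        sig = significant_genes(res, alpha)
        sig_sets.append(set(sig["gene"]))
        directions.append(dict(zip(sig["gene"], sig["direction"])))
    common = set.intersection(*sig_sets)
    if require_direction:
        common = {
            g for g in common if len({d[g] for d in directions}) == 1
        }
    return sorted(common)
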