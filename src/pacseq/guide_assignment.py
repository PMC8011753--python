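"""Per-gRNA binomial mixture model and guide-to-cell assignment.

For each guide g independently, a cell's UMI count k_i for g out of its
total gRNA UMI count n_i is modelled as a two-component binomial mixture

    z_i ~ Bernoulli(pi_signal),    k_i | z_i ~ Binomial(n_i, p_{z_i}),

where the low-rate component captures counts arising from noise (mapping
artefacts, ambient molecules) and the high-rate component captures true
presence of the guide in the cell.  The fit is by EM, initialised from a
two-component Gaussian mixture on the raw count fractions k_i/n_i.  A
guide is called present in a cell when the posterior probability that its
count arose from the noise component is below a threshold (default 0.05).
Cells with exactly one present guide are assigned to it; the detection
rate is the fraction of high-quality cells that are assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, logsumexp
from sklearn.mixture import GaussianMixture

from .io_formats import CountMatrix

_EPS = 1e-6


@dataclass
class MixtureFit:
    """Fitted two-component binomial mixture for one guide.

    After fitting, components are ordered so ``p_noise < p_signal``.
    ``degenerate`` marks all-zero-count fits (no signal component; every
    cell called absent); ``low_support`` marks fits with fewer than
    ``min_cells`` nonzero-count cells.
    """

    guide_id: str | None
    p_noise: float
    p_signal: float
    pi_signal: float
    loglik_trace: np.ndarray
    converged: bool
    n_cells_used: int
    degenerate: bool = False
    low_support: bool = False


def _binom_logpmf(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    # log C(n,k) + k log p + (n-k) log(1-p), stable for p in (0,1)
    p = min(max(p, _EPS), 1.0 - _EPS)
    log_coef = -betaln(1.0 + n - k, 1.0 + k) - np.log(n + 1.0)
    return log_coef + k * np.log(p) + (n - k) * np.log1p(-p)


def _loglik(k: np.ndarray, n: np.ndarray, p0: float, p1: float, pi1: float) -> float:
    pi1 = min(max(pi1, _EPS), 1.0 - _EPS)
    comp = np.stack(
        [np.log1p(-pi1) + _binom_logpmf(k, n, p0), np.log(pi1) + _binom_logpmf(k, n, p1)]
    )
    return float(logsumexp(comp, axis=0).sum())


def fit_binomial_mixture(
    k: np.ndarray,
    n: np.ndarray,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    min_cells: int = 3,
    seed: int = 0,
    guide_id: str | None = None,
) -> MixtureFit:
    """Fit the two-component binomial mixture for one guide by EM.

    Parameters
    ----------
    k, n
        Per-cell guide UMI counts and total gRNA UMI counts, restricted to
        cells with ``n > 0`` (cells with n == 0 must be excluded upstream;
        they can never support presence).
    tol
        EM stops when the log-likelihood gain falls below this value.
    min_cells
        Minimum number of cells with k > 0 for a fully supported fit.
    seed
        Seed for the Gaussian-mixture initialisation.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if k.shape != n.shape:
        raise ValueError("k and n must have the same length")
    if np.any(n <= 0):
        raise ValueError("all cells must have total gRNA count n > 0")
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("counts must satisfy 0 <= k <= n")

    if not np.any(k > 0):
        return MixtureFit(
            guide_id, 0.0, 1.0, 0.0, np.array([]), True, len(k), degenerate=True
        )
    low_support = int(np.sum(k > 0)) < min_cells

    frac = k / n
    p0, p1, pi1 = _gmm_initialise(frac, seed)

    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # E step: responsibilities of the signal component
        log_noise = np.log1p(-min(max(pi1, _EPS), 1 - _EPS)) + _binom_logpmf(k, n, p0)
        log_signal = np.log(min(max(pi1, _EPS), 1 - _EPS)) + _binom_logpmf(k, n, p1)
        log_tot = np.logaddexp(log_noise, log_signal)
        trace.append(float(log_tot.sum()))
        r1 = np.exp(log_signal - log_tot)
        r0 = 1.0 - r1
        # M step: weighted closed-form updates
        p0 = float(np.clip(np.sum(r0 * k) / max(np.sum(r0 * n), _EPS), _EPS, 1 - _EPS))
        p1 = float(np.clip(np.sum(r1 * k) / max(np.sum(r1 * n), _EPS), _EPS, 1 - _EPS))
        pi1 = float(np.mean(r1))
        if len(trace) >= 2 and trace[-1] - trace[-2] < tol:
            converged = True
            break
    trace.append(_loglik(k, n, p0, p1, pi1))

    trace_arr = np.asarray(trace)
    gains = np.diff(trace_arr)
    # EM guarantees monotone log-likelihood; tolerate only float round-off
    assert np.all(gains >= -1e-8 * (1.0 + np.abs(trace_arr[:-1]))), (
        "EM log-likelihood decreased"
    )

    if p0 > p1:
        p0, p1, pi1 = p1, p0, 1.0 - pi1
    return MixtureFit(
        guide_id, p0, p1, pi1, trace_arr, converged, len(k), low_support=low_support
    )


def _gmm_initialise(frac: np.ndarray, seed: int) -> tuple[float, float, float]:
    """Initial (p_noise, p_signal, pi_signal) from a 2-component GMM on k/n."""
    x = frac.reshape(-1, 1)
    if len(np.unique(frac)) < 2:
        base = float(np.clip(frac[0], _EPS, 1 - _EPS))
        return max(_EPS, base * 0.9), min(1 - _EPS, max(base * 1.1, 10 * _EPS)), 0.5
    gmm = GaussianMixture(
        n_components=2, random_state=seed, reg_covar=1e-10, n_init=1
    ).fit(x)
    means = gmm.means_.ravel()
    weights = gmm.weights_.ravel()
    order = np.argsort(means)
    p0 = float(np.clip(means[order[0]], _EPS, 1 - _EPS))
    p1 = float(np.clip(means[order[1]], _EPS, 1 - _EPS))
    pi1 = float(np.clip(weights[order[1]], _EPS, 1 - _EPS))
    if abs(p1 - p0) < 1e-4:
        # coincident clusters: perturb by +/-10% so EM can separate them
        p0 = max(_EPS, p0 * 0.9)
        p1 = min(1 - _EPS, max(p1 * 1.1, p0 + 1e-4))
    return p0, p1, pi1


def noise_probability(fit: MixtureFit, k, n) -> np.ndarray:
    """Posterior probability that the observed count arose from noise.

    ``(1-pi) Binom(k; n, p_noise) / [(1-pi) Binom(k; n, p_noise) +
    pi Binom(k; n, p_signal)]``; cells with n == 0 are defined as pure
    noise (probability 1), and a degenerate fit is pure noise everywhere.
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    if np.any(k > n) or np.any(k < 0):
        raise ValueError("counts must satisfy 0 <= k <= n")
    out = np.ones_like(k, dtype=float)
    if fit.degenerate:
        return out
    pos = n > 0
    pi1 = min(max(fit.pi_signal, _EPS), 1 - _EPS)
    log_noise = np.log1p(-pi1) + _binom_logpmf(k[pos], n[pos], fit.p_noise)
    log_signal = np.log(pi1) + _binom_logpmf(k[pos], n[pos], fit.p_signal)
    out[pos] = np.exp(log_noise - np.logaddexp(log_noise, log_signal))
    return out


def call_presence(fit: MixtureFit, k, n, threshold: float = 0.05) -> np.ndarray:
    """Boolean presence calls: present iff noise probability < threshold (strict)."""
    return noise_probability(fit, k, n) < threshold


def fit_all_guides(
    counts: CountMatrix,
    *,
    threshold: float = 0.05,
    seed: int = 0,
    **fit_opts,
) -> tuple[dict[str, MixtureFit], pd.DataFrame]:
    """Fit every guide independently and return fits plus a presence table.

    Cells with total gRNA count 0 are globally absent for every guide; each
    mixture is fit on the cells with n > 0 only.
    """
    dense = np.asarray(counts.matrix.todense(), dtype=float)
    totals = dense.sum(axis=1)
    pos = totals > 0
    presence = np.zeros(dense.shape, dtype=bool)
    fits: dict[str, MixtureFit] = {}
    for j, gid in enumerate(counts.features):
        fit = fit_binomial_mixture(
            dense[pos, j], totals[pos], seed=seed, guide_id=gid, **fit_opts
        )
        fits[gid] = fit
        presence[pos, j] = call_presence(fit, dense[pos, j], totals[pos], threshold)
    presence_df = pd.DataFrame(presence, index=counts.barcodes, columns=counts.features)
    return fits, presence_df


def fits_to_frame(fits: Mapping[str, MixtureFit]) -> pd.DataFrame:
    """Per-guide fit diagnostics table."""
    rows = []
    for gid, f in fits.items():
        rows.append(
            {
                "guide_id": gid,
                "p_noise": f.p_noise,
                "p_signal": f.p_signal,
                "pi_signal": f.pi_signal,
                "converged": f.converged,
                "degenerate": f.degenerate,
                "low_support": f.low_support,
                "n_cells_used": f.n_cells_used,
                "n_iterations": max(len(f.loglik_trace) - 1, 0),
            }
        )
    return pd.DataFrame(rows)


def assign_cells(presence: pd.DataFrame) -> pd.DataFrame:
    """Per-cell assignment from a cells x guides boolean presence table.

    Status is ``assigned`` iff exactly one guide is present; otherwise
    ``none_present`` or ``multiple_present`` and no guide is assigned.
    """
    values = presence.to_numpy(dtype=bool)
    n_present = values.sum(axis=1)
    guide_idx = values.argmax(axis=1)
    assigned = np.where(
        n_present == 1, np.asarray(presence.columns)[guide_idx], None
    )
    status = np.select(
        [n_present == 0, n_present == 1], ["none_present", "assigned"], "multiple_present"
    )
    present_lists = [
        ",".join(presence.columns[row]) for row in values
    ]
    return pd.DataFrame(
        {
            "cell_barcode": presence.index,
            "present_guides": present_lists,
            "n_present": n_present,
            "assigned_guide": assigned,
            "status": status,
        }
    ).set_index("cell_barcode")


def detection_rate(assignments: pd.DataFrame, hq_cells: Sequence[str]) -> float:
    """Fraction of high-quality cells mapped to exactly one guide.

    Cells in ``hq_cells`` missing from the assignment table (e.g. no gRNA
    reads at all) count as unassigned.
    """
    hq = list(hq_cells)
    if not hq:
        raise ValueError("hq_cells must be non-empty")
    status = assignments["status"]
    n_assigned = sum(
        1 for c in hq if c in status.index and status.loc[c] == "assigned"
    )
    return n_assigned / len(hq)


def assignment_summary(assignments: pd.DataFrame) -> pd.DataFrame:
    """Cells per assigned guide plus the unassigned categories (pie-chart data)."""
    counts = assignments.loc[
        assignments["status"] == "assigned", "assigned_guide"
    ].value_counts()
    rows = [{"category": g, "n_cells": int(c)} for g, c in counts.items()]
    for status in ("none_present", "multiple_present"):
        rows.append(
            {
                "category": status,
                "n_cells": int((assignments["status"] == status).sum()),
            }
        )
    return pd.DataFrame(rows)
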