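"""Westfall-Young single-step minP / maxT permutation FWER control.

Both procedures use the joint permutation distribution of the component
statistics, so the dependence between the clique/separator hypotheses is
taken into account (unlike Bonferroni).  minP operates on per-hypothesis
permutation p-values and is valid for either covariance estimator; maxT
compares components on the -log of their asymptotic chi-square p-values and
is valid only under the MLE, where the asymptotic reference holds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("sourceset")

PERMUTATION_CAP = 10000
PERMUTATION_FLOOR = 100


@dataclass(frozen=True)
class CorrectionResult:
    method: str                 # "minP" | "maxT"
    alpha: float
    cutoff: float               # p-value threshold (minP) / transformed-statistic threshold (maxT)
    rejected: np.ndarray        # bool per component
    adjusted: np.ndarray        # adjusted p-values per component


def build_pvalue_matrix(observed_stats: np.ndarray,
                        perm_stats: np.ndarray) -> np.ndarray:
    """Per-hypothesis permutation p-value matrix, components x (B+1).

    Every column -- the observed statistics in column 0 and each permutation
    in columns 1..B -- is ranked against the *other* B columns of the pooled
    (B+1)-column ensemble with add-one counting (single pool reused, no
    nested permutations).  Under the null the B+1 columns are exchangeable,
    so the joint distribution of the p-value matrix is fully symmetric and
    the min-p quantile is an exact-level reference; ranking permutations only
    within their own pool would make their p-values one grid step larger than
    the observed ones and bias the cutoff upward.
    """
    m, B = perm_stats.shape
    out = np.empty((m, B + 1))
    for j in range(m):
        v = perm_stats[j]
        o = observed_stats[j]
        order = np.sort(v)
        # self contributes the add-one; #{b: v[b] >= x} = B - #{v < x}
        out[j, 0] = (1.0 + B - np.searchsorted(order, o, side="left")) / (1.0 + B)
        counts = B - np.searchsorted(order, v, side="left")  # includes self
        out[j, 1:] = (counts + (o >= v)) / (1.0 + B)
    return out


def minp_correct(perm_pvalue_matrix: np.ndarray, alpha: float) -> CorrectionResult:
    """Single-step minP: reject components whose observed permutation p-value
    falls at or below the empirical alpha-quantile of the min-over-components
    p-value across permutations.

    The cutoff is the largest achievable p-level whose add-one exceedance
    estimate stays <= alpha, which for a single component reduces to an
    exact-level permutation test.  Ties use non-strict ``p <= cutoff`` --
    conservative but non-empty on the discrete permutation p-value grid.
    """
    pmat = np.asarray(perm_pvalue_matrix, dtype=float)
    observed = pmat[:, 0]
    B = pmat.shape[1] - 1
    if 1.0 / (B + 1) > alpha:
        logger.warning(
            "B=%d gives p-value resolution %.4g > alpha=%g: cutoff may be degenerate",
            B, 1.0 / (B + 1), alpha,
        )
    minima = np.sort(pmat[:, 1:].min(axis=0))
    # largest cutoff c with (1 + #{b: min_b <= c}) / (1 + B) <= alpha
    allowed = math.floor(alpha * (B + 1) - 1)
    if allowed < 0:
        cutoff = 0.0
    elif allowed >= B:
        cutoff = 1.0
    else:
        cutoff = float(np.nextafter(minima[allowed], 0.0))
    rejected = observed <= cutoff
    adjusted = (1.0 + np.searchsorted(minima, observed, side="right")) / (1.0 + B)
    return CorrectionResult("minP", alpha, cutoff, rejected, adjusted)


def maxt_correct(stat_matrix: np.ndarray, dfs, alpha: float,
                 estimator: str = "mle") -> CorrectionResult:
    """Single-step maxT on -log asymptotic chi-square p-values.

    Components with different degrees of freedom are put on a common scale by
    the monotone transform ``t = -logsf_chi2(lambda; df)`` before taking
    per-permutation maxima; the cutoff is the smallest threshold whose
    add-one exceedance estimate of the max stays <= alpha.
    """
    if estimator != "mle":
        raise ValueError(
            "maxT requires the asymptotic reference distribution: only the "
            "minP version is applicable with ridge estimates"
        )
    smat = np.asarray(stat_matrix, dtype=float)
    dfs = np.asarray(dfs, dtype=float)
    B = smat.shape[1] - 1
    t = -stats.chi2.logsf(smat, dfs[:, None])
    t_obs = t[:, 0]
    maxima = np.sort(t[:, 1:].max(axis=0))[::-1]  # descending
    # smallest cutoff c with (1 + #{b: max_b >= c}) / (1 + B) <= alpha
    allowed = math.floor(alpha * (B + 1) - 1)
    if allowed < 0:
        cutoff = math.inf
    elif allowed >= B:
        cutoff = -math.inf
    else:
        cutoff = float(np.nextafter(maxima[allowed], math.inf))
    rejected = t_obs >= cutoff
    ascending = maxima[::-1]
    counts = B - np.searchsorted(ascending, t_obs, side="left")
    adjusted = (1.0 + counts) / (1.0 + B)
    return CorrectionResult("maxT", alpha, cutoff, rejected, adjusted)


def recommended_permutations(m: int, alpha: float, method: str = "minp") -> int:
    """Permutation-count recommendation: ceil(m/alpha) for minP as an absolute
    minimum, ceil(1/alpha) for maxT; capped at 10000.

    The floor of :data:`PERMUTATION_FLOOR` is applied when a run resolves
    ``permutations="auto"``, not here, so the bare recommendation stays
    faithful to the m/alpha and 1/alpha rules.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    method = method.lower()
    if method == "minp":
        rec = math.ceil(m / alpha)
    elif method == "maxt":
        rec = math.ceil(1 / alpha)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(PERMUTATION_CAP, rec)


def max_mc_error_percent(n_runs: int) -> float:
    """Worst-case binomial Monte-Carlo standard error of an estimated
    proportion over ``n_runs`` replicates, in percent: 100 * sqrt(0.25/n)."""
    return 100.0 * math.sqrt(0.25 / n_runs)
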