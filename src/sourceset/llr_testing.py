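"""Two-sample Gaussian log-likelihood-ratio tests on cliques and separators.

For a node set ``A`` the marginal statistic is

    lambda(A) = sum_l n_l * log(|Sigma_hat_A| / |Sigma_hat_A^(l)|)

where ``Sigma_hat_A`` is the maximum-likelihood covariance estimate under the
null of equal distributions (centered at the grand mean, denominator
``n_1 + n_2``) and ``Sigma_hat_A^(l)`` the per-condition estimates (centered
at the condition means, denominator ``n_l``).  Centering the pooled estimate
at the grand mean makes the statistic sensitive to both mean and covariance
differences, which is the classical joint-equality likelihood ratio.  The
conditional statistic of a hypothesis component ``(C, S)`` is
``lambda(C) - lambda(S)``; no conditional distribution is ever estimated.

The MLE exists only when ``min(n1, n2)`` exceeds the component size; below
that a ridge-regularized variant adds a small common quantity to the
diagonals of all three estimates, chosen once per run and frozen across
permutations so label exchangeability is preserved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .graph_engine import ComponentCatalogue, Node, _key

logger = logging.getLogger("sourceset")

RIDGE_GRID = (1e-4, 1e-3, 1e-2, 1e-1)
RIDGE_COND_MAX = 1e6


class EstimatorInfeasibleError(ValueError):
    """MLE requested where min(n1, n2) <= component size (or singular fit)."""


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------


@dataclass
class TwoSampleData:
    """Expression matrix (genes x samples) split into two labelled conditions.

    ``condition`` holds 0/1 per sample; label 0 is condition 1 (by convention
    the lexicographically smaller original label).
    """

    matrix: np.ndarray
    genes: tuple[Node, ...]
    condition: np.ndarray
    labels: tuple[str, str] = ("1", "2")
    gene_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.condition = np.asarray(self.condition, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be genes x samples")
        if self.matrix.shape[0] != len(self.genes):
            raise ValueError("gene list does not match matrix rows")
        if self.matrix.shape[1] != self.condition.size:
            raise ValueError("condition labels do not match matrix columns")
        if np.isnan(self.matrix).any():
            raise ValueError("missing values in expression matrix")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene IDs must be unique")
        if not set(np.unique(self.condition)) <= {0, 1}:
            raise ValueError("condition must be coded 0/1")
        if self.n1 == 0 or self.n2 == 0:
            raise ValueError("both conditions must be non-empty")
        self.gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n1(self) -> int:
        return int(np.sum(self.condition == 0))

    @property
    def n2(self) -> int:
        return int(np.sum(self.condition == 1))

    def submatrix(self, nodes) -> np.ndarray:
        rows = [self.gene_index[g] for g in sorted(nodes, key=_key)]
        missing = [g for g in nodes if g not in self.gene_index]
        if missing:
            raise KeyError(f"genes not in data: {missing}")
        return self.matrix[rows]

    @classmethod
    def from_frames(cls, expr: pd.DataFrame, classes: pd.Series) -> "TwoSampleData":
        """Build from an expression DataFrame (genes x samples) and a sample ->
        condition mapping; the two condition labels are taken in lexicographic
        order as (condition 1, condition 2)."""
        classes = classes.astype(str)
        levels = sorted(classes.unique())
        if len(levels) != 2:
            raise ValueError(f"need exactly two condition labels, got {levels}")
        common = [s for s in expr.columns if s in classes.index]
        if len(common) < len(expr.columns):
            logger.warning("dropping %d sample(s) without condition label",
                           len(expr.columns) - len(common))
        expr = expr[common]
        cond = (classes.loc[common] == levels[1]).to_numpy().astype(int)
        return cls(matrix=expr.to_numpy(dtype=float),
                   genes=tuple(expr.index),
                   condition=cond,
                   labels=(levels[0], levels[1]))


@dataclass(frozen=True)
class CovarianceEstimate:
    sigma_pooled: np.ndarray
    sigma_1: np.ndarray
    sigma_2: np.ndarray
    estimator: str
    ridge_eps: float


@dataclass
class ComponentTest:
    """One hypothesis component H = (clique, separator) with its statistics."""

    clique: frozenset
    separator: frozenset
    lambda_marginal_clique: float
    lambda_marginal_sep: float
    lambda_conditional: float
    df: int
    p_asymptotic: float | None = None
    p_permutation: float | None = None
    perm_stats: np.ndarray | None = field(default=None, repr=False)
    adjusted_p: float | None = None
    rejected: bool | None = None


# ---------------------------------------------------------------------------
# Covariance estimation
# ---------------------------------------------------------------------------


def _group_covariances(x: np.ndarray, cond: np.ndarray):
    """MLE covariances (denominator n) pooled at the grand mean and per group."""
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    pooled = xc @ xc.T / n
    out = [pooled]
    for g in (0, 1):
        xg = x[:, cond == g]
        xgc = xg - xg.mean(axis=1, keepdims=True)
        out.append(xgc @ xgc.T / xg.shape[1])
    return out


def estimate_cov(data: TwoSampleData, nodes, estimator: str,
                 ridge_eps: float | None = None) -> CovarianceEstimate:
    """Pooled (under H) and per-condition covariance estimates for ``nodes``.

    Under ``"ridge"``, ``ridge_eps`` (from :func:`choose_ridge_eps`, or
    recomputed here on the requested nodes if not supplied) is added to every
    diagonal, guaranteeing positive definiteness.
    """
    d = len(set(nodes))
    if estimator == "mle" and min(data.n1, data.n2) <= d:
        raise EstimatorInfeasibleError(
            f"MLE needs min(n1, n2) > {d} for component {sorted(nodes, key=_key)}; "
            f"have n1={data.n1}, n2={data.n2}. Use the ridge estimator."
        )
    x = data.submatrix(nodes)
    pooled, s1, s2 = _group_covariances(x, data.condition)
    if estimator == "mle":
        eps = 0.0
    elif estimator == "ridge":
        eps = choose_ridge_eps(data, [frozenset(nodes)]) if ridge_eps is None \
            else float(ridge_eps)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    if eps:
        eye = np.eye(d)
        pooled, s1, s2 = pooled + eps * eye, s1 + eps * eye, s2 + eps * eye
    return CovarianceEstimate(pooled, s1, s2, estimator, eps)


def choose_ridge_eps(data: TwoSampleData, node_sets) -> float:
    """Global ridge diagonal inflation for a run.

    ``eps = c * mean(diag(pooled covariance of the full gene set))`` with ``c``
    the smallest grid value for which every component-sized submatrix in both
    conditions has condition number <= 1e6; one value per run, frozen across
    permutations.  Falls back to the largest grid value if none qualifies.
    """
    pooled, s1, s2 = _group_covariances(data.matrix, data.condition)
    base = float(np.mean(np.diag(pooled)))
    if base <= 0:
        base = 1.0
    idx_sets = [[data.gene_index[g] for g in sorted(ns, key=_key)]
                for ns in node_sets]
    for c in RIDGE_GRID:
        eps = c * base
        ok = True
        for rows in idx_sets:
            for s in (s1, s2):
                sub = s[np.ix_(rows, rows)] + eps * np.eye(len(rows))
                w = np.linalg.eigvalsh(sub)
                if w[0] <= 0 or w[-1] / w[0] > RIDGE_COND_MAX:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return eps
    return RIDGE_GRID[-1] * base


# ---------------------------------------------------------------------------
# Log-likelihood-ratio statistics
# ---------------------------------------------------------------------------


def _logdet_pd(m: np.ndarray, context: str) -> float:
    """log-determinant via Cholesky; raises if the matrix is not PD."""
    try:
        chol = np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise EstimatorInfeasibleError(
            f"covariance estimate not positive definite for {context}"
        ) from exc
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def llr_marginal(data: TwoSampleData, nodes, estimator: str,
                 ridge_eps: float | None = None) -> float:
    """Marginal statistic lambda(A); lambda(empty set) = 0."""
    if len(nodes) == 0:
        return 0.0
    est = estimate_cov(data, nodes, estimator, ridge_eps)
    ctx = f"A={sorted(nodes, key=_key)}"
    n1, n2 = data.n1, data.n2
    return ((n1 + n2) * _logdet_pd(est.sigma_pooled, ctx)
            - n1 * _logdet_pd(est.sigma_1, ctx)
            - n2 * _logdet_pd(est.sigma_2, ctx))


def llr_conditional(data: TwoSampleData, clique, separator, estimator: str,
                    ridge_eps: float | None = None) -> float:
    """Conditional statistic lambda(C) - lambda(S) for component (C, S)."""
    clique, separator = frozenset(clique), frozenset(separator)
    if not separator <= clique:
        raise ValueError("separator must be a subset of the clique")
    if clique == separator:
        return 0.0
    return (llr_marginal(data, clique, estimator, ridge_eps)
            - llr_marginal(data, separator, estimator, ridge_eps))


def chisq_df(clique_size: int, separator_size: int) -> int:
    """Degrees of freedom of the asymptotic chi-square reference.

    Parameter count of a p-variate Gaussian mean + covariance is
    ``p + p(p+1)/2``; the component tests the difference between clique and
    separator parameterizations.
    """
    p, s = clique_size, separator_size
    if not (0 <= s < p):
        raise ValueError(f"need 0 <= separator_size < clique_size, got {s}, {p}")
    count = lambda q: q + q * (q + 1) // 2
    return count(p) - count(s)


# ---------------------------------------------------------------------------
# Permutation machinery
# ---------------------------------------------------------------------------


def _batched_lambda(x: np.ndarray, masks: np.ndarray, n1: int, n2: int,
                    eps: float, mle: bool) -> np.ndarray:
    """lambda(A) for one node set under a batch of group-1 membership masks.

    ``x`` is d x n data; ``masks`` is B x n of 0/1 with row sums n1.  The
    pooled grand-mean estimate is permutation invariant and computed once.
    """
    d, n = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    pooled = xc @ xc.T / n + eps * np.eye(d)
    ld_pooled = _logdet_pd(pooled, "pooled")

    def group_logdets(w: np.ndarray, ng: int) -> np.ndarray:
        mean = (w @ x.T) / ng                                   # B x d
        sec = np.einsum("bn,in,jn->bij", w, x, x) / ng          # B x d x d
        cov = sec - mean[:, :, None] * mean[:, None, :] + eps * np.eye(d)
        sign, ld = np.linalg.slogdet(cov)
        if mle and np.any(sign <= 0):
            raise EstimatorInfeasibleError(
                "singular per-group covariance in a permutation under MLE"
            )
        return ld

    ld1 = group_logdets(masks.astype(float), n1)
    ld2 = group_logdets(1.0 - masks.astype(float), n2)
    return (n1 + n2) * ld_pooled - n1 * ld1 - n2 * ld2


def permutation_statistics(
    data: TwoSampleData,
    catalogue: ComponentCatalogue,
    B: int,
    seed: int,
    estimator: str = "mle",
    ridge_eps: float | None = None,
) -> list[ComponentTest]:
    """Observed and permutation statistics for every distinct component.

    One batch of ``B`` random label permutations is drawn up front and reused
    for every component, so the joint permutation null is preserved.  Marginal
    statistics are computed once per distinct clique / non-empty separator and
    the conditional statistics assembled by subtraction.  Under ridge the
    diagonal inflation is frozen at its observed-data value.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if estimator not in ("mle", "ridge"):
        raise ValueError(f"unknown estimator {estimator!r}")
    n1, n2 = data.n1, data.n2
    n = n1 + n2
    n_assignments = math.comb(n, n1)
    if B > n_assignments:
        logger.warning(
            "B=%d exceeds the %d distinct label assignments; duplicates allowed",
            B, n_assignments,
        )

    node_sets: dict[frozenset, None] = {}
    for _, c, s in catalogue.components:
        node_sets.setdefault(c, None)
        if s:
            node_sets.setdefault(s, None)

    if estimator == "mle":
        too_big = max(len(ns) for ns in node_sets)
        if min(n1, n2) <= too_big:
            raise EstimatorInfeasibleError(
                f"MLE needs min(n1, n2) > p* = {too_big}; use ridge"
            )
        eps = 0.0
    else:
        eps = choose_ridge_eps(data, list(node_sets)) if ridge_eps is None \
            else float(ridge_eps)

    rng = np.random.default_rng(seed)
    base = (data.condition == 0).astype(np.int8)
    masks = np.empty((B, n), dtype=np.int8)
    for b in range(B):
        masks[b] = base[rng.permutation(n)]

    obs: dict[frozenset, float] = {}
    perm: dict[frozenset, np.ndarray] = {}
    for ns in node_sets:
        x = data.submatrix(ns)
        obs[ns] = _batched_lambda(x, base[None, :], n1, n2, eps,
                                  estimator == "mle")[0]
        perm[ns] = _batched_lambda(x, masks, n1, n2, eps, estimator == "mle")

    tests: list[ComponentTest] = []
    for _, c, s in catalogue.components:
        lam_c, lam_s = obs[c], obs[s] if s else 0.0
        perm_c = perm[c]
        perm_s = perm[s] if s else np.zeros(B)
        lam = lam_c - lam_s
        perm_lam = perm_c - perm_s
        df = chisq_df(len(c), len(s))
        p_perm = float((1 + np.sum(perm_lam >= lam)) / (1 + B))
        p_asym = float(stats.chi2.sf(lam, df)) if estimator == "mle" else None
        tests.append(
            ComponentTest(
                clique=c, separator=s,
                lambda_marginal_clique=float(lam_c),
                lambda_marginal_sep=float(lam_s),
                lambda_conditional=float(lam),
                df=df,
                p_asymptotic=p_asym,
                p_permutation=p_perm,
                perm_stats=perm_lam,
            )
        )
    return tests
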