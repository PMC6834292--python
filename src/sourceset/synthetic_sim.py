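"""Synthetic two-condition data generation for the source-set estimator.

The generator draws multivariate normal (optionally skew-normal) data that
are Markov with respect to a decomposable graph in a reference condition,
and builds a perturbed condition by one of three mechanisms:

* ``marginal`` -- inflate the mean and variance of a target node subset ``D``
  by a relative intensity ``delta`` while reconstructing the conditional law
  of the remaining variables given ``D`` unchanged, so ``D`` is a source set
  by construction (intensities 0.2 / 0.6 / 1.0 = mild / moderate / strong);
* ``structural`` -- zero selected entries of the concentration matrix,
  removing conditional-dependence edges;
* ``mean_shift`` -- leave the covariance untouched and move the mean to
  ``Sigma @ e_target * mu_t``, i.e. a sparse intervention on one node whose
  displacement propagates through the covariance operator (intensities
  1 / 5 / 10 / 50 = weak / mild / moderate / strong).

Because real reference parameters are not shipped, :func:`random_ggm` draws
a concentration matrix supported exactly on the graph edges (diagonally
dominant, hence positive definite) from a documented seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .graph_engine import DecomposableGraph, PathwayGraph, triangulate, _key
from .llr_testing import TwoSampleData

logger = logging.getLogger("sourceset")

MARGINAL_INTENSITY = {"mild": 0.2, "moderate": 0.6, "strong": 1.0}
MEAN_SHIFT_INTENSITY = {"weak": 1.0, "mild": 5.0, "moderate": 10.0, "strong": 50.0}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GGMSpec:
    """Gaussian graphical model: mean + covariance/concentration pair.

    ``check_markov`` verifies that the concentration matrix vanishes on
    non-adjacent pairs; perturbed specs may relax it (a marginal perturbation
    of a multi-node ``D`` can introduce fill within ``D``).
    """

    graph: DecomposableGraph
    mu: np.ndarray
    sigma: np.ndarray
    concentration: np.ndarray
    check_markov: bool = True
    nodes: tuple = field(init=False)

    def __post_init__(self) -> None:
        self.nodes = self.graph.nodes
        p = len(self.nodes)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.mu.shape != (p,) or self.sigma.shape != (p, p):
            raise ValueError("parameter dimensions do not match the graph")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if np.linalg.eigvalsh(self.sigma)[0] <= 0:
            raise ValueError("sigma must be positive definite")
        if not np.allclose(self.sigma @ self.concentration, np.eye(p), atol=1e-8):
            raise ValueError("concentration is not the inverse of sigma")
        if self.check_markov:
            adj = {frozenset(e) for e in self.graph.edges}
            for i, u in enumerate(self.nodes):
                for j, v in enumerate(self.nodes):
                    if i < j and frozenset((u, v)) not in adj:
                        if abs(self.concentration[i, j]) > 1e-10:
                            raise ValueError(
                                f"concentration non-zero at non-adjacent pair "
                                f"({u!r}, {v!r}): not Markov to the graph"
                            )

    def index_of(self, node) -> int:
        return self.nodes.index(node)


@dataclass(frozen=True)
class PerturbationSpec:
    """Declarative description of a perturbation scenario."""

    kind: str                       # "marginal" | "structural" | "mean_shift" | "null"
    D: frozenset = frozenset()
    delta: float = 0.0
    removed_edges: tuple = ()
    mu_target: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("marginal", "structural", "mean_shift", "null"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "marginal" and (not self.D or self.delta <= 0):
            raise ValueError("marginal perturbation needs non-empty D and delta > 0")


# ---------------------------------------------------------------------------
# Reference model
# ---------------------------------------------------------------------------


def fixture_graph() -> DecomposableGraph:
    """The fixed 10-node chordal simulation graph.

    Maximal cliques {1,2,3}, {3,4,5}, {5,6}, {6,7}, {5,8,9,10}; k = 5,
    p* = 4; node 5 is a singleton separator cutting {1,2,3,4} off from the
    rest, so perturbations of node 5 and of clique {5,8,9,10} exercise the
    minimal- versus graphical-source-set distinction.
    """
    cliques = [(1, 2, 3), (3, 4, 5), (5, 6), (6, 7), (5, 8, 9, 10)]
    edges = sorted(
        {
            tuple(sorted((u, v)))
            for c in cliques
            for i, u in enumerate(c)
            for v in c[i + 1:]
        }
    )
    g = PathwayGraph(nodes=tuple(range(1, 11)), edges=tuple(edges), directed=False)
    dg = triangulate(g)
    assert not dg.fill_in  # already chordal
    return dg


def random_ggm(graph: DecomposableGraph, seed: int,
               unit_variance: bool = True, zero_mean: bool = False) -> GGMSpec:
    """Random GGM Markov to ``graph``.

    Off-diagonal concentration entries are sampled on the edge set (magnitude
    0.15-0.45, random sign) and the diagonal is set above the absolute row
    sum, giving a diagonally dominant -- hence positive definite -- matrix.
    Means are drawn on a log-expression-like scale (5-10) unless zeroed.
    """
    rng = np.random.default_rng(seed)
    nodes = graph.nodes
    p = len(nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    K = np.zeros((p, p))
    for e in sorted(graph.edges, key=lambda e: sorted(map(_key, e))):
        u, v = sorted(e, key=_key)
        w = rng.uniform(0.15, 0.45) * rng.choice([-1.0, 1.0])
        K[idx[u], idx[v]] = K[idx[v], idx[u]] = w
    K[np.diag_indices(p)] = np.abs(K).sum(axis=1) + rng.uniform(0.3, 0.6, size=p)
    sigma = np.linalg.inv(K)
    if unit_variance:
        d = 1.0 / np.sqrt(np.diag(sigma))
        sigma = sigma * np.outer(d, d)
        K = np.linalg.inv(sigma)
    mu = np.zeros(p) if zero_mean else rng.uniform(5.0, 10.0, size=p)
    return GGMSpec(graph=graph, mu=mu, sigma=sigma, concentration=K)


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------


def perturb_marginal(spec: GGMSpec, D, delta: float) -> GGMSpec:
    """Inflate mean and variance of ``X_D`` by ``delta`` (relative), leaving
    the conditional law of the other variables given ``X_D`` unchanged.

    With ``B = Sigma_{D',D} Sigma_{DD}^{-1}`` the regression matrix and
    ``a``, ``Sigma_cond`` the conditional intercept and covariance, the new
    joint is reassembled from the scaled marginal block and the *original*
    conditional parameters, which is the defining property of ``D`` being a
    source set.
    """
    D = frozenset(D)
    if not D:
        raise ValueError("D must be non-empty")
    if not D <= set(spec.nodes):
        raise ValueError(f"D contains nodes outside the graph: {sorted(D - set(spec.nodes), key=_key)}")
    if delta == 0:
        return spec
    d_idx = [i for i, n in enumerate(spec.nodes) if n in D]
    r_idx = [i for i, n in enumerate(spec.nodes) if n not in D]
    S = spec.sigma
    mu = spec.mu
    S_dd = S[np.ix_(d_idx, d_idx)]
    S_rd = S[np.ix_(r_idx, d_idx)]
    S_rr = S[np.ix_(r_idx, r_idx)]
    B = S_rd @ np.linalg.inv(S_dd)
    a = mu[r_idx] - B @ mu[d_idx]
    S_cond = S_rr - B @ S_dd @ B.T

    mu_d_new = (1.0 + delta) * mu[d_idx]
    S_dd_new = (1.0 + delta) * S_dd
    S_rd_new = B @ S_dd_new
    S_rr_new = S_cond + B @ S_dd_new @ B.T
    mu_r_new = a + B @ mu_d_new

    p = len(spec.nodes)
    mu_new = np.empty(p)
    mu_new[d_idx], mu_new[r_idx] = mu_d_new, mu_r_new
    S_new = np.empty((p, p))
    S_new[np.ix_(d_idx, d_idx)] = S_dd_new
    S_new[np.ix_(r_idx, d_idx)] = S_rd_new
    S_new[np.ix_(d_idx, r_idx)] = S_rd_new.T
    S_new[np.ix_(r_idx, r_idx)] = S_rr_new
    # fill can only appear inside the D block, so the result stays Markov
    # whenever D lies within a single clique
    markov = spec.check_markov and any(D <= c for c in spec.graph.cliques)
    return GGMSpec(graph=spec.graph, mu=mu_new, sigma=S_new,
                   concentration=np.linalg.inv(S_new),
                   check_markov=markov)


def strengthen_edges(spec: GGMSpec, edges, factor: float) -> GGMSpec:
    """Scale the magnitude of selected concentration entries (used to make a
    later structural removal a non-trivial perturbation)."""
    K = spec.concentration.copy()
    idx = {n: i for i, n in enumerate(spec.nodes)}
    for u, v in edges:
        i, j = idx[u], idx[v]
        if K[i, j] == 0:
            raise ValueError(f"edge ({u!r}, {v!r}) has no conditional dependence")
        K[i, j] *= factor
        K[j, i] = K[i, j]
    if np.linalg.eigvalsh(K)[0] <= 0:
        raise ValueError("strengthening broke positive definiteness")
    return GGMSpec(graph=spec.graph, mu=spec.mu.copy(),
                   sigma=np.linalg.inv(K), concentration=K)


def perturb_structure(spec: GGMSpec, edges_to_remove) -> GGMSpec:
    """Zero selected concentration entries (remove conditional dependencies).

    Raises if the zeroed matrix is no longer positive definite.
    """
    edges_to_remove = list(edges_to_remove)
    if not edges_to_remove:
        return spec
    adj = {frozenset(e) for e in spec.graph.edges}
    idx = {n: i for i, n in enumerate(spec.nodes)}
    K = spec.concentration.copy()
    for u, v in edges_to_remove:
        if frozenset((u, v)) not in adj:
            raise ValueError(f"({u!r}, {v!r}) is not an edge of the graph")
        K[idx[u], idx[v]] = K[idx[v], idx[u]] = 0.0
    if np.linalg.eigvalsh(K)[0] <= 0:
        raise ValueError(
            "removing the requested edges breaks positive definiteness"
        )
    return GGMSpec(graph=spec.graph, mu=spec.mu.copy(),
                   sigma=np.linalg.inv(K), concentration=K)


def mean_shift(spec: GGMSpec, target, mu_t: float) -> GGMSpec:
    """Propagated mean shift: condition-2 mean ``mu + Sigma e_target mu_t``,
    covariance unchanged.

    The displacement is the covariance operator applied to a sparse vector,
    so the conditional law of the other variables given the target is
    identical across conditions and the minimal source set is {target}.
    """
    t = spec.index_of(target)
    mu_new = spec.mu + spec.sigma[:, t] * mu_t
    return GGMSpec(graph=spec.graph, mu=mu_new, sigma=spec.sigma.copy(),
                   concentration=spec.concentration.copy(),
                   check_markov=spec.check_markov)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


# half-normal |N(0,1)| moments: mean, variance, third central moment
_HN_MEAN = np.sqrt(2 / np.pi)
_HN_VAR = 1 - 2 / np.pi
_HN_MU3 = np.sqrt(2 / np.pi) * (4 / np.pi - 1)


def _draw(rng: np.random.Generator, spec: GGMSpec, n: int,
          skewness: np.ndarray | None) -> np.ndarray:
    """n draws (p x n) from the spec, optionally with skewed margins.

    Skewed margins use an additive half-normal construction with an
    independent skewing source per node: ``X_i = mu_i - b d_i + d_i |U_i| +
    Z_i`` with ``Z ~ N(0, Sigma - var(|U|) diag(d^2))``.  ``d_i`` is chosen
    by third-moment matching, so the mean, the full covariance matrix and
    the marginal skewness of every node are matched exactly.  (The exact
    multivariate skew-normal family cannot reach appreciable marginal
    skewness under an exact covariance match when the skewed nodes are
    weakly correlated -- its PSD constraint subtracts a rank-one multiple of
    the joint skewing direction -- so this skew-normal-type construction is
    used instead.)
    """
    p = len(spec.nodes)
    if skewness is None or not np.any(skewness):
        return spec.mu[:, None] + np.linalg.cholesky(spec.sigma) \
            @ rng.standard_normal((p, n))
    gamma = np.asarray(skewness, dtype=float)
    if gamma.shape != (p,):
        raise ValueError("skewness vector must align with the spec nodes")
    sd = np.sqrt(np.diag(spec.sigma))
    d = np.sign(gamma) * sd * (np.abs(gamma) / _HN_MU3) ** (1 / 3)
    resid_cov = spec.sigma - _HN_VAR * np.diag(d**2)
    if np.linalg.eigvalsh(resid_cov)[0] <= 0:
        raise ValueError(
            "skewness too strong for the given covariance: the residual "
            "Gaussian part is no longer positive definite"
        )
    u = np.abs(rng.standard_normal((p, n)))
    z = np.linalg.cholesky(resid_cov) @ rng.standard_normal((p, n))
    return (spec.mu[:, None] - _HN_MEAN * d[:, None]
            + d[:, None] * u + z)


def sample(spec1: GGMSpec, spec2: GGMSpec, n1: int, n2: int, seed: int,
           skewness: np.ndarray | None = None) -> TwoSampleData:
    """Draw a two-condition dataset (condition 1 from ``spec1``, condition 2
    from ``spec2``), optionally with skew-normal margins.

    The skewness vector is aligned with the node order of the specs; mean and
    covariance of each condition match the spec exactly, with the stated
    marginal skewness injected on the non-zero entries.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n1, n2 >= 2")
    if spec1.nodes != spec2.nodes:
        raise ValueError("the two specs must share the same node set")
    rng = np.random.default_rng(seed)
    x1 = _draw(rng, spec1, n1, skewness)
    x2 = _draw(rng, spec2, n2, skewness)
    return TwoSampleData(
        matrix=np.hstack([x1, x2]),
        genes=spec1.nodes,
        condition=np.array([0] * n1 + [1] * n2),
        labels=("1", "2"),
    )


def default_skewness(spec: GGMSpec, gamma: float = 0.3,
                     n_skewed: int = 4) -> np.ndarray:
    """Skewness vector applying ``gamma`` to the first ``n_skewed`` nodes
    (by sorted label), zero elsewhere."""
    order = sorted(range(len(spec.nodes)), key=lambda i: _key(spec.nodes[i]))
    out = np.zeros(len(spec.nodes))
    out[order[:n_skewed]] = gamma
    return out


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------


def make_scenario(
    perturbation: PerturbationSpec,
    graph: DecomposableGraph | None = None,
    seed: int = 0,
    unit_variance: bool = True,
) -> tuple[GGMSpec, GGMSpec]:
    """Reference and perturbed GGM pair for a named scenario.

    ``null`` returns the same spec twice; ``mean_shift`` uses a zero-mean
    reference so the two conditions are N(0, Sigma) and N(Sigma mu, Sigma).
    """
    if graph is None:
        graph = fixture_graph()
    if perturbation.kind == "mean_shift":
        ref = random_ggm(graph, seed, unit_variance=unit_variance, zero_mean=True)
        (target,) = perturbation.D if perturbation.D else (5,)
        return ref, mean_shift(ref, target, perturbation.mu_target)
    ref = random_ggm(graph, seed, unit_variance=unit_variance)
    if perturbation.kind == "null":
        return ref, ref
    if perturbation.kind == "marginal":
        return ref, perturb_marginal(ref, perturbation.D, perturbation.delta)
    # structural: strengthen the doomed conditional dependencies first so
    # their removal is a non-trivial perturbation, backing off if the
    # strengthened concentration would lose positive definiteness
    for factor in (3.0, 2.0, 1.5, 1.2, 1.0):
        try:
            strengthened = strengthen_edges(ref, perturbation.removed_edges,
                                            factor)
            break
        except ValueError:
            continue
    return strengthened, perturb_structure(strengthened, perturbation.removed_edges)
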