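"""Gene-scoring network metrics and their z-score adjustments.

Three metrics score the genes of a module subnetwork (DAPN or DGN):

* **Adamic-Adar** — for each gene pair the sum over common neighbors z of
  1/log(k_z), with k_z the weighted degree (strength) of z in the module;
  a gene's score S_x is the sum of its pairwise similarities with every
  other module gene.  This mirrors the inverse-log-weighted similarity of
  igraph.
* **PageRank** — damped random walk on the weighted module subnetwork
  (damping 0.75 by default); transition probabilities proportional to edge
  weights, uniform teleportation.
* **Neighborhood scoring** — a blend of a gene's own z-score with the mean
  z of its supra-threshold-weight neighbors:
  ``X_i = α·x_i + (1−α)·mean(x_j : w_ij > ε)``.

The Adamic-Adar and PageRank base scores are then damped by the expression
evidence: a gene present in both DAPN and DGN is scaled by
``0.5^|z_drug + z_disease|`` (or divided by ``e^|z_drug + z_disease|``), so a
drug that reverses the disease signature (z-sum ≈ 0) keeps its topological
score while non-reversing or module-private genes are pushed down the
ranking.

Scoring is module-local: degrees, neighborhoods and walks are taken on the
module's induced subnetwork, never the full FIN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from netdr.network import GeneModule

# ranking direction per metric: damped topological scores rank high-to-low,
# neighborhood scores low-to-high
RANK_DIRECTION: dict[str, str] = {
    "AA1": "descending",
    "AA2": "descending",
    "PR1": "descending",
    "PR2": "descending",
    "NS": "ascending",
}

METRICS = tuple(RANK_DIRECTION)


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the requested tolerance."""


@dataclass
class ScoreTable:
    """Per-gene scores for one metric, with the metric's ranking direction."""

    metric: str
    scores: dict[str, float]
    rank_direction: str = ""

    def __post_init__(self):
        if self.metric not in RANK_DIRECTION:
            raise ValueError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if not self.rank_direction:
            self.rank_direction = RANK_DIRECTION[self.metric]
        if self.rank_direction != RANK_DIRECTION[self.metric]:
            raise ValueError(
                f"{self.metric} must rank {RANK_DIRECTION[self.metric]}, got {self.rank_direction}"
            )


def _safe_inv_log(strength: np.ndarray) -> np.ndarray:
    """1/log(k) with the low-degree safeguard.

    With weighted degrees the strength can be ≤ 1, where log(k) ≤ 0 would
    flip or blow up the contribution; such nodes use log(1 + k) instead,
    which is positive and continuous in k.
    """
    out = np.empty_like(strength, dtype=float)
    low = strength <= 1.0
    out[low] = 1.0 / np.log1p(strength[low])
    out[~low] = 1.0 / np.log(strength[~low])
    return out


def adamic_adar_scores(
    module: GeneModule,
    weighted_degree: bool = False,
    safeguard_low_degree: bool = True,
) -> dict[str, float]:
    """Adamic-Adar similarity score S_x for every module gene.

    For each unordered gene pair (x, y), ``S_xy = Σ_z 1/log(k_z)`` over the
    common neighbors z (natural log), and ``S_x = Σ_{y≠x} S_xy``.  By
    default k_z is the plain degree of z in the module subnetwork — the
    inverse-log-weighted similarity convention, under which a common
    neighbor always has k_z ≥ 2 and the denominator is safely positive.

    With ``weighted_degree`` the strength (sum of incident edge weights) is
    used instead; strengths can then fall to 1 or below, where
    ``safeguard_low_degree`` floors the denominator at ``log(1 + k_z)``
    (disabling it raises on such nodes instead of returning infinities).
    """
    g = module.subnetwork.graph
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n < 2:
        raise ValueError("Adamic-Adar needs a module subnetwork with at least 2 nodes")
    idx = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n), dtype=float)  # binary adjacency (common-neighbor test)
    strength = np.zeros(n, dtype=float)
    for a, b, w in module.subnetwork.edges():
        i, j = idx[a], idx[b]
        adj[i, j] = adj[j, i] = 1.0
        strength[i] += w if weighted_degree else 1.0
        strength[j] += w if weighted_degree else 1.0
    if safeguard_low_degree:
        with np.errstate(divide="ignore"):
            inv_log = _safe_inv_log(strength)
    else:
        bad = strength[adj.sum(axis=1) > 0] <= 1.0
        if bad.any():
            raise ValueError(
                "node with weighted degree <= 1 encountered and safeguard disabled"
            )
        inv_log = np.where(strength > 1.0, 1.0 / np.log(np.maximum(strength, 1.0 + 1e-300)), 0.0)
    inv_log = np.where(strength > 0, inv_log, 0.0)  # isolated node contributes nothing
    pair = adj @ (adj * inv_log[:, None])  # pair[x, y] = Σ_{z ∈ N(x)∩N(y)} 1/log(k_z)
    s = pair.sum(axis=1) - np.diag(pair)  # exclude the y = x term
    return {v: float(s[idx[v]]) for v in nodes}


def pagerank_scores(
    module: GeneModule,
    damping: float = 0.75,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> dict[str, float]:
    """Weighted PageRank of the module subnetwork by power iteration.

    Each undirected edge acts as two directed edges; the walk leaves a node
    with probability proportional to edge weight, and teleports uniformly
    with probability ``1 − damping``.  Scores sum to 1.  Iteration stops when
    the L1 change drops below ``tol``; exceeding ``max_iter`` raises
    :class:`ConvergenceError` with the residual.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError(f"damping must be in (0, 1), got {damping}")
    g = module.subnetwork.graph
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("PageRank needs a non-empty module subnetwork")
    idx = {v: i for i, v in enumerate(nodes)}
    W = np.zeros((n, n), dtype=float)
    for a, b, w in module.subnetwork.edges():
        i, j = idx[a], idx[b]
        W[i, j] = W[j, i] = w
    out_strength = W.sum(axis=1)
    dangling = out_strength == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(dangling[:, None], 0.0, W / np.where(dangling, 1.0, out_strength)[:, None])
    r = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    for _ in range(max_iter):
        dangling_mass = r[dangling].sum() if dangling.any() else 0.0
        r_new = damping * (T.T @ r + dangling_mass / n) + teleport
        delta = float(np.abs(r_new - r).sum())
        r = r_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"PageRank did not converge in {max_iter} iterations (L1 residual {delta:.3e})"
        )
    r = r / r.sum()  # remove accumulated floating-point drift
    return {v: float(r[idx[v]]) for v in nodes}


def neighborhood_scores(
    module: GeneModule,
    z: Mapping[str, float] | Callable[[str], float],
    alpha: float = 0.7,
    epsilon: float = 0.1,
) -> dict[str, float]:
    """Neighborhood scoring: blend a gene's z with its neighborhood mean z.

    ``X_i = α·x_i + (1−α)·(Σ_{j : w_ij > ε} x_j)/N`` with N the number of
    neighbors whose edge weight exceeds ε; when N = 0 the score is ``α·x_i``.
    ``z`` may be a mapping (missing genes → 0) or a callable.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    zf = z if callable(z) else (lambda gene: z.get(gene, 0.0))
    g = module.subnetwork.graph
    out: dict[str, float] = {}
    for i in g.nodes:
        xi = float(zf(i))
        neigh = [j for j in g.neighbors(i) if g[i][j]["weight"] > epsilon]
        if neigh:
            mean_neigh = sum(float(zf(j)) for j in neigh) / len(neigh)
            out[i] = alpha * xi + (1.0 - alpha) * mean_neigh
        else:
            out[i] = alpha * xi
    return out


def _z_sum(
    gene: str,
    in_other: bool,
    z_self: Callable[[str], float],
    z_other: Callable[[str], float],
) -> float:
    if in_other:
        return abs(z_self(gene) + z_other(gene))
    return abs(z_self(gene))


def _as_zfun(z) -> Callable[[str], float]:
    if callable(getattr(z, "z", None)):
        return z.z  # DrugSignature / DiseaseSignature
    if callable(z):
        return z
    return lambda gene: z.get(gene, 0.0)


def adjust_multiplicative(
    base: Mapping[str, float],
    module_self: GeneModule,
    module_other: GeneModule,
    z_self,
    z_other,
) -> dict[str, float]:
    """Damp base scores by ``0.5^|z|``-style expression factors.

    For a gene in both modules the exponent is ``|z_self + z_other|`` (a
    reversing drug makes it ≈ 0, leaving the base score intact); a gene only
    in ``module_self`` uses ``|z_self|``.  z functions return 0 for
    unmeasured genes, so those factors are exactly 1.
    """
    zs, zo = _as_zfun(z_self), _as_zfun(z_other)
    other_members = module_other.members
    return {
        g: base[g] * 0.5 ** _z_sum(g, g in other_members, zs, zo)
        for g in module_self.members
    }


def adjust_exponential(
    base: Mapping[str, float],
    module_self: GeneModule,
    module_other: GeneModule,
    z_self,
    z_other,
) -> dict[str, float]:
    """Same branch structure as :func:`adjust_multiplicative`, dividing the
    base score by ``e^|z-sum|`` instead of multiplying by ``0.5^|z-sum|``."""
    zs, zo = _as_zfun(z_self), _as_zfun(z_other)
    other_members = module_other.members
    return {
        g: base[g] * math.exp(-_z_sum(g, g in other_members, zs, zo))
        for g in module_self.members
    }
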