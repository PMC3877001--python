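"""Hard k-means-style initialization for the fuzzy optimizer.

The optimizer starts from a hard partition found by alternating
minimization of the same stationary-weighted objective restricted to
indicator memberships: given a partition, the lumped chain is computed by
stationary-weighted aggregation; given the lumped chain, every node is
reassigned to the cluster whose lifted row is closest to the node's own
transition row in the 1/mu-weighted norm. Both half-steps are exact
minimizations, so the objective never increases between sweeps. The best
of several seeded random restarts is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import MarkovChain
from .lumping import Partition, indicator, lump_fuzzy, objective

__all__ = ["InitConfig", "kmeans_partition", "indicator_membership"]


@dataclass
class InitConfig:
    restarts: int = 8
    max_sweeps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


def _hard_objective(chain: MarkovChain, assign: np.ndarray, K: int) -> float:
    rho = np.zeros((chain.N, K))
    rho[np.arange(chain.N), assign] = 1.0
    return objective(chain, rho, lump_fuzzy(chain, rho))


def _repair_empty(d2: np.ndarray, new: np.ndarray, K: int) -> np.ndarray:
    """Move the worst-fitting nodes into clusters the sweep left empty."""
    for k in np.flatnonzero(np.bincount(new, minlength=K) == 0):
        own = d2[np.arange(len(new)), new]
        # never strip a cluster down to zero while repairing another
        movable = np.bincount(new, minlength=K)[new] > 1
        candidates = np.flatnonzero(movable)
        worst = candidates[np.argmax(own[candidates])]
        new[worst] = k
    return new


def _one_run(
    chain: MarkovChain, K: int, assign: np.ndarray, max_sweeps: int
) -> np.ndarray:
    P, mu = chain.P, chain.mu
    for _ in range(max_sweeps):
        d2 = _distances(P, mu, assign, K)
        new = _repair_empty(d2, d2.argmin(axis=1), K)
        if np.array_equal(new, assign):
            break
        assign = new
    return assign


def _distances(P: np.ndarray, mu: np.ndarray, assign: np.ndarray, K: int) -> np.ndarray:
    """mu-weighted squared distance of each node row to each lifted centroid row."""
    N = len(mu)
    rho = np.zeros((N, K))
    rho[np.arange(N), assign] = 1.0
    mu_hat = rho.T @ mu
    flux = rho.T @ (mu[:, None] * P) @ rho
    p_hat = flux / mu_hat[:, None]
    # lifted row of cluster k: Q[k, y] = p_hat[k, c(y)] mu[y] / mu_hat[c(y)]
    Q = p_hat[:, assign] * (mu[None, :] / mu_hat[assign][None, :])
    diff = P[:, None, :] - Q[None, :, :]
    d2 = np.einsum("xky,y->xk", diff * diff, 1.0 / mu)
    return mu[:, None] * d2


def kmeans_partition(
    chain: MarkovChain, K: int, cfg: InitConfig | None = None
) -> Partition:
    """Hard K-partition by alternating minimization of the lumping objective.

    Deterministic for a fixed seed; the best of ``cfg.restarts`` random
    initial assignments is returned.
    """
    if cfg is None:
        cfg = InitConfig()
    if not 2 <= K <= chain.N:
        raise ValueError(f"K must be in [2, N={chain.N}], got {K}")
    rng = np.random.default_rng(cfg.seed)
    best_J = np.inf
    best = None
    for _ in range(cfg.restarts):
        assign = rng.integers(0, K, chain.N)
        # ensure every cluster starts nonempty
        assign[rng.permutation(chain.N)[:K]] = np.arange(K)
        assign = _one_run(chain, K, assign, cfg.max_sweeps)
        J = _hard_objective(chain, assign, K)
        if J < best_J:
            best_J = J
            best = assign.copy()
    return Partition(assignment=best, K=K)


def indicator_membership(part: Partition) -> np.ndarray:
    """Indicator matrix of a hard partition (rows sum to 1 exactly)."""
    return indicator(part)
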