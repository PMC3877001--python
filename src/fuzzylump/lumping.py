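"""Hard and fuzzy lumping of a reversible chain, lifting, and the objective.

Given a membership matrix ``rho`` (N x K, row-stochastic: ``rho[x, k]`` is
the probability that node ``x`` belongs to cluster ``k``), the lumped chain
aggregates transition flux by stationary weight:

    mu_hat[k]   = sum_x mu[x] rho[x, k]
    p_hat[k, l] = sum_{x,y} mu[x] rho[x, k] p[x, y] rho[y, l] / mu_hat[k]

``p_hat`` is row-stochastic and inherits detailed balance with respect to
``mu_hat``. A lumped chain is lifted back to the node space through

    p_tilde[x, y] = sum_{k,l} rho[x, k] p_hat[k, l] mu[y] rho[y, l] / mu_hat[l]

and the quality of the reduction is the stationary-weighted Hilbert-Schmidt
distance

    J = sum_{x,y} (mu[x] / mu[y]) (p[x, y] - p_tilde[x, y])^2 .

Minimizing J over (rho, p_hat) is the fuzzy-partitioning problem solved in
:mod:`fuzzylump.optimize`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .network import MarkovChain

__all__ = [
    "Partition",
    "LumpedChain",
    "validate_membership",
    "lumped_stationary",
    "lump_hard",
    "lump_fuzzy",
    "lift",
    "objective",
    "optimal_lumped",
    "unconstrained_optimal_phat",
    "DegenerateClusterError",
]


class DegenerateClusterError(ValueError):
    """A cluster carries zero stationary mass (mu_hat[k] = 0)."""


@dataclass
class Partition:
    """A hard partition: cluster index in ``0..K-1`` for each node."""

    assignment: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1:
            raise ValueError("assignment must be a 1-d index vector")
        if self.assignment.min() < 0 or self.assignment.max() >= self.K:
            raise ValueError("cluster indices out of range")
        present = np.unique(self.assignment)
        if len(present) != self.K:
            missing = sorted(set(range(self.K)) - set(present.tolist()))
            raise ValueError(f"empty cluster(s): {missing}")

    @property
    def N(self) -> int:
        return len(self.assignment)


@dataclass
class LumpedChain:
    """A K-state lumped chain: row-stochastic ``p_hat`` + stationary ``mu_hat``."""

    p_hat: np.ndarray = field(repr=False)
    mu_hat: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.p_hat = np.asarray(self.p_hat, dtype=float)
        self.mu_hat = np.asarray(self.mu_hat, dtype=float)

    @property
    def K(self) -> int:
        return self.p_hat.shape[0]

    def detailed_balance_violation(self) -> float:
        flux = self.mu_hat[:, None] * self.p_hat
        return float(np.abs(flux - flux.T).max())


def validate_membership(rho: np.ndarray, *, tol: float = 1e-9) -> np.ndarray:
    """Check that ``rho`` is a valid N x K membership matrix and return it."""
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 2:
        raise ValueError("membership must be a 2-d N x K matrix")
    if np.any(rho < -tol):
        raise ValueError("membership entries must be nonnegative")
    if not np.allclose(rho.sum(axis=1), 1.0, atol=tol, rtol=0.0):
        bad = int(np.argmax(np.abs(rho.sum(axis=1) - 1.0)))
        raise ValueError(f"membership row {bad} does not sum to 1")
    return rho


def lumped_stationary(rho: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Aggregated stationary weights mu_hat[k] = sum_x mu[x] rho[x, k]."""
    rho = np.asarray(rho, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if rho.shape[0] != mu.shape[0]:
        raise ValueError("rho and mu disagree on N")
    mu_hat = rho.T @ mu
    if np.any(mu_hat <= 0):
        k = int(np.flatnonzero(mu_hat <= 0)[0])
        raise DegenerateClusterError(f"cluster {k} has zero stationary mass")
    return mu_hat


def indicator(part: Partition) -> np.ndarray:
    """Indicator membership: rho[x, k] = 1 iff node x is in cluster k."""
    rho = np.zeros((part.N, part.K))
    rho[np.arange(part.N), part.assignment] = 1.0
    return rho


def lump_hard(chain: MarkovChain, part: Partition) -> LumpedChain:
    """Lump a chain over a hard partition (stationary-weighted aggregation)."""
    return lump_fuzzy(chain, indicator(part))


def lump_fuzzy(chain: MarkovChain, rho: np.ndarray) -> LumpedChain:
    """Lump a chain over a fuzzy membership matrix.

    Reduces to :func:`lump_hard` when ``rho`` is an indicator matrix.
    The result satisfies lumped detailed balance
    ``mu_hat[k] p_hat[k,l] = mu_hat[l] p_hat[l,k]`` whenever the input
    chain is reversible.
    """
    rho = validate_membership(rho)
    mu_hat = lumped_stationary(rho, chain.mu)
    flux = rho.T @ (chain.mu[:, None] * chain.P) @ rho  # K x K aggregated flux
    p_hat = flux / mu_hat[:, None]
    return LumpedChain(p_hat=p_hat, mu_hat=mu_hat)


def lift(
    lumped: LumpedChain, rho: np.ndarray, mu: np.ndarray
) -> np.ndarray:
    """Lift a lumped chain back to an N x N row-stochastic matrix.

    ``p_tilde[x, y] = sum_{k,l} rho[x,k] p_hat[k,l] mu[y] rho[y,l] / mu_hat[l]``.
    Each row of the result sums to 1 for any row-stochastic ``p_hat``.
    """
    rho = np.asarray(rho, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(lumped.mu_hat <= 0):
        k = int(np.flatnonzero(lumped.mu_hat <= 0)[0])
        raise DegenerateClusterError(f"cluster {k} has zero stationary mass")
    # Lambda[l, y] = mu[y] rho[y, l] / mu_hat[l]: conditional node distribution
    lam = (mu[None, :] * rho.T) / lumped.mu_hat[:, None]
    return rho @ lumped.p_hat @ lam


def objective(
    chain: MarkovChain,
    rho: np.ndarray,
    lumped: LumpedChain,
    weighting: str = "stationary",
) -> float:
    """Hilbert-Schmidt distance between the chain and the lifted lumped chain.

    ``weighting="stationary"`` (default, the convention used throughout this
    package) weights the squared residual at (x, y) by ``mu[x]/mu[y]``;
    ``weighting="frobenius"`` uses the unweighted Frobenius norm.
    """
    p_tilde = lift(lumped, rho, chain.mu)
    E = chain.P - p_tilde
    if weighting == "stationary":
        W = chain.mu[:, None] / chain.mu[None, :]
    elif weighting == "frobenius":
        W = 1.0
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return float(np.sum(W * E * E))


def optimal_lumped(chain: MarkovChain, rho: np.ndarray) -> LumpedChain:
    """Lumped chain used as the optimal reduced chain for a membership.

    For hard (indicator) memberships this is provably the unique minimizer
    of the stationary-weighted objective over K x K matrices: the
    stationarity condition in ``p_hat`` reads ``R' M (P - P_tilde) R = 0``
    and the aggregation formula solves it exactly when ``R' M R`` is
    diagonal, which holds precisely for indicator ``R``. For genuinely
    fuzzy memberships the exact unconstrained minimizer (available as
    :func:`unconstrained_optimal_phat`) may leave the probability simplex;
    the aggregation formula is the canonical stochastic surrogate and is
    what the optimizer maintains.
    """
    return lump_fuzzy(chain, rho)


def unconstrained_optimal_phat(chain: MarkovChain, rho: np.ndarray) -> np.ndarray:
    """Exact unconstrained minimizer of J over ``p_hat`` for fixed ``rho``.

    Solves ``C p_hat diag(mu_hat)^-1 C = R' M P R`` with ``C = R' M R``.
    The result is row-stochastic (rows sum to 1) but may contain negative
    entries for fuzzy memberships; it coincides with
    :func:`optimal_lumped` on indicator memberships.
    """
    rho = validate_membership(rho)
    mu = chain.mu
    mu_hat = lumped_stationary(rho, mu)
    C = rho.T @ (mu[:, None] * rho)
    B = rho.T @ (mu[:, None] * chain.P) @ rho
    Ci = np.linalg.inv(C)
    p_hat = Ci @ B @ Ci @ np.diag(mu_hat)
    if not np.allclose(p_hat.sum(axis=1), 1.0, atol=1e-8):
        warnings.warn("unconstrained optimal p_hat rows deviate from sum 1")
    return p_hat
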