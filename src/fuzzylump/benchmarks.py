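"""Benchmark networks and evaluation statistics.

Two standard test beds for soft community detection:

* the planted-partition ("ad hoc") benchmark — 128 nodes in four equal
  clusters, expected degree 16, with the mixing controlled by the expected
  out-of-cluster degree ``z_out``;
* the Zachary karate club friendship network (34 members, 78 edges),
  shipped as package data together with the faction alignment observed
  when the club split.

Evaluation statistics: the degree fraction (the fraction of a node's edges
landing in each reference cluster, a natural soft reference label), the
mean / max row-wise l-infinity error between a fitted membership and the
degree fraction, majority-rule hardening, and membership histograms (the
two-peak structure of a well-recovered planted partition).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.optimize import linear_sum_assignment

from .network import Network, load_network
from .lumping import Partition, validate_membership

__all__ = [
    "AdHocSpec",
    "generate_ad_hoc",
    "degree_fraction",
    "membership_error",
    "majority_rule",
    "membership_histogram",
    "align_columns",
    "permutation_agreement",
    "karate_fixture",
    "karate_factions",
]

logger = logging.getLogger(__name__)


@dataclass
class AdHocSpec:
    """Parameters of the planted-partition benchmark.

    ``z_in + z_out = avg_degree`` fixes the intra/inter link probabilities:
    ``p_in = z_in / (N/K - 1)`` and ``p_out = z_out / (N - N/K)``.
    """

    N: int = 128
    K: int = 4
    avg_degree: float = 16.0
    z_out: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N % self.K != 0:
            raise ValueError("N must be divisible by K")
        if not 0.0 <= self.z_out <= self.avg_degree:
            raise ValueError("z_out must lie in [0, avg_degree]")

    @property
    def z_in(self) -> float:
        return self.avg_degree - self.z_out

    @property
    def p_in(self) -> float:
        return self.z_in / (self.N // self.K - 1)

    @property
    def p_out(self) -> float:
        return self.z_out / (self.N - self.N // self.K)


def generate_ad_hoc(spec: AdHocSpec) -> tuple[Network, Partition]:
    """Sample a planted-partition network and return it with its labels.

    Intra-cluster pairs are linked independently with ``p_in``,
    inter-cluster pairs with ``p_out``. Nodes that come out isolated have
    their incident pairs re-drawn so the returned network is valid.
    """
    if not 0.0 <= spec.p_in <= 1.0 or not 0.0 <= spec.p_out <= 1.0:
        raise ValueError("derived p_in/p_out outside [0, 1]")
    if spec.z_out == 0.0:
        warnings.warn(
            "z_out = 0: the planted clusters are disconnected blocks",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    N, K = spec.N, spec.K
    labels = np.repeat(np.arange(K), N // K)
    prob = np.where(labels[:, None] == labels[None, :], spec.p_in, spec.p_out)
    upper = np.triu(rng.random((N, N)) < prob, k=1)
    A = (upper | upper.T).astype(float)
    # re-draw the incident pairs of isolated nodes until none remain
    for _ in range(1000):
        isolated = np.flatnonzero(A.sum(axis=1) == 0)
        if isolated.size == 0:
            break
        for x in isolated:
            draws = rng.random(N) < prob[x]
            draws[x] = False
            A[x, :] = A[:, x] = draws.astype(float)
    else:  # pragma: no cover - astronomically unlikely for sane specs
        raise RuntimeError("failed to remove isolated nodes")
    net = Network(node_ids=[str(i + 1) for i in range(N)], W=A)
    return net, Partition(assignment=labels, K=K)


def degree_fraction(net: Network, ref: Partition) -> np.ndarray:
    """e[x, k]: fraction of node x's edge weight landing in reference cluster k."""
    if ref.N != net.N:
        raise ValueError("partition does not cover the network's nodes")
    ind = np.zeros((net.N, ref.K))
    ind[np.arange(net.N), ref.assignment] = 1.0
    n_xk = net.W @ ind
    d = net.degrees
    return n_xk / d[:, None]


def align_columns(rho: np.ndarray, ref_soft: np.ndarray) -> np.ndarray:
    """Permute the columns of ``rho`` to best match a reference soft labeling.

    Maximum-overlap assignment (Hungarian) on the K x K column-overlap
    matrix; cluster labels are arbitrary, so errors are only meaningful
    after this alignment.
    """
    rho = np.asarray(rho, dtype=float)
    ref_soft = np.asarray(ref_soft, dtype=float)
    overlap = rho.T @ ref_soft
    rows, cols = linear_sum_assignment(-overlap)
    perm = np.empty_like(cols)
    perm[cols] = rows
    return rho[:, perm]


def membership_error(
    rho: np.ndarray, e: np.ndarray, align: bool = True
) -> tuple[float, float]:
    """Mean and max row-wise l-infinity deviation between rho and e."""
    rho = np.asarray(rho, dtype=float)
    e = np.asarray(e, dtype=float)
    if rho.shape != e.shape:
        raise ValueError(f"shape mismatch: {rho.shape} vs {e.shape}")
    if align:
        rho = align_columns(rho, e)
    per_node = np.abs(rho - e).max(axis=1)
    return float(per_node.mean()), float(per_node.max())


def majority_rule(rho: np.ndarray) -> Partition:
    """Harden a membership: each node goes to its maximum-probability cluster.

    Ties are broken toward the lowest cluster index (and logged).
    """
    rho = validate_membership(rho)
    hard = rho.argmax(axis=1)  # argmax takes the first maximum: lowest index
    n_ties = int(np.sum((rho == rho.max(axis=1, keepdims=True)).sum(axis=1) > 1))
    if n_ties:
        logger.info("majority rule: %d tied node(s) broken to lowest index", n_ties)
    present = np.unique(hard)
    relabel = {int(k): i for i, k in enumerate(present)}
    return Partition(
        assignment=np.array([relabel[int(k)] for k in hard]), K=len(present)
    )


def membership_histogram(
    rho: np.ndarray, bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster histograms of the membership values.

    Returns ``(counts, edges)`` where ``counts[k]`` is the histogram of
    ``{rho[x, k] : all x}`` on shared [0, 1] bin edges. For a well-resolved
    planted cluster the histogram is bimodal: a small peak near the
    in-cluster membership level and a large peak near zero from all the
    nodes outside the cluster.
    """
    rho = validate_membership(rho)
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts = np.stack([np.histogram(rho[:, k], bins=edges)[0] for k in range(rho.shape[1])])
    return counts, edges


def permutation_agreement(found: Partition, ref: Partition) -> float:
    """Fraction of nodes whose labels match under the best label permutation."""
    if found.N != ref.N:
        raise ValueError("partitions cover different node sets")
    K = max(found.K, ref.K)
    conf = np.zeros((K, K))
    for a, b in zip(found.assignment, ref.assignment):
        conf[a, b] += 1
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / found.N)


def karate_fixture() -> Network:
    """The Zachary karate club friendship network (34 nodes, 78 edges)."""
    text = resources.files("fuzzylump.data").joinpath("karate.txt").read_text()
    return load_network(text, format="edgelist", weighted=False)


def karate_factions() -> Partition:
    """Zachary's two-faction alignment of the 34 members.

    Cluster 0 is the instructor's (Mr. Hi's) faction, cluster 1 the
    administrator's. Individual 9 is placed with the administrator's
    faction (his recorded political alignment before the fission). The
    assignment is ordered like :func:`karate_fixture`'s node indexing, so
    it compares directly against partitions fitted on that network.
    """
    text = resources.files("fuzzylump.data").joinpath("karate_factions.txt").read_text()
    group_of: dict[str, int] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        node, group = line.split()
        group_of[node] = int(group) - 1
    net = karate_fixture()
    assign = np.array([group_of[label] for label in net.node_ids])
    return Partition(assignment=assign, K=2)
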