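"""Weighted undirected networks and their random-walk Markov chains.

A network with symmetric nonnegative weight matrix ``W`` induces a
discrete-time Markov chain with transition probabilities

    p(x, y) = w(x, y) / d(x),        d(x) = sum_y w(x, y),

whose stationary distribution is degree-proportional,

    mu(x) = d(x) / sum_z d(z),

and which satisfies detailed balance, mu(x) p(x, y) = mu(y) p(y, x).
Everything downstream (lumping, lifting, the Hilbert-Schmidt objective)
relies on this reversible structure, so directed input is rejected.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Network",
    "MarkovChain",
    "NetworkError",
    "load_network",
    "build_chain",
    "check_detailed_balance",
]

#: tolerance used when validating symmetry of an input weight matrix
SYMMETRY_TOL = 1e-10


class NetworkError(ValueError):
    """Raised for invalid network input (asymmetry, negative weights, ...)."""


@dataclass
class Network:
    """An undirected weighted network.

    Attributes
    ----------
    node_ids : list of str
        Node labels in order of first appearance in the input. All matrices
        are indexed in this order.
    W : ndarray, shape (N, N)
        Symmetric nonnegative weight matrix. Self-loops sit on the diagonal.
    """

    node_ids: list[str]
    W: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.node_ids)
        if self.W.shape != (n, n):
            raise NetworkError(
                f"weight matrix shape {self.W.shape} does not match "
                f"{n} node labels"
            )
        if np.any(self.W < 0):
            x, y = np.argwhere(self.W < 0)[0]
            raise NetworkError(
                f"negative weight between {self.node_ids[x]!r} and "
                f"{self.node_ids[y]!r}"
            )
        if not np.allclose(self.W, self.W.T, atol=SYMMETRY_TOL, rtol=0.0):
            raise NetworkError("weight matrix is not symmetric")
        deg = self.W.sum(axis=1)
        if np.any(deg == 0):
            bad = [self.node_ids[i] for i in np.flatnonzero(deg == 0)]
            raise NetworkError(f"isolated node(s) with zero degree: {bad}")

    @property
    def N(self) -> int:
        """Number of nodes."""
        return len(self.node_ids)

    @property
    def M(self) -> int:
        """Number of edges (unordered pairs with positive weight)."""
        upper = np.triu(self.W, k=1)
        loops = np.diag(self.W)
        return int(np.count_nonzero(upper) + np.count_nonzero(loops))

    @property
    def degrees(self) -> np.ndarray:
        """Weighted degrees d(x) = sum_y w(x, y)."""
        return self.W.sum(axis=1)


@dataclass
class MarkovChain:
    """Random-walk Markov chain of a network.

    ``P`` is row-stochastic, ``mu`` is the (degree-proportional) stationary
    distribution. ``node_ids`` is carried along for reporting.
    """

    P: np.ndarray = field(repr=False)
    mu: np.ndarray = field(repr=False)
    node_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        n = self.P.shape[0]
        if self.P.shape != (n, n) or self.mu.shape != (n,):
            raise ValueError("inconsistent P / mu shapes")
        if not np.allclose(self.P.sum(axis=1), 1.0, atol=1e-12, rtol=0.0):
            raise ValueError("P is not row-stochastic")
        if abs(self.mu.sum() - 1.0) > 1e-12:
            raise ValueError("mu does not sum to 1")

    @property
    def N(self) -> int:
        return self.P.shape[0]


def _parse_edgelist(text: str, weighted: bool) -> tuple[list[str], np.ndarray]:
    index: dict[str, int] = {}
    edges: list[tuple[int, int, float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2 or len(parts) > 3:
            raise NetworkError(f"line {lineno}: expected 'u v [w]', got {raw!r}")
        u, v = parts[0], parts[1]
        if len(parts) == 3:
            if not weighted:
                raise NetworkError(
                    f"line {lineno}: weight column present but weighted=False"
                )
            try:
                w = float(parts[2])
            except ValueError:
                raise NetworkError(f"line {lineno}: bad weight {parts[2]!r}") from None
        else:
            w = 1.0
        if w < 0:
            raise NetworkError(f"line {lineno}: negative weight {w}")
        for lab in (u, v):
            if lab not in index:
                index[lab] = len(index)
        edges.append((index[u], index[v], w))
    if not edges:
        raise NetworkError("empty edge list")
    n = len(index)
    W = np.zeros((n, n))
    for i, j, w in edges:
        if i == j:
            W[i, i] += w  # self-loop: counted once on the diagonal
        else:
            W[i, j] += w
            W[j, i] += w
    labels = [lab for lab, _ in sorted(index.items(), key=lambda kv: kv[1])]
    return labels, W


def _parse_matrix(text: str) -> tuple[list[str], np.ndarray]:
    rows = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        rows.append([float(v) for v in line.replace(",", " ").split()])
    if not rows:
        raise NetworkError("empty matrix input")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1 or lengths.pop() != len(rows):
        raise NetworkError(f"matrix is not square: {len(rows)} rows")
    W = np.array(rows, dtype=float)
    labels = [str(i + 1) for i in range(len(rows))]
    return labels, W


def load_network(
    source: str | os.PathLike | io.TextIOBase,
    format: str = "edgelist",
    weighted: bool = True,
) -> Network:
    """Read a network from an edge list or a square weight matrix.

    Parameters
    ----------
    source
        Path to a file, an open text stream, or the raw text itself
        (a string containing a newline or whitespace-separated tokens).
    format
        ``"edgelist"``: lines ``u v [w]``; comments start with ``#``;
        duplicate edges are summed and the edge set is symmetrized.
        ``"matrix"``: a delimited square numeric block.
    weighted
        For edge lists, whether a third weight column is allowed.

    Returns
    -------
    Network
        Validated symmetric network (raises :class:`NetworkError` on
        asymmetry, negative weights or isolated nodes).
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        raise NetworkError(f"cannot read network from {source!r}")

    if format == "edgelist":
        labels, W = _parse_edgelist(text, weighted)
    elif format == "matrix":
        labels, W = _parse_matrix(text)
    else:
        raise NetworkError(f"unknown format {format!r}")
    return Network(node_ids=labels, W=W)


def network_from_adjacency(W: np.ndarray, node_ids: list[str] | None = None) -> Network:
    """Wrap an in-memory symmetric weight matrix as a :class:`Network`."""
    W = np.asarray(W, dtype=float)
    if node_ids is None:
        node_ids = [str(i + 1) for i in range(W.shape[0])]
    return Network(node_ids=list(node_ids), W=W)


def build_chain(net: Network) -> MarkovChain:
    """Build the random-walk chain: p(x,y) = w(x,y)/d(x), mu ∝ degree."""
    d = net.degrees
    P = net.W / d[:, None]
    mu = d / d.sum()
    return MarkovChain(P=P, mu=mu, node_ids=list(net.node_ids))


def check_detailed_balance(chain: MarkovChain) -> float:
    """Maximum violation of mu(x) p(x,y) = mu(y) p(y,x) over all pairs."""
    flux = chain.mu[:, None] * chain.P
    return float(np.abs(flux - flux.T).max())
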