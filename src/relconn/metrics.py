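"""Directed graph indices: Q, GE, LE, CC, T, R.

All six indices are computed on binary adjacency matrices with the
``A[i, j] = 1  <=>  edge i -> j`` convention, using the directed
formulations standard in network neuroscience:

* modularity ``Q = (1/m) sum_ij (A_ij - k_i^out k_j^in / m) d(c_i, c_j)``
  maximized over community partitions;
* global efficiency ``GE = (1/(n(n-1))) sum_{i != j} 1/d_ij`` with
  unreachable pairs contributing zero (``d`` = directed shortest path);
* local efficiency ``LE`` = mean over nodes of the GE of the subgraph
  induced on the union of a node's in- and out-neighbors;
* directed clustering (Fagiolo) with triangle count
  ``t_i = (1/2) [(A + A^T)^3]_ii`` and denominator
  ``k_i^tot (k_i^tot - 1) - 2 k_i^<->``;
* transitivity ``T = sum_i t_i / sum_i [k_i^tot (k_i^tot-1) - 2 k_i^<->]``;
* assortativity ``R`` = Pearson correlation of (source out-degree,
  sink in-degree) over directed edges.

Zero-denominator nodes contribute 0 (rather than being dropped) so means
stay comparable across subjects at fixed n; degree-degenerate assortativity
is returned as NaN.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .network import BinaryNetwork


@dataclass
class CommunityPartition:
    labels: np.ndarray
    q: float


@dataclass
class GraphIndices:
    Q: float
    GE: float
    LE: float
    CC: float
    T: float
    R: float

    def as_dict(self) -> dict[str, float]:
        return {"Q": self.Q, "GE": self.GE, "LE": self.LE,
                "CC": self.CC, "T": self.T, "R": self.R}


def _adj(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    A = net.A if isinstance(net, BinaryNetwork) else np.asarray(net)
    return (A != 0).astype(int)


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

def directed_modularity_value(A: np.ndarray, labels: np.ndarray) -> float:
    """Evaluate directed Q at a given partition (the printed objective)."""
    A = _adj(A)
    m = A.sum()
    if m == 0:
        raise ValueError("modularity undefined for an empty graph")
    k_out = A.sum(axis=1)
    k_in = A.sum(axis=0)
    B = A - np.outer(k_out, k_in) / m
    same = labels[:, None] == labels[None, :]
    return float((B * same).sum() / m)


def _partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, k: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(k + 1):
            labels[i] = c
            yield from rec(i + 1, max(k, c + 1))

    yield from rec(1, 1) if n > 1 else iter([labels.copy()])


def _exact_modularity(A: np.ndarray) -> tuple[float, np.ndarray]:
    best_q, best_labels = -np.inf, None
    for labels in _partitions(A.shape[0]):
        q = directed_modularity_value(A, labels)
        if q > best_q + 1e-15:
            best_q, best_labels = q, labels
    return best_q, best_labels


def _greedy_modularity(A: np.ndarray, rng: np.random.Generator) -> tuple[float, np.ndarray]:
    """Greedy agglomeration followed by single-node relocation passes."""
    n = A.shape[0]
    m = A.sum()
    k_out = A.sum(axis=1)
    k_in = A.sum(axis=0)
    B = (A - np.outer(k_out, k_in) / m) / m
    Bs = B + B.T                                  # merge gain matrix
    labels = np.arange(n)                          # singleton start

    def community_gain(labels: np.ndarray) -> np.ndarray:
        comms = np.unique(labels)
        k = len(comms)
        M = np.zeros((k, k))
        for a in range(k):
            ia = labels == comms[a]
            for b in range(a + 1, k):
                ib = labels == comms[b]
                M[a, b] = Bs[np.ix_(ia, ib)].sum()
        return comms, M

    # agglomeration
    improved = True
    while improved:
        improved = False
        comms, M = community_gain(labels)
        if len(comms) < 2:
            break
        a, b = np.unravel_index(np.argmax(M), M.shape)
        if M[a, b] > 1e-13:
            labels[labels == comms[b]] = comms[a]
            improved = True

    # relocation refinement
    for _ in range(50):
        moved = False
        for i in rng.permutation(n):
            current = labels[i]
            others = np.unique(labels)
            # gain of moving i from its community to community c
            base = Bs[i, labels == current].sum() - Bs[i, i]
            best_gain, best_c = 0.0, current
            for c in others:
                if c == current:
                    continue
                gain = Bs[i, labels == c].sum() - base
                if gain > best_gain + 1e-13:
                    best_gain, best_c = gain, c
            if best_c != current:
                labels[i] = best_c
                moved = True
        if not moved:
            break
    return directed_modularity_value(A, labels), labels


def modularity(net: BinaryNetwork | np.ndarray, seed: int = 0,
               n_restarts: int = 20, exact_max: int = 8) -> tuple[float, CommunityPartition]:
    """Maximize directed modularity; exact for n <= ``exact_max``.

    Tiny graphs are solved by enumeration over all set partitions; larger
    graphs use seeded greedy agglomeration with relocation refinement and
    ``n_restarts`` restarts (best-of).
    """
    A = _adj(net)
    if A.sum() == 0:
        raise ValueError("modularity requires at least one edge")
    if A.shape[0] <= exact_max:
        q, labels = _exact_modularity(A)
    else:
        rng = np.random.default_rng(seed)
        q, labels = -np.inf, None
        for _ in range(n_restarts):
            qq, ll = _greedy_modularity(A, rng)
            if qq > q:
                q, labels = qq, ll
    return q, CommunityPartition(labels, q)


# ---------------------------------------------------------------------------
# efficiency / clustering / assortativity
# ---------------------------------------------------------------------------

def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    A = _adj(net)
    n = A.shape[0]
    if n < 2:
        raise ValueError("global efficiency requires n >= 2")
    D = shortest_path(A, method="D", directed=True, unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    A = _adj(net)
    n = A.shape[0]
    acc = 0.0
    for i in range(n):
        nbrs = np.where((A[i] | A[:, i]) & (np.arange(n) != i))[0]
        if len(nbrs) < 2:
            continue
        acc += global_efficiency(A[np.ix_(nbrs, nbrs)])
    return acc / n


def _triangles_and_denominator(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    Asym = A + A.T
    t = np.diag(np.linalg.matrix_power(Asym, 3)) / 2.0
    k_tot = A.sum(axis=1) + A.sum(axis=0)
    k_rec = np.diag(A @ A)
    denom = k_tot * (k_tot - 1) - 2 * k_rec
    return t, denom.astype(float)


def clustering(net: BinaryNetwork | np.ndarray) -> float:
    """Mean directed (Fagiolo) clustering coefficient."""
    A = _adj(net)
    if A.shape[0] < 3:
        raise ValueError("clustering requires n >= 3")
    t, denom = _triangles_and_denominator(A)
    cc = np.where(denom > 0, t / np.where(denom > 0, denom, 1.0), 0.0)
    return float(cc.mean())


def transitivity(net: BinaryNetwork | np.ndarray) -> float:
    A = _adj(net)
    if A.shape[0] < 3:
        raise ValueError("transitivity requires n >= 3")
    t, denom = _triangles_and_denominator(A)
    total = denom.sum()
    return float(t.sum() / total) if total > 0 else 0.0


def assortativity(net: BinaryNetwork | np.ndarray) -> float:
    """Out-in degree assortativity over directed edges (NaN when degenerate)."""
    A = _adj(net)
    src, dst = np.nonzero(A)
    if len(src) < 2:
        return float("nan")
    x = A.sum(axis=1)[src].astype(float)   # source out-degree
    y = A.sum(axis=0)[dst].astype(float)   # sink in-degree
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def compute_indices(net: BinaryNetwork | np.ndarray, seed: int = 0,
                    n_restarts: int = 20) -> GraphIndices:
    """All six indices of one binary network."""
    q, _ = modularity(net, seed=seed, n_restarts=n_restarts)
    return GraphIndices(
        Q=q,
        GE=global_efficiency(net),
        LE=local_efficiency(net),
        CC=clustering(net),
        T=transitivity(net),
        R=assortativity(net),
    )
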