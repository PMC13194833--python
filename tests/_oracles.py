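"""Deliberately naive reference implementations used as independent oracles.

Everything here is written as explicit loops over nodes/pairs/partitions so
that agreement with the vectorized package implementations is a meaningful
cross-check rather than a tautology.
"""

import itertools

import numpy as np
import networkx as nx


def oracle_ge(A):
    n = A.shape[0]
    G = nx.from_numpy_array(A, create_using=nx.DiGraph)
    total = 0.0
    for i in range(n):
        lengths = nx.single_source_shortest_path_length(G, i)
        for j in range(n):
            if j != i and j in lengths and lengths[j] > 0:
                total += 1.0 / lengths[j]
    return total / (n * (n - 1))


def oracle_le(A):
    n = A.shape[0]
    acc = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and (A[i, j] or A[j, i])]
        if len(nbrs) >= 2:
            acc += oracle_ge(A[np.ix_(nbrs, nbrs)])
    return acc / n


def oracle_triangles(A, i):
    n = A.shape[0]
    t = 0.0
    for j in range(n):
        for h in range(n):
            if j == i or h == i or j == h:
                continue
            t += (A[i, j] + A[j, i]) * (A[i, h] + A[h, i]) * (A[j, h] + A[h, j])
    return t / 2.0


def oracle_cc(A):
    n = A.shape[0]
    vals = []
    for i in range(n):
        ktot = A[i].sum() + A[:, i].sum()
        krec = (A[i] * A[:, i]).sum()
        denom = ktot * (ktot - 1) - 2 * krec
        vals.append(oracle_triangles(A, i) / denom if denom > 0 else 0.0)
    return float(np.mean(vals))


def oracle_t(A):
    n = A.shape[0]
    num = sum(oracle_triangles(A, i) for i in range(n))
    den = 0.0
    for i in range(n):
        ktot = A[i].sum() + A[:, i].sum()
        krec = (A[i] * A[:, i]).sum()
        den += ktot * (ktot - 1) - 2 * krec
    return num / den if den > 0 else 0.0


def oracle_r(A):
    edges = [(i, j) for i, j in zip(*np.nonzero(A))]
    if len(edges) < 2:
        return float("nan")
    x = np.array([A[i].sum() for i, _ in edges], float)
    y = np.array([A[:, j].sum() for _, j in edges], float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def partitions_oracle(n):
    """Set partitions as restricted-growth label assignments."""
    for assign in itertools.product(*[range(i + 1) for i in range(n)]):
        mx = -1
        ok = True
        for a in assign:
            if a > mx + 1:
                ok = False
                break
            mx = max(mx, a)
        if ok:
            yield np.array(assign)


def oracle_q_value(A, labels):
    """Directed modularity at one partition, summed pair by pair."""
    m = A.sum()
    k_out = [A[i].sum() for i in range(A.shape[0])]
    k_in = [A[:, j].sum() for j in range(A.shape[0])]
    q = 0.0
    for i in range(A.shape[0]):
        for j in range(A.shape[0]):
            if labels[i] == labels[j]:
                q += A[i, j] - k_out[i] * k_in[j] / m
    return q / m


def oracle_q(A):
    """Exhaustive directed modularity over all set partitions."""
    best = -np.inf
    for labels in partitions_oracle(A.shape[0]):
        best = max(best, oracle_q_value(A, labels))
    return best


def oracle_q_nx(A):
    """Exhaustive Q using networkx's directed modularity (extra oracle)."""
    G = nx.from_numpy_array(A, create_using=nx.DiGraph)
    best = -np.inf
    for labels in partitions_oracle(A.shape[0]):
        comms = [set(np.where(labels == c)[0]) for c in np.unique(labels)]
        best = max(best, nx.algorithms.community.modularity(G, comms))
    return best
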