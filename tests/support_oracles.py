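"""Independent brute-force oracles shared by the test suite.

Exhaustive modularity maximization (all set partitions of small graphs) and
hand-computed node-role metrics — deliberately independent of the package's
Louvain implementation.
"""

import numpy as np

from alenet.network import modularity


def all_partitions(n):
    def rec(elems):
        if not elems:
            yield []
            return
        first, rest = elems[0], elems[1:]
        for p in rec(rest):
            for i in range(len(p)):
                yield p[:i] + [p[i] + [first]] + p[i + 1:]
            yield p + [[first]]

    for p in rec(list(range(n))):
        lab = np.zeros(n, dtype=int)
        for c, grp in enumerate(p):
            lab[list(grp)] = c
        yield lab


def exhaustive_max_q(W, gamma=1.0):
    return max(modularity(W, lab, gamma) for lab in all_partitions(len(W)))


def _edges(n, pairs, w=1.0):
    W = np.zeros((n, n))
    for a, b in pairs:
        W[a, b] = W[b, a] = w
    return W


def oracle_graphs():
    """Small graphs for exhaustive-vs-Louvain comparison (<= 10 nodes)."""
    rng = np.random.default_rng(123)
    graphs = [
        ("two disconnected triangles", _edges(6, [(0, 1), (1, 2), (0, 2),
                                                  (3, 4), (4, 5), (3, 5)])),
        ("barbell", _edges(8, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5),
                               (2, 3), (5, 6), (6, 7), (5, 7)])),
        ("ring of 10", _edges(10, [(i, (i + 1) % 10) for i in range(10)])),
    ]
    for k in range(2):
        n = 8
        W = (rng.random((n, n)) < 0.4).astype(float) * rng.random((n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        graphs.append((f"random weighted {k}", W))
    return graphs


def hand_metric_cases():
    """(W, labels, expected P, expected z_within) computed by hand."""
    cases = []

    # 1. two triangles: all strength within own module -> P = 0; regular
    #    within-module degree -> z = 0
    W1 = _edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    lab1 = np.array([1, 1, 1, 2, 2, 2])
    cases.append((W1, lab1, np.zeros(6), np.zeros(6)))

    # 2. star node 0 splitting its strength evenly over two 2-node modules:
    #    P_0 = 1 - 2*(2/4)^2 = 0.5; leaves have all strength in one module.
    #    No within-module edges anywhere -> z = 0.
    W2 = _edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])
    lab2 = np.array([3, 1, 1, 2, 2])
    cases.append((W2, lab2, np.array([0.5, 0, 0, 0, 0]), np.zeros(5)))

    # 3. one module, hub with within-strengths k = [3, 2, 2, 1]:
    #    z = (k - 2) / sqrt(0.5); single module -> P = 0
    W3 = _edges(4, [(0, 1), (0, 2), (0, 3), (1, 2)])
    lab3 = np.ones(4, dtype=int)
    z3 = (np.array([3.0, 2.0, 2.0, 1.0]) - 2.0) / np.sqrt(0.5)
    cases.append((W3, lab3, np.zeros(4), z3))

    return cases
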