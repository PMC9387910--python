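"""Independent brute-force oracles used by the acceptance tests.

These deliberately avoid the package's own code paths: indices are computed
by explicit edge-set scans and the ranked FDR by a double loop.
"""

import numpy as np


def brute_force_network_indices(graph):
    edges = set(graph.edges())
    nodes = list(graph.nodes())
    n = len(edges)
    N = len(nodes)
    cs = {}
    ncf = {}
    for v in nodes:
        n_o = sum(1 for (a, _) in edges if a == v)
        n_i = sum(1 for (_, b) in edges if b == v)
        cs[v] = n_o / (n_o + n_i) if (n_o + n_i) else None
        ncf[v] = n_o - n_i
    n_recip = sum(1 for (a, b) in edges if (b, a) in edges)
    return {
        "cd": n / (2 * N * (N - 1)),
        "ge": 1 - (n - (N - 1)) / (N * (N - 1)),
        "c_recip": n_recip / n if n else None,
        "cs": cs,
        "ncf": ncf,
    }


def brute_force_ranked_fdr(p_values, crit=0.05):
    p = list(map(float, p_values))
    k = len(p)
    order = sorted(range(k), key=lambda i: p[i])
    q = [k * p[order[i]] / (i + 1) for i in range(k)]
    fdr_sorted = [min(q[i:]) for i in range(k)]
    fdr = [0.0] * k
    for rank, idx in enumerate(order):
        fdr[idx] = fdr_sorted[rank]
    fdr = np.array(fdr)
    return fdr, fdr < crit
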