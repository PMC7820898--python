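"""Independent brute-force oracles used only by the tests."""

import itertools

import numpy as np


def brute_force_elementary_cycles(edges):
    """All elementary directed cycles, by exhaustive path extension.

    Returns canonical tuples (smallest node first).  Exponential — use
    only on small graphs.
    """
    nodes = sorted({n for e in edges for n in e})
    succ = {n: sorted(b for a, b in edges if a == n) for n in nodes}
    cycles = set()

    def extend(path):
        head = path[0]
        for nxt in succ[path[-1]]:
            if nxt == head:
                k = path.index(min(path))
                cycles.add(tuple(path[k:] + path[:k]))
            elif nxt not in path and nxt > head:
                # only roots at the cycle's smallest node: each cycle found once
                extend(path + [nxt])

    for n in nodes:
        extend([n])
    return sorted(cycles, key=lambda c: (len(c), c))


def naive_average_linkage(distances):
    """O(n^3) UPGMA merge heights, independent of SciPy.

    Returns the sorted list of merge heights.
    """
    d = np.asarray(distances, dtype=float)
    clusters = [[i] for i in range(d.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            h = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
            if best is None or h < best[0]:
                best = (h, i, j)
        h, i, j = best
        heights.append(h)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return sorted(heights)


def pair_deviation_quantile(sigma, prob):
    """Closed-form quantile of r = x1 / mean(x1, x2), x_i = c*2^N(0, s^2).

    r = 2 / (1 + 2^(-D)) with D = log2(x1) - log2(x2) ~ N(0, 2 s^2),
    and r is increasing in D, so quantiles map through directly.
    """
    from scipy.stats import norm

    z = norm.ppf(prob)
    return 2.0 / (1.0 + 2.0 ** (-z * sigma * np.sqrt(2.0)))
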