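"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a statistic from its textbook definition with the
simplest possible code (explicit loops, no shared helpers with the package)
so the implementations under test are checked against an independent route.
"""

import itertools

import numpy as np


def bh_stepup(pvals):
    """BH adjusted p: min over j >= rank(i) of p(j) * m / j, clipped at 1."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = []
        for later_pos, j in enumerate(order, start=1):
            if later_pos >= rank_pos:
                candidates.append(p[j] * m / later_pos)
        adj[i] = min(1.0, min(candidates))
    return np.array(adj)


def complete_linkage(dist):
    """O(n^3) agglomerative complete linkage; returns merge heights sorted.

    ``dist`` is a full square distance matrix.  Only the multiset of merge
    heights is returned (cluster labellings are not compared).
    """
    n = len(dist)
    clusters = [{i} for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(dist[i][j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return sorted(heights)


def gsea_running_sum(metrics, in_set, p):
    """Brute-force weighted running sum over a ranked universe.

    ``metrics``: metric per ranked position (descending order assumed);
    ``in_set``: booleans marking set members.  Returns (ES, running list).
    """
    n = len(metrics)
    nh = sum(in_set)
    weights = [abs(metrics[i]) ** p for i in range(n) if in_set[i]]
    total = sum(weights)
    running = []
    s = 0.0
    for i in range(n):
        if in_set[i]:
            s += (abs(metrics[i]) ** p / total) if total > 0 else 1.0 / nh
        else:
            s -= 1.0 / (n - nh)
        running.append(s)
    # extremum: first occurrence of the largest magnitude
    best = running[0]
    for v in running[1:]:
        if abs(v) > abs(best):
            best = v
    return best, running


def exhaustive_es_distribution(metrics, set_size, p):
    """ES of every possible membership of the given size (exhaustive null)."""
    n = len(metrics)
    out = []
    for combo in itertools.combinations(range(n), set_size):
        mask = [i in combo for i in range(n)]
        es, _ = gsea_running_sum(metrics, mask, p)
        out.append(es)
    return np.array(out)


def nes_ratio_fdr(obs_nes, null_nes_pool):
    """Naive NES-ratio FDR q per observed NES (loops over the definition)."""
    qs = []
    pool = list(null_nes_pool)
    for v in obs_nes:
        if v == 0:
            qs.append(1.0)
            continue
        if v > 0:
            n_pos = sum(1 for x in pool if x > 0)
            null_frac = (
                sum(1 for x in pool if x >= v) / n_pos if n_pos else float("nan")
            )
            obs_pos = [x for x in obs_nes if x > 0]
            obs_frac = sum(1 for x in obs_pos if x >= v) / len(obs_pos)
        else:
            n_neg = sum(1 for x in pool if x < 0)
            null_frac = (
                sum(1 for x in pool if x <= v) / n_neg if n_neg else float("nan")
            )
            obs_neg = [x for x in obs_nes if x < 0]
            obs_frac = sum(1 for x in obs_neg if x <= v) / len(obs_neg)
        qs.append(min(null_frac / obs_frac, 1.0))
    return np.array(qs)


def pca_top2_reconstruction(x):
    """Top-2 PC reconstruction via eigendecomposition of the covariance."""
    xc = x - x.mean(axis=0, keepdims=True)
    cov = np.cov(xc, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    idx = np.argsort(vals)[::-1][:2]
    basis = vecs[:, idx]
    return xc @ basis @ basis.T
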