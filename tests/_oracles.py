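"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive (enumeration, full translation,
from-scratch recomputation) and shares no code path with the implementations
under test.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from Bio.Seq import Seq


def translation_effect(cds: str, position: int, alt_base: str) -> str:
    """Classify a substitution by translating the *whole* sequence before
    and after with Biopython's vertebrate mitochondrial table."""
    before = str(Seq(cds).translate(table=2))
    mutated = cds[: position - 1] + alt_base + cds[position:]
    after = str(Seq(mutated).translate(table=2))
    if "*" in after and "*" not in before:
        return "nonsense"
    if after == before:
        return "synonymous"
    return "missense"


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg by the definition: adj(i) = min over all j with
    p_j >= p_i of m * p_j / rank_j, capped at 1."""
    p = np.asarray(p_values, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    rank = np.empty(m, int)
    rank[order] = np.arange(1, m + 1)
    out = np.empty(m)
    for i in range(m):
        candidates = [
            m * p[j] / rank[j]
            for j in range(m)
            if p[j] > p[i] or (p[j] == p[i] and rank[j] >= rank[i])
        ]
        out[i] = min(1.0, min(candidates))
    return out


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration of all 2x2 tables with
    the observed margins, summing those no more likely than observed."""
    (a, b), (c, d) = np.asarray(table, int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0

    def pmf(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    observed = pmf(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = sum(
        pmf(x) for x in range(lo, hi + 1) if pmf(x) <= observed * (1 + 1e-9)
    )
    return min(total, 1.0)


def average_linkage(dist: np.ndarray):
    """O(n^3) agglomeration: at every step, recompute every inter-cluster
    average distance from the original matrix, merge the smallest (ties by
    smallest node-id pair).  Returns scipy-style merge tuples."""
    n = len(dist)
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(sorted(clusters), 2):
            d = float(np.mean([
                dist[a, b] for a in clusters[i] for b in clusters[j]
            ]))
            key = (d, i, j)
            if best is None or key < best:
                best = key
        d, i, j = best
        members = clusters.pop(i) + clusters.pop(j)
        merges.append((i, j, d, len(members)))
        clusters[next_id] = members
        next_id += 1
    return merges


def welch_p_by_permutation(a, b, n_draws: int, seed: int) -> tuple[float, float]:
    """Monte-Carlo permutation two-sided p for the difference in means,
    using the Welch t statistic as the test statistic.  Returns (p, SE)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    na = len(a)

    def tstat(x, y):
        sx = x.var(ddof=1) / len(x)
        sy = y.var(ddof=1) / len(y)
        return (x.mean() - y.mean()) / np.sqrt(sx + sy)

    observed = abs(tstat(a, b))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_draws):
        perm = rng.permutation(pooled)
        if abs(tstat(perm[:na], perm[na:])) >= observed:
            hits += 1
    p = hits / n_draws
    se = np.sqrt(max(p * (1 - p), 1e-12) / n_draws)
    return p, se


def student_t_p(a, b) -> tuple[float, float]:
    """Classical equal-variance two-sample t (closed form) for the
    equal-n case; returns (t, two-sided p) via the t distribution."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, 2 * tdist.sf(abs(t), df)
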