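"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately naive - exact rational arithmetic and full
enumeration - and shares no code with the implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE p by full enumeration over heterozygote counts.

    Conditional probability of h hets given N diploids and m minor copies:
    P(h) = N! / (n_min_hom! h! n_maj_hom!) * 2^h / C(2N, m) ... computed as
    exact rationals and normalised, so only relative ordering matters.
    """
    n = n_hom_ref + n_het + n_hom_alt
    m = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if m == 0:
        return 1.0
    weights = {}
    for h in range(m % 2, m + 1, 2):
        min_hom = (m - h) // 2
        maj_hom = n - h - min_hom
        if maj_hom < 0:
            continue
        # multinomial coefficient times 2^h, as an exact integer weight
        w = Fraction(
            comb(n, h) * comb(n - h, min_hom) * 2**h
        )
        weights[h] = w
    total = sum(weights.values())
    obs = weights[n_het]
    p = sum(w for w in weights.values() if w <= obs) / total
    return float(p)


def mwu_exact_oracle(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments.

    Requires tie-free pooled data. p = min(1, 2*min(P(U <= u), P(U >= u)))
    under the permutation null.
    """
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    n1 = len(x)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    for idx in combinations(range(len(pooled)), n1):
        r = sum(i + 1 for i in idx)
        us.append(r - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def ks_exact_oracle(x, y) -> float:
    """Two-sample K-S p by enumerating all pooled-rank assignments (no ties)."""
    x, y = np.sort(np.asarray(x, float)), np.sort(np.asarray(y, float))
    n1, n2 = len(x), len(y)
    pooled = np.sort(np.concatenate([x, y]))
    assert len(np.unique(pooled)) == n1 + n2, "oracle requires no ties"

    def d_stat(ix: frozenset) -> float:
        cx = cy = 0
        d = 0.0
        for i in range(n1 + n2):
            if i in ix:
                cx += 1
            else:
                cy += 1
            d = max(d, abs(cx / n1 - cy / n2))
        return d

    d_obs = d_stat(frozenset(np.searchsorted(pooled, x)))
    count = total = 0
    for idx in combinations(range(n1 + n2), n1):
        total += 1
        if d_stat(frozenset(idx)) >= d_obs - 1e-12:
            count += 1
    return count / total


def bh_stepup_oracle(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values from the step-up definition."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, i in enumerate(order[::-1]):
        rank = m - rank_from_top  # 1-based rank of p[i] from the smallest
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def hypergeom_tail_oracle(k: int, n_bg: int, big_k: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N=n_bg, K=big_k, n) in exact rationals."""
    total = comb(n_bg, n)
    acc = Fraction(0)
    for j in range(k, min(big_k, n) + 1):
        if n - j <= n_bg - big_k:
            acc += Fraction(comb(big_k, j) * comb(n_bg - big_k, n - j), total)
    return float(acc)
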