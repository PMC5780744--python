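"""Independent straight-line oracles used by the unit and acceptance tests.

These deliberately re-derive results from the narrative rule definitions
with naive linear searches and brute-force enumeration, sharing no code
path with the package implementation they check.
"""

from __future__ import annotations

from itertools import product

import numpy as np

PROM = 5000


def brute_force_tail(pwm, bg, score: float, slack: float = 5e-3) -> float:
    """P(S >= score) by enumerating all 4^w words weighted by background."""
    mat = np.log2(pwm.matrix / bg.array)
    w = pwm.width
    total = 0.0
    for word in product(range(4), repeat=w):
        s = sum(mat[i, b] for i, b in enumerate(word))
        if s >= score - slack:
            total += float(np.prod([bg.array[b] for b in word]))
    return total


def brute_force_threshold(pwm, bg, alpha: float, eps: float = 1e-3) -> float:
    """Exact threshold by sorting all word scores (grid-rounded)."""
    mat = np.log2(pwm.matrix / bg.array)
    w = pwm.width
    scored = []
    for word in product(range(4), repeat=w):
        s = round(sum(mat[i, b] for i, b in enumerate(word)) / eps) * eps
        p = float(np.prod([bg.array[b] for b in word]))
        scored.append((s, p))
    scored.sort(reverse=True)
    mass = 0.0
    threshold = None
    i = 0
    while i < len(scored):
        s = scored[i][0]
        block = 0.0
        while i < len(scored) and scored[i][0] == s:
            block += scored[i][1]
            i += 1
        if mass + block > alpha:
            break
        mass += block
        threshold = s
    return threshold  # None when even the top score exceeds alpha


def enumerate_word_scores(pwm, bg):
    """(scores, probabilities) of all 4^w words, vectorized enumeration."""
    mat = np.log2(pwm.matrix / bg.array)
    w = pwm.width
    words = np.indices((4,) * w).reshape(w, -1)
    scores = mat[np.arange(w)[:, None], words].sum(axis=0)
    probs = np.prod(bg.array[words], axis=0)
    return scores, probs


# ---------------------------------------------------------------------------
# regulatory-domain oracle


def oracle_domain(rule_name: str, gene, genes, chrom_len: int, caps=None):
    """[start, end) of one gene's domain from the narrative definition.

    ``gene``/``genes`` are (tss, strand) tuples; all on one chromosome.
    """
    caps = caps or {"rule1": 300_000, "rule2": 1_000_000}
    tss, strand = gene
    others = [g for g in genes if g[0] != tss]
    left_n = max((g for g in others if g[0] < tss), key=lambda g: g[0], default=None)
    right_n = min((g for g in others if g[0] > tss), key=lambda g: g[0], default=None)

    prom = (max(0, tss - PROM), min(chrom_len, tss + PROM))
    if rule_name == "promoter":
        return prom
    if rule_name == "rule3":
        lo = left_n[0] if left_n else 0
        hi = right_n[0] if right_n else chrom_len
    elif rule_name == "rule4":
        lo = (tss + left_n[0]) // 2 if left_n else 0
        hi = (tss + right_n[0]) // 2 if right_n else chrom_len
    else:  # basal plus extension
        up, down = (5000, 5000) if rule_name == "rule1" else (5000, 1000)
        cap = caps[rule_name]

        def basal(g):
            t, s = g
            return (t - up, t + down) if s == "+" else (t - down, t + up)

        b_lo, b_hi = basal(gene)
        ext_lo = max(tss - cap, basal(left_n)[1] if left_n else 0, 0)
        ext_hi = min(tss + cap, basal(right_n)[0] if right_n else chrom_len, chrom_len)
        lo, hi = min(b_lo, ext_lo), max(b_hi, ext_hi)
    lo, hi = min(lo, prom[0]), max(hi, prom[1])
    return max(0, lo), min(chrom_len, hi)


def oracle_membership(rule_name: str, pos: int, genes, chrom_len: int):
    """Set of gene indices whose domain contains ``pos`` (per-base view)."""
    out = set()
    for i, g in enumerate(genes):
        lo, hi = oracle_domain(rule_name, g, genes, chrom_len)
        if lo <= pos < hi:
            out.add(i)
    return out


# ---------------------------------------------------------------------------
# CTCF forward-reverse shortening oracle


def oracle_fr_shorten(domain, tss, sites):
    """(start, end) after FR shortening; ``sites`` are (start, end, orient).

    A literal walk of the stated rule: candidates strictly inside the
    domain and outside the +-5 kb promoter; on each side, scan outward
    from the TSS, skip wrongly-oriented sites until the first correctly
    oriented one, follow the uninterrupted run, cut at its most external
    site.
    """
    d_lo, d_hi = domain
    p_lo, p_hi = tss - PROM, tss + PROM
    inside = [
        s for s in sites
        if s[0] >= d_lo and s[1] <= d_hi and (s[1] <= p_lo or s[0] >= p_hi)
    ]
    left = sorted((s for s in inside if s[1] <= p_lo), key=lambda s: -s[1])
    right = sorted((s for s in inside if s[0] >= p_hi), key=lambda s: s[0])

    def walk(ordered, want):
        run = None
        for s in ordered:
            if s[2] is None:
                continue
            if s[2] == want:
                run = s
            elif run is not None:
                break
        return run

    lf = walk(left, "F")
    rr = walk(right, "R")
    return (lf[0] if lf else d_lo, rr[1] if rr else d_hi)


def oracle_nearest_shorten(domain, tss, sites):
    """nearest_any mode: cut each side at the candidate closest to the TSS."""
    d_lo, d_hi = domain
    p_lo, p_hi = tss - PROM, tss + PROM
    inside = [
        s for s in sites
        if s[0] >= d_lo and s[1] <= d_hi and (s[1] <= p_lo or s[0] >= p_hi)
    ]
    left = [s for s in inside if s[1] <= p_lo]
    right = [s for s in inside if s[0] >= p_hi]
    lo = max(left, key=lambda s: (s[1], -s[0]))[0] if left else d_lo
    hi = min(right, key=lambda s: s[0])[1] if right else d_hi
    return lo, hi


# ---------------------------------------------------------------------------
# combinatorics


def hypergeom_upper_tail(k: int, N: int, n: int, K: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, n, K), by the literal sum."""
    from math import comb

    total = 0
    for i in range(k, min(n, K) + 1):
        total += comb(n, i) * comb(N - n, K - i)
    return total / comb(N, K)


def bh_qvalues(pvals):
    """Literal step-up BH: q_(i) = min_{j>=i} p_(j) m / j, original order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out
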