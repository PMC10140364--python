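"""Independent brute-force oracles used by the test suite.

These are deliberately naive implementations (exact fractions, full
enumeration, O(n^2) scans) kept separate from the package code they check.
"""

from fractions import Fraction
from math import comb


def binom_tail_exact(m, n, r):
    """P(X >= m) for X ~ Binomial(n, r), summed term by term."""
    return float(sum(comb(n, k) * (r ** k) * ((1 - r) ** (n - k))
                     for k in range(m, n + 1)))


def fisher_two_sided_exact(m1, u1, m2, u2):
    """Two-sided Fisher p by exact-fraction hypergeometric enumeration."""
    N = m1 + u1 + m2 + u2
    K = m1 + m2
    n = m1 + u1

    def pmf(k):
        return Fraction(comb(K, k) * comb(N - K, n - k), comb(N, n))

    kmin = max(0, n - (N - K))
    kmax = min(n, K)
    p_obs = pmf(m1)
    return float(sum(pmf(k) for k in range(kmin, kmax + 1) if pmf(k) <= p_obs))


def hypergeom_tail_exact(k, N, K, n):
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact fractions."""
    hi = min(K, n)
    return float(sum(Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
                     for j in range(k, hi + 1)))


def bh_qvalues_naive(pvalues):
    """Textbook Benjamini-Hochberg: sort, scale, enforce monotonicity."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvalues[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q


def call_dmrs_naive(positions, pvalues, signs, m1, u1, m2, u2,
                    p_threshold=1e-5, sig_proportion=0.5, min_sites=3,
                    min_length=50, merge_gap=100, max_site_gap=500,
                    revalidate=True):
    """Slow re-statement of the region rules on one chromosome/context.

    Returns (start, end, n_sites, n_sig, direction) tuples.
    """
    n = len(positions)
    sig = [pvalues[i] < p_threshold and signs[i] != 0 for i in range(n)]

    runs = []
    for i in range(n):
        if not sig[i]:
            continue
        if (runs and signs[i] == signs[runs[-1][-1]]
                and positions[i] - positions[runs[-1][-1]] <= max_site_gap):
            runs[-1].append(i)
        else:
            runs.append([i])

    def describe(i0, i1, run_sign):
        n_sites = i1 - i0 + 1
        n_sig = sum(1 for j in range(i0, i1 + 1)
                    if sig[j] and signs[j] == run_sign)
        return {
            "i0": i0, "i1": i1, "sign": run_sign,
            "start": positions[i0], "end": positions[i1] + 1,
            "n_sites": n_sites, "n_sig": n_sig,
        }

    def ok(r):
        return (r["n_sites"] >= min_sites
                and (r["end"] - r["start"]) > min_length
                and r["n_sig"] / r["n_sites"] > sig_proportion)

    regions = [describe(run[0], run[-1], signs[run[0]]) for run in runs]
    regions = [r for r in regions if ok(r)]

    merged = []
    for r in regions:
        if (merged and r["sign"] == merged[-1]["sign"]
                and r["start"] - merged[-1]["end"] < merge_gap):
            fused = describe(merged[-1]["i0"], r["i1"], r["sign"])
            fused["was_merged"] = True
            merged[-1] = fused
        else:
            r.setdefault("was_merged", False)
            merged.append(r)

    out = []
    for r in merged:
        if revalidate and r["was_merged"] and not ok(r):
            continue
        span = range(r["i0"], r["i1"] + 1)
        mean1 = sum(m1[j] for j in span) / sum(m1[j] + u1[j] for j in span)
        mean2 = sum(m2[j] for j in span) / sum(m2[j] + u2[j] for j in span)
        out.append((r["start"], r["end"], r["n_sites"], r["n_sig"],
                    "hyper" if mean2 > mean1 else "hypo"))
    return out
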