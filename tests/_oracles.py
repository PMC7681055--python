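"""Independent oracles used by the test suite.

Each oracle is a deliberately naive, literal implementation (rational
arithmetic, per-base interval scans, textbook formulas, exhaustive truth
tables) kept separate from the library code paths it checks.
"""

from fractions import Fraction
from math import comb

import numpy as np
from scipy.stats import chi2


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) by exact enumeration of favourable draw counts."""
    denom = comb(N, n)
    hi = min(K, n)
    s = sum(comb(K, j) * comb(N - K, n - j) for j in range(max(k, 0), hi + 1))
    return Fraction(s, denom)


def hypergeom_tail_logspace(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) computed independently in log space for large universes.

    The log-pmf at the support start is a compensated sum of exact log
    ratios, and subsequent terms follow the log-domain recurrence
    log pmf(j+1) = log pmf(j) + log((K-j)(n-j)) - log((j+1)(N-K-n+j+1)),
    which avoids the catastrophic cancellation of differencing large
    log-gamma values. Requires N >= K + n (support starting at 0), which
    holds for every tested case.
    """
    import math

    if k <= max(0, K + n - N):
        return 1.0
    jmax = min(K, n)
    if k > jmax:
        return 0.0
    if K + n > N:
        raise NotImplementedError("oracle assumes the support starts at 0")
    logp = math.fsum(math.log(N - K - i) - math.log(N - i) for i in range(n))
    logs = []
    for j in range(jmax + 1):
        if j >= k:
            logs.append(logp)
        if j < jmax:
            logp += (math.log(K - j) + math.log(n - j)
                     - math.log(j + 1) - math.log(N - K - n + j + 1))
    m = max(logs)
    return float(math.exp(m) * math.fsum(math.exp(x - m) for x in logs))


def yates_two_prop_oracle(k1: int, n1: int, k2: int, n2: int
                          ) -> tuple[float, float]:
    """Textbook continuity-corrected 2x2 chi-square on two proportions."""
    p_pool = (k1 + k2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 0.0, 1.0
    observed = [k1, n1 - k1, k2, n2 - k2]
    expected = [n1 * p_pool, n1 * (1 - p_pool),
                n2 * p_pool, n2 * (1 - p_pool)]
    dev = [abs(o - e) for o, e in zip(observed, expected)]
    correction = min(0.5, min(dev))
    stat = sum((d - correction) ** 2 / e for d, e in zip(dev, expected))
    return stat, float(chi2.sf(stat, 1))


def pearson_2x2_oracle(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Uncorrected Pearson chi-square on a 2x2 table via the closed form."""
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / \
        ((a + b) * (c + d) * (a + c) * (b + d))
    return stat, float(chi2.sf(stat, 1))


def holm_oracle(pvals):
    """Holm step-down by its definition: max-of-prefix of (m-i)·p_(i)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def bh_oracle(pvals):
    """Benjamini-Hochberg step-up by its definition: min-of-suffix of m·p/(i)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, m * p[idx] / (rank + 1))
        adj[idx] = running
    return adj


def per_base_bound_oracle(genes, peaks, window: int) -> dict[str, bool]:
    """Gene boundness by literal per-base intersection of peak and window."""
    bound = {}
    for g in genes:
        lo = max(0, g.tss - window)
        window_bases = set(range(lo, g.tss + window + 1))
        hit = False
        for p in peaks:
            if p.chrom != g.chrom:
                continue
            if any(base in window_bases for base in range(p.start, p.end)):
                hit = True
                break
        bound[g.gene_id] = hit
    return bound


def fate_oracle(m_ctrl: bool, m_dis: bool, m_kd: bool,
                d_ctrl: str, d_dis: str, d_kd: str,
                strict: bool) -> tuple[str, str]:
    """Exhaustive truth table for (fate, modifier dependence).

    Directions are "up"/"down" for members and "none" for non-members.
    """
    if m_ctrl and m_dis:
        return "conserved", "not_applicable"
    if not m_ctrl and not m_dis:
        return "never_target", "not_applicable"
    fate = "lost_in_disease" if m_ctrl else "gained_in_disease"
    if m_kd == m_ctrl:
        dependence = "dependent"
        ref_member, ref_dir = m_ctrl, d_ctrl
    else:
        dependence = "independent"
        ref_member, ref_dir = m_dis, d_dis
    if strict and m_kd and ref_member and d_kd != ref_dir:
        dependence = "unresolved"
    return fate, dependence
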