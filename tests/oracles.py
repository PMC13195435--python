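"""Independent textbook implementations used as oracles by the test suite.

Everything here is deliberately written as plain per-site/per-sample loops
with its own formulas, sharing no code with the package implementation.
"""

import numpy as np
from scipy.integrate import quad
from scipy.special import zeta

MISSING = -1


def site_stats(dos_row):
    """(called allele count, alt frequency) for one site's dosage vector."""
    called = [d for d in dos_row if d != MISSING]
    n = 2 * len(called)
    if n == 0:
        return 0, float("nan")
    return n, sum(called) / n


def pi_per_site(dos_row):
    n, p = site_stats(dos_row)
    if n <= 1:
        return None
    return n / (n - 1) * 2 * p * (1 - p)


def oracle_window_pi(dos, span):
    total = 0.0
    for row in dos:
        v = pi_per_site(row)
        if v is not None:
            total += v
    return total / span


def harmonic_number(m):
    """H_m = sum_{i<=m} 1/i for possibly non-integer m, via the integral
    identity H_m = int_0^1 (1 - t^m)/(1 - t) dt."""
    val, _ = quad(lambda t: (1 - t ** m) / (1 - t) if t < 1 else m, 0, 1,
                  limit=200, epsabs=1e-13, epsrel=1e-13)
    return val


def oracle_tajimas_d(dos):
    """Tajima's D over a panel of sites; non-integer harmonic-mean sample
    size handled through analytic continuations of the a1/a2 sums."""
    seg = []
    theta_pi = 0.0
    for row in dos:
        n, p = site_stats(row)
        if n > 2 and 0 < p < 1:
            seg.append(n)
            theta_pi += n / (n - 1) * 2 * p * (1 - p)
    S = len(seg)
    if S == 0:
        return float("nan")
    n = S / sum(1.0 / x for x in seg)
    a1 = harmonic_number(n - 1)
    a2 = zeta(2, 1) - zeta(2, n)      # sum_{i<n} 1/i^2
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (theta_pi - S / a1) / np.sqrt(var)


def wc_site_components(dosA, dosB):
    """Weir & Cockerham (1984) a, b, c for one site and two populations of
    diploids; None when either population has no calls."""
    gA = [d for d in dosA if d != MISSING]
    gB = [d for d in dosB if d != MISSING]
    n1, n2 = len(gA), len(gB)
    if n1 == 0 or n2 == 0 or n1 + n2 <= 2:
        return None
    r = 2
    p1 = sum(gA) / (2 * n1)
    p2 = sum(gB) / (2 * n2)
    h1 = sum(1 for d in gA if d == 1) / n1
    h2 = sum(1 for d in gB if d == 1) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    if pbar <= 0 or pbar >= 1:
        return (0.0, 0.0, 0.0)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return (a, b, c)


def oracle_fst(dosA, dosB):
    num = den = 0.0
    for rowA, rowB in zip(dosA, dosB):
        comp = wc_site_components(rowA, rowB)
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
    return num / den if den != 0 else float("nan")


def brute_force_roh(pos, dos, min_len=1_000, min_snps=50):
    """Quadratic-scan oracle for run-of-homozygosity detection: maximal
    het-free stretches; missing calls neither break a run nor count."""
    n = len(dos)
    hom = [(d != MISSING) and (d != 1) for d in dos]
    het = [d == 1 for d in dos]
    out = []
    i = 0
    while i < n:
        if not hom[i]:
            i += 1
            continue
        last_hom = i
        count = 0
        for j in range(i, n):
            if het[j]:
                break
            if hom[j]:
                last_hom = j
                count += 1
        start, end = int(pos[i]), int(pos[last_hom])
        if count >= min_snps and end - start + 1 > min_len:
            out.append((start, end, count))
        i = last_hom + 1
        while i < n and not het[i] and not hom[i]:
            i += 1
        if i < n and het[i]:
            i += 1
    return out
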