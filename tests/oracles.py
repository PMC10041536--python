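"""Independent brute-force oracles used to cross-check the vectorised
implementations. Deliberately written with explicit loops and textbook
formulas, never sharing code with the package."""

from __future__ import annotations

import math

import numpy as np


def wc84_components_oracle(cohorts):
    """Weir & Cockerham (1984) variance components a, b, c for one biallelic
    site over r cohorts of diploid dosages (missing = -1), explicit loops."""
    r = len(cohorts)
    n = []
    p = []
    h = []
    for dos in cohorts:
        dos = [d for d in dos if d != -1]
        ni = len(dos)
        n.append(ni)
        p.append(sum(dos) / (2.0 * ni))
        h.append(sum(1 for d in dos if d == 1) / ni)
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - ((2 * nbar - 1) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def pi_oracle(haplotypes, length_bp):
    """Nucleotide diversity by all-pairs Hamming distance."""
    n = len(haplotypes)
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(1 for x, y in zip(haplotypes[i], haplotypes[j]) if x != y)
            pairs += 1
    return total / pairs / length_bp if pairs else 0.0


def ehh_oracle(hap, carriers, core, j):
    """EHH at flanking site j by direct pairwise haplotype comparison of the
    segment between the core and j among carriers. The core column itself is
    excluded so EHH(core) = 1 by convention (for allele-specific carrier
    sets the core column is constant anyway)."""
    lo, hi = min(core, j), max(core, j)
    cols = [k for k in range(lo, hi + 1) if k != core]
    n = len(carriers)
    if n < 2:
        return 0.0
    same = 0
    for a in range(n):
        for b in range(a + 1, n):
            if all(hap[carriers[a]][k] == hap[carriers[b]][k] for k in cols):
                same += 1
    return same / (n * (n - 1) / 2)


def ihh_oracle(hap, positions, core, cutoff=0.05):
    """Two-sided trapezoid integral of the pooled-haplotype EHH curve,
    truncated at the last point with EHH >= cutoff per side."""
    carriers = list(range(len(hap)))
    total = 0.0
    for step in (-1, +1):
        xs = [0.0]
        ys = [1.0]
        j = core + step
        while 0 <= j < len(positions):
            e = ehh_oracle(hap, carriers, core, j)
            if e < cutoff:
                break
            xs.append(abs(positions[j] - positions[core]))
            ys.append(e)
            j += step
        for k in range(1, len(xs)):
            total += 0.5 * (ys[k] + ys[k - 1]) * (xs[k] - xs[k - 1])
    return total


def r2_dosage_oracle(a, b):
    """Squared Pearson correlation via the raw textbook formula."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b)) / n
    va = sum((x - ma) ** 2 for x in a) / n
    vb = sum((y - mb) ** 2 for y in b) / n
    return cov * cov / (va * vb)


def r2_haplotype_oracle(haps):
    """r^2 from direct haplotype frequency counts of a (n, 2) 0/1 matrix."""
    n = len(haps)
    p_ab = sum(1 for h in haps if h[0] == 1 and h[1] == 1) / n
    p_a = sum(h[0] for h in haps) / n
    p_b = sum(h[1] for h in haps) / n
    d = p_ab - p_a * p_b
    return d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))


def ols_ttest_oracle(y, X, g):
    """OLS p-value for the coefficient of g in y ~ X + g (t distribution)."""
    from scipy import stats

    A = np.column_stack([X, g])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    df = len(y) - A.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(A.T @ A)
    t = beta[-1] / math.sqrt(cov[-1, -1])
    return 2 * stats.t.sf(abs(t), df)


def gls_dense_oracle(y, X, K, g, sg2, se2):
    """Dense-GLS p-value: whiten by the Cholesky factor of sg2*K + se2*I,
    then ordinary least squares."""
    V = sg2 * K + se2 * np.eye(len(y))
    L = np.linalg.cholesky(V)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, np.column_stack([X, g]))
    return ols_ttest_oracle(yw, Xw[:, :-1], Xw[:, -1])


def chi2_2x2_oracle(a, b, c, d):
    """Pearson chi-square statistic (ad-bc)^2 N / (row and column products)."""
    n = a + b + c + d
    return (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
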