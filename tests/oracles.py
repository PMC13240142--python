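"""Independent scalar/brute-force oracles used only by the test suite.

Everything here is deliberately loop-based and separate from the package's
vectorized code paths.
"""

from __future__ import annotations

import math
from itertools import combinations, product

import numpy as np
from scipy.stats import rankdata

MISSING = -1


def site_pi_pairs(col) -> float:
    """Mean pairwise difference among sampled alleles, by exhaustive pair
    enumeration."""
    alleles = []
    for g in col:
        if g != MISSING:
            alleles.extend([1] * int(g) + [0] * (2 - int(g)))
    m = len(alleles)
    if m < 2:
        return math.nan
    diff = sum(1 for x, y in combinations(alleles, 2) if x != y)
    return diff / math.comb(m, 2)


def wc_components_scalar(col, idx_a, idx_b):
    """Direct scalar transcription of the two-level WC84 (a, b, c) formulas
    for r = 2 populations at one site."""
    r = 2.0
    stats = []
    for idx in (idx_a, idx_b):
        gts = [int(col[i]) for i in idx if col[i] != MISSING]
        n = len(gts)
        if n == 0:
            return (math.nan, math.nan, math.nan)
        p = sum(gts) / (2.0 * n)
        h = sum(1 for g in gts if g == 1) / n
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    if n1 + n2 <= 2:
        return (math.nan, math.nan, math.nan)
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2.0
    return (a, b, c)


def window_fst_scalar(calls, idx_a, idx_b, site_idx):
    num = den = 0.0
    any_usable = False
    for s in site_idx:
        a, b, c = wc_components_scalar(calls[:, s], idx_a, idx_b)
        if math.isnan(a):
            continue
        any_usable = True
        num += a
        den += a + b + c
    if not any_usable or den == 0.0:
        return math.nan
    return num / den


def window_pi_scalar(calls, idx, site_idx, span):
    total = 0.0
    for s in site_idx:
        v = site_pi_pairs(calls[idx, s])
        if not math.isnan(v):
            total += v
    return total / span


def tajima_d_scalar(calls, idx, site_idx):
    """Step-by-step Tajima's D with hand-computed constants; n fixed at
    2 x min called diploids over segregating sites."""
    seg = []
    for s in site_idx:
        gts = [int(calls[i, s]) for i in idx if calls[i, s] != MISSING]
        m = 2 * len(gts)
        j = sum(gts)
        if m >= 2 and 0 < j < m:
            seg.append((m, j, len(gts)))
    S = len(seg)
    if S == 0:
        return math.nan
    n = 2 * min(t[2] for t in seg)
    if n < 4:
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    pi_sum = sum(2.0 * j * (m - j) / (m * (m - 1.0)) for m, j, _ in seg)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_sum - S / a1) / math.sqrt(var)


def ranksum_exact_enum(x, y):
    """Exact two-sided rank-sum p by enumerating every assignment of the
    pooled midranks to the x-sample."""
    x = list(map(float, x))
    y = list(map(float, y))
    nx = len(x)
    ranks = rankdata(np.asarray(x + y))
    w = float(ranks[:nx].sum())
    sums = [sum(c) for c in combinations(ranks, nx)]
    eps = 1e-9
    p_low = sum(1 for s in sums if s <= w + eps) / len(sums)
    p_high = sum(1 for s in sums if s >= w - eps) / len(sums)
    return w, min(1.0, 2.0 * min(p_low, p_high))


def signedrank_exact_enum(pairs):
    """Exact two-sided signed-rank p by enumerating all 2^k sign
    assignments of the nonzero |difference| midranks."""
    d = [float(a) - float(b) for a, b in pairs]
    d = [v for v in d if v != 0.0]
    k = len(d)
    if k == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(np.asarray(d)))
    w_plus = float(ranks[np.asarray(d) > 0].sum())
    sums = []
    for signs in product((0, 1), repeat=k):
        sums.append(sum(r for r, s in zip(ranks, signs) if s))
    eps = 1e-9
    p_low = sum(1 for s in sums if s <= w_plus + eps) / len(sums)
    p_high = sum(1 for s in sums if s >= w_plus - eps) / len(sums)
    return w_plus, min(1.0, 2.0 * min(p_low, p_high))


def random_genotype_matrix(rng, n_samples, n_sites, missing_rate=0.1):
    """Raw dosage array with missingness for oracle-equivalence tests."""
    calls = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)
    return calls
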