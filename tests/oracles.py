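"""Independent brute-force oracles used only by the test suite.

Each oracle is a direct, unoptimised transcription of the defining formula
or published pseudocode, deliberately sharing no code with the package.
"""

import itertools
import math

import numpy as np


def minmax(X):
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    return (X - lo) / span


def relief_f_bruteforce(X, y, n_neighbors=1):
    """Relief weights by exhaustive neighbour search (plain loops)."""
    Xs = minmax(X)
    y = np.asarray(y)
    n, d = Xs.shape
    classes = sorted(set(y.tolist()))
    priors = {c: float(np.mean(y == c)) for c in classes}
    w = np.zeros(d)
    for j in range(n):
        dists = [math.dist(Xs[j], Xs[i]) if i != j else math.inf
                 for i in range(n)]
        same = [i for i in range(n) if i != j and y[i] == y[j]]
        same.sort(key=lambda i: (dists[i], i))
        hits = same[:n_neighbors]
        hit = np.mean([(Xs[j] - Xs[i]) ** 2 for i in hits], axis=0)
        miss = np.zeros(d)
        for c in classes:
            if c == y[j]:
                continue
            others = [i for i in range(n) if y[i] == c]
            others.sort(key=lambda i: (dists[i], i))
            near = others[:n_neighbors]
            term = np.mean([(Xs[j] - Xs[i]) ** 2 for i in near], axis=0)
            miss += priors[c] / (1.0 - priors[y[j]]) * term
        w += miss - hit
    return w


def entropy(series):
    vals = {}
    for v in series:
        vals[v] = vals.get(v, 0) + 1
    n = len(series)
    return -sum((c / n) * math.log(c / n) for c in vals.values())


def su(a, b):
    """Symmetrical uncertainty from plug-in entropies (plain dicts)."""
    ha, hb = entropy(list(a)), entropy(list(b))
    if ha <= 0 or hb <= 0:
        return 0.0
    hab = entropy(list(zip(a, b)))
    return 2.0 * (ha + hb - hab) / (ha + hb)


def cfs_merit(subset, codes, y):
    k = len(subset)
    if k == 0:
        return 0.0
    r_cf = np.mean([su(codes[:, i], y) for i in subset])
    if k == 1:
        return r_cf
    pairs = list(itertools.combinations(subset, 2))
    r_ff = np.mean([su(codes[:, i], codes[:, j]) for i, j in pairs])
    return k * r_cf / math.sqrt(k + k * (k - 1) * r_ff)


def cfs_exhaustive(codes, y):
    """Best-merit subset over every non-empty subset of the columns."""
    d = codes.shape[1]
    best, best_merit = (), 0.0
    for r in range(1, d + 1):
        for subset in itertools.combinations(range(d), r):
            m = cfs_merit(subset, codes, y)
            if m > best_merit + 1e-12:
                best, best_merit = subset, m
    return best, best_merit


def fcbf_trace(codes, y, delta=0.0):
    """Literal FCBF pseudocode: rank by SU(f, class), keep predominant.

    SU values are rounded to 12 decimals so that exact ties (broken by
    feature index) are not perturbed by summation order.
    """
    d = codes.shape[1]
    su_c = [round(su(codes[:, i], y), 12) for i in range(d)]
    s_list = sorted([i for i in range(d) if su_c[i] > delta],
                    key=lambda i: (-su_c[i], i))
    kept = []
    while s_list:
        fp = s_list[0]
        kept.append(fp)
        rest = []
        for fq in s_list[1:]:
            if round(su(codes[:, fp], codes[:, fq]), 12) >= su_c[fq]:
                continue  # fq removed as redundant with fp
            rest.append(fq)
        s_list = rest
    return kept


def sign_test_enumeration(n_pos, n_neg):
    """Two-sided sign-test p by enumerating all 2^n sign patterns."""
    n = n_pos + n_neg
    observed = abs(n_pos - n / 2.0)
    count = 0
    for pattern in itertools.product([0, 1], repeat=n):
        k = sum(pattern)
        if abs(k - n / 2.0) >= observed - 1e-12:
            count += 1
    return count / 2.0**n
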