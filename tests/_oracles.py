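"""Independent brute-force reference implementations used only by tests.

These follow the estimator definitions literally (explicit template loops,
per-row CDFs, pair counting) and share no code path with the package.
"""

import math

import numpy as np


def oracle_distance_pair(x, m):
    """Double-loop Chebyshev template distances at m and m+1."""
    x = np.asarray(x, dtype=float)
    n = x.size
    L = n - m
    dm = np.zeros((L, L))
    dm1 = np.zeros((L, L))
    for i in range(L):
        for j in range(L):
            dm[i, j] = max(abs(x[i + k] - x[j + k]) for k in range(m))
            dm1[i, j] = max(abs(x[i + k] - x[j + k]) for k in range(m + 1))
    return dm, dm1


def oracle_scope(dm, dm1):
    """Pool both matrices' off-diagonal entries, deduplicate, sort."""
    L = dm.shape[0]
    vals = set()
    for i in range(L):
        for j in range(L):
            if i != j:
                vals.add(dm[i, j])
                vals.add(dm1[i, j])
    return np.array(sorted(vals))


def oracle_profiles(dm, dm1, scope):
    """Row-wise empirical CDFs at each scope value, then the column mean."""
    L = dm.shape[0]
    off = ~np.eye(L, dtype=bool)
    phi_m = np.empty(scope.size)
    phi_m1 = np.empty(scope.size)
    for q, s in enumerate(scope):
        pd_m = [(dm[i][off[i]] <= s).sum() / (L - 1) for i in range(L)]
        pd_m1 = [(dm1[i][off[i]] <= s).sum() / (L - 1) for i in range(L)]
        phi_m[q] = np.mean(pd_m)
        phi_m1[q] = np.mean(pd_m1)
    return phi_m, phi_m1


def oracle_sampen(x, m, r):
    """Naive match-count SampEn; r in SD units (population SD); NaN if undefined."""
    x = np.asarray(x, dtype=float)
    r_abs = r * np.sqrt(np.mean((x - x.mean()) ** 2))
    dm, dm1 = oracle_distance_pair(x, m)
    L = dm.shape[0]
    cm = cm1 = 0
    for i in range(L):
        for j in range(L):
            if i != j:
                cm += dm[i, j] <= r_abs
                cm1 += dm1[i, j] <= r_abs
    if cm == 0 or cm1 == 0:
        return float("nan")
    return math.log(cm / cm1)


def oracle_npsampen(x, m):
    """Straight-line NPSampEn: scope, row CDFs, column means, mean log-ratio.

    Scope bins with a zero (m+1)-profile are excluded from sum and divisor.
    The inner CDF evaluation is vectorized over scope bins by broadcasting
    (the matrices are compared against every bin at once) but keeps the
    literal per-row definition.
    """
    x = np.asarray(x, dtype=float)
    dm, dm1 = oracle_distance_pair(x, m)
    scope = oracle_scope(dm, dm1)
    L = dm.shape[0]
    off = ~np.eye(L, dtype=bool)
    rows_m = np.stack([dm[i][off[i]] for i in range(L)])  # (L, L-1)
    rows_m1 = np.stack([dm1[i][off[i]] for i in range(L)])
    pd_m = (rows_m[:, :, None] <= scope[None, None, :]).mean(axis=1)  # (L, nbin)
    pd_m1 = (rows_m1[:, :, None] <= scope[None, None, :]).mean(axis=1)
    phi_m = pd_m.mean(axis=0)
    phi_m1 = pd_m1.mean(axis=0)
    total = 0.0
    used = 0
    for a, b in zip(phi_m, phi_m1):
        if b > 0:
            total += math.log(a / b)
            used += 1
    return total / used


def oracle_auc(scores, labels):
    """Exhaustive pair-counting AUC: ties count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (pos.size * neg.size)
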