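"""Brute-force reference implementations used only as test oracles.

Each function recomputes a score by direct enumeration, independently of
the library code paths it checks.
"""

import numpy as np


def brute_silhouette(X, labels):
    n = len(X)
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j])
                     for j in range(n) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def brute_ari(a, b):
    n = len(a)
    same_a = np.equal.outer(np.asarray(a), np.asarray(a))
    same_b = np.equal.outer(np.asarray(b), np.asarray(b))
    iu = np.triu_indices(n, 1)
    n11 = int((same_a[iu] & same_b[iu]).sum())
    na = int(same_a[iu].sum())
    nb = int(same_b[iu].sum())
    npairs = n * (n - 1) // 2
    expected = na * nb / npairs
    maximum = (na + nb) / 2
    if maximum == expected:
        return 1.0
    return (n11 - expected) / (maximum - expected)


def brute_knn(high, low, k):
    n = len(high)
    fracs = []
    for i in range(n):
        dh = [(np.linalg.norm(high[i] - high[j]), j)
              for j in range(n) if j != i]
        dl = [(np.linalg.norm(low[i] - low[j]), j)
              for j in range(n) if j != i]
        nh = {j for _, j in sorted(dh)[:k]}
        nl = {j for _, j in sorted(dl)[:k]}
        fracs.append(len(nh & nl) / k)
    return float(np.mean(fracs))


def _ranks_average_ties(v):
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v))
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def brute_cpd(high, low):
    dh, dl = [], []
    n = len(high)
    for i in range(n):
        for j in range(i + 1, n):
            dh.append(np.linalg.norm(high[i] - high[j]))
            dl.append(np.linalg.norm(low[i] - low[j]))
    rh = _ranks_average_ties(np.array(dh))
    rl = _ranks_average_ties(np.array(dl))
    return float(np.corrcoef(rh, rl)[0, 1])
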