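"""Independent brute-force oracles used by both the unit and acceptance tests.

These deliberately avoid the package's own implementations: plain Python
loops and full enumerations, usable only at small problem sizes.
"""

import itertools

import numpy as np


def sampen_bruteforce(x, m=2, r_frac=0.2):
    """Exhaustive O(N^2) sample-entropy pair counting."""
    x = np.asarray(x, float)
    n = x.size
    r = r_frac * x.std()
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def wilcoxon_exact_p_bruteforce(d):
    """Two-sided exact Wilcoxon p by enumerating all 2^n sign assignments."""
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4
    dev_obs = abs(w_obs - mean_w)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mean_w) >= dev_obs - 1e-9:
            count += 1
    return count / 2**n
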