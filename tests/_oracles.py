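"""Deliberately naive reference implementations used only as test oracles.

Everything here is written as directly from the defining formulas as
possible - explicit loops, no vectorization, no shared code with the
package - so that agreement with the fast implementations is meaningful.
"""

import math


def sampen_bruteforce(x, m, r):
    """Sample entropy by exhaustive pair counting.

    Templates i = 0..N-m-1 at both lengths; per-template match fraction over
    the other N-m-1 templates with strict Chebyshev criterion d < r.
    """
    x = list(map(float, x))
    n = len(x)
    n_t = n - m

    def cheb(i, j, mm):
        return max(abs(x[i + k] - x[j + k]) for k in range(mm))

    def mean_fraction(mm):
        total = 0.0
        for i in range(n_t):
            cnt = 0
            for j in range(n_t):
                if j != i and cheb(i, j, mm) < r:
                    cnt += 1
            total += cnt / (n_t - 1)
        return total / n_t

    b = mean_fraction(m)
    a = mean_fraction(m + 1)
    if a == 0.0:
        return math.inf
    return -math.log(a / b)


def fuzzyen_bruteforce(x, m, r, n):
    """Fuzzy entropy by exhaustive double loops over baseline-removed
    embeddings with exponential membership exp(-d^n / r)."""
    x = list(map(float, x))
    big_n = len(x)
    n_t = big_n - m

    def embed(i, mm):
        mean = sum(x[i + k] for k in range(mm)) / mm
        return [x[i + k] - mean for k in range(mm)]

    def phi(mm):
        total = 0.0
        for i in range(n_t):
            s = 0.0
            for j in range(n_t):
                if j == i:
                    continue
                u, v = embed(i, mm), embed(j, mm)
                d = max(abs(a - b) for a, b in zip(u, v))
                s += math.exp(-(d ** n) / r)
            total += s / (n_t - 1)
        return total / n_t

    return math.log(phi(m)) - math.log(phi(m + 1))
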