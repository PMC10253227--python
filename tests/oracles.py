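"""Independent brute-force oracles used to cross-check the statistics.

These deliberately avoid the code paths (and, where possible, the
libraries) they verify: the KS oracle evaluates both ECDFs at every
pooled point with a double loop, the BH oracle executes the step-up
definition literally, and the hypergeometric oracle sums exact rational
PMF terms with ``math.comb``.
"""

from __future__ import annotations

from math import comb
from typing import Sequence


def ks_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """sup_v |ECDF_x(v) - ECDF_y(v)| evaluated at every observed point."""
    points = list(x) + list(y)
    best = 0.0
    for v in points:
        fx = sum(1 for a in x if a <= v) / len(x)
        fy = sum(1 for b in y if b <= v) / len(y)
        best = max(best, abs(fx - fy))
    return best


def bh_oracle(p: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up by the definition, in input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order, start=1):
        q[i] = min(min(p[j] * m / (order.index(j) + 1) for j in order[pos - 1:]), 1.0)
    return q


def hypergeom_upper_oracle(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by exact integer summation of C(K,x) C(N-K,n-x) / C(N,n)."""
    total = comb(N, n)
    acc = 0
    for x in range(k, min(n, K) + 1):
        if n - x <= N - K:
            acc += comb(K, x) * comb(N - K, n - x)
    return acc / total
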