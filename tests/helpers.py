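"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: running sums
are accumulated position by position in pure Python, permutation p-values
by complete enumeration, and Spearman via explicit ranks + the Pearson
product-moment formula.
"""

from __future__ import annotations

import math
from itertools import combinations


def brute_force_running_sum(
    metrics: list[float], is_member: list[bool], p: float
) -> list[float]:
    """Position-by-position running sum of the weighted KS statistic."""
    n = len(metrics)
    n_hit = sum(is_member)
    assert 0 < n_hit < n
    total = math.fsum(abs(m) ** p for m, hit in zip(metrics, is_member) if hit)
    running = []
    acc = 0.0
    for m, hit in zip(metrics, is_member):
        if hit:
            acc += (abs(m) ** p / total) if total > 0 else 1.0 / n_hit
        else:
            acc -= 1.0 / (n - n_hit)
        running.append(acc)
    return running


def brute_force_es(
    metrics: list[float], is_member: list[bool], p: float
) -> tuple[float, int]:
    """ES = running-sum extremum of largest magnitude (positive on ties)."""
    running = brute_force_running_sum(metrics, is_member, p)
    hi = max(running)
    lo = min(running)
    if hi >= -lo - 1e-9:  # positive extremum preferred on magnitude ties
        return hi, running.index(hi)
    return lo, running.index(lo)


def exhaustive_null_es(metrics: list[float], k: int, p: float) -> list[float]:
    """ES of every k-subset of the ranked universe (exact null)."""
    n = len(metrics)
    out = []
    for subset in combinations(range(n), k):
        member = [i in set(subset) for i in range(n)]
        out.append(brute_force_es(metrics, member, p)[0])
    return out


def exhaustive_p(null_es: list[float], observed: float) -> float:
    """Sign-stratified exact permutation p-value (ties counted inclusively,
    with the same 1e-9 slack the comparison needs in float arithmetic)."""
    if observed > 0:
        same = [e for e in null_es if e > 0]
        count = sum(e >= observed - 1e-9 for e in same)
    else:
        same = [e for e in null_es if e < 0]
        count = sum(e <= observed + 1e-9 for e in same)
    return count / len(same)


def spearman_oracle(x: list[float], y: list[float]) -> float:
    """Rank-Pearson Spearman on tie-free vectors (plain formulas only)."""
    def ranks(values: list[float]) -> list[float]:
        order = sorted(range(len(values)), key=lambda i: values[i])
        r = [0.0] * len(values)
        for rank, i in enumerate(order, start=1):
            r[i] = float(rank)
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5
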