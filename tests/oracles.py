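"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths (and scipy/statsmodels
shortcuts) they are used to check.
"""

from itertools import combinations
from math import comb


def exact_rank_sum_p(group_a, group_b) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration (no ties)."""
    a = list(group_a)
    b = list(group_b)
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    n1 = len(a)
    m = n1 * len(b)
    u_obs = sum(1 for x in a for y in b if x > y)
    lo, hi = min(u_obs, m - u_obs), max(u_obs, m - u_obs)
    extreme = 0
    for chosen in combinations(range(len(pooled)), n1):
        sel = set(chosen)
        u = sum(
            1
            for i in sel
            for j in range(len(pooled))
            if j not in sel and pooled[i] > pooled[j]
        )
        if u <= lo or u >= hi:
            extreme += 1
    return min(1.0, extreme / comb(len(pooled), n1))


def bh_step_up(p_values) -> list[float]:
    """Benjamini-Hochberg by the textbook step-up recursion."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p_values[i] * m / rank)
        q[i] = val
        prev = val
    return q
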