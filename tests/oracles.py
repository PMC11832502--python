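"""Independent brute-force reference implementations.

Each oracle recomputes an estimator from its definition with the most
literal algorithm available — explicit loops, exhaustive enumeration, or
closed-form evaluation — sharing no code with the package implementations
they check.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations

import numpy as np
from scipy.stats import norm


def permutation_entropy_naive(x, D: int, tau: int) -> float:
    """Ordinal-pattern entropy by explicit window-by-window pattern listing."""
    x = list(map(float, x))
    n_win = len(x) - (D - 1) * tau
    pats = []
    for i in range(n_win):
        w = [x[i + k * tau] for k in range(D)]
        pats.append(tuple(sorted(range(D), key=lambda k: (w[k], k))))
    counts = Counter(pats)
    return -sum((c / n_win) * math.log(c / n_win) for c in counts.values())


def sampen_counts_naive(x, m: int, r: float) -> tuple[int, int]:
    """Template-match counts by the O(n²) double loop over all pairs."""
    x = list(map(float, x))
    nt = len(x) - m
    A = B = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) < r:
                B += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) < r:
                    A += 1
    return A, B


def sample_entropy_naive(x, m: int, r: float) -> float:
    A, B = sampen_counts_naive(x, m, r)
    if B == 0:
        raise ValueError("undefined")
    return math.inf if A == 0 else -math.log(A / B)


def lz76_naive(bits) -> int:
    """Exhaustive-history parse on strings with the `in` operator."""
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    c = i = 0
    while i < n:
        k = 1
        while i + k <= n and s[i:i + k] in s[:i + k - 1]:
            k += 1
        c += 1
        i += k
    return c


def renyi_entropy_naive(x, grid, h: float, alpha: float) -> float:
    """Rényi entropy from the full Gaussian mixture, integrated manually.

    The density at every grid point is the exact mean of n Gaussian kernels
    (via scipy's normal pdf), and the integral of f^alpha uses a hand-written
    trapezoid sum.
    """
    x = np.asarray(x, dtype=float)
    f = np.array([norm.pdf(g, loc=x, scale=h).mean() for g in grid])
    fa = f ** alpha
    integral = 0.0
    for i in range(len(grid) - 1):
        integral += 0.5 * (fa[i] + fa[i + 1]) * (grid[i + 1] - grid[i])
    return math.log(integral) / (1.0 - alpha)


def higuchi_fd_naive(x, k_max: int) -> float:
    """Canonical Higuchi algorithm written with plain loops and a manual
    least-squares slope."""
    x = list(map(float, x))
    N = len(x)
    ln_invk, ln_L = [], []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            n_m = (N - 1 - m) // k
            if n_m < 1:
                continue
            total = 0.0
            for i in range(1, n_m + 1):
                total += abs(x[m + i * k] - x[m + (i - 1) * k])
            lengths.append(total * (N - 1) / (n_m * k) / k)
        ln_invk.append(math.log(1.0 / k))
        ln_L.append(math.log(sum(lengths) / len(lengths)))
    mx = sum(ln_invk) / len(ln_invk)
    my = sum(ln_L) / len(ln_L)
    sxx = sum((u - mx) ** 2 for u in ln_invk)
    sxy = sum((u - mx) * (v - my) for u, v in zip(ln_invk, ln_L))
    return sxy / sxx


def mwu_exact_p_enumeration(a, b) -> float:
    """Two-sided exact Mann–Whitney p by enumerating every group assignment.

    All C(n1+n2, n1) ways of labelling the pooled observations are listed;
    the p-value is the fraction whose U statistic is at least as extreme
    (in either tail) as the observed one. Assumes no ties.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1, n2 = len(a), len(b)

    def u_stat(group_a):
        group_a = list(group_a)
        rest = list(pooled)
        for v in group_a:
            rest.remove(v)
        return sum(1 for x in group_a for y in rest if x > y)

    u_obs = u_stat(a)
    extremity_obs = min(u_obs, n1 * n2 - u_obs)
    count = total = 0
    for combo in combinations(range(n1 + n2), n1):
        u = u_stat([pooled[i] for i in combo])
        if min(u, n1 * n2 - u) <= extremity_obs:
            count += 1
        total += 1
    return count / total


def longest_clean_run_brute(mask) -> tuple[int, int]:
    """(start, length) of the longest all-true window by scanning all O(n²)
    windows; earliest start wins ties."""
    mask = list(bool(v) for v in mask)
    n = len(mask)
    best = (0, 0)
    for start in range(n):
        for stop in range(start + 1, n + 1):
            if all(mask[start:stop]) and stop - start > best[1]:
                best = (start, stop - start)
    return best
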