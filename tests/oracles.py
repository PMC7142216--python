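"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit loops and textbook
formulas — so it shares no code path with the package implementation
it checks.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def naive_partial_loglik(beta: float, x, time, event) -> float:
    """Cox log partial likelihood for one covariate, no tied times.

    ll(b) = sum over events i of [ b*x_i - log sum_{j: t_j >= t_i} exp(b*x_j) ].
    """
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for i in range(len(x)):
        if event[i] != 1:
            continue
        risk = [np.exp(beta * x[j]) for j in range(len(x)) if time[j] >= time[i]]
        ll += beta * x[i] - np.log(sum(risk))
    return ll


def grid_search_beta(x, time, event, lo=-3.0, hi=3.0, step=1e-4) -> float:
    """Arg-max of the naive partial likelihood on a fixed grid."""
    grid = np.arange(lo, hi + step / 2, step)
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    # vectorized over the grid, looping subjects (n is tiny)
    ll = np.zeros_like(grid)
    for i in range(len(x)):
        if event[i] != 1:
            continue
        at_risk = [j for j in range(len(x)) if time[j] >= time[i]]
        denom = np.zeros_like(grid)
        for j in at_risk:
            denom += np.exp(grid * x[j])
        ll += grid * x[i] - np.log(denom)
    return float(grid[np.argmax(ll)])


def naive_score_and_info(beta: float, x, time, event) -> tuple[float, float]:
    """First and (negative) second derivative of the naive log partial
    likelihood at ``beta``, from the textbook risk-set sums."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    u = 0.0
    info = 0.0
    for i in range(len(x)):
        if event[i] != 1:
            continue
        at_risk = [j for j in range(len(x)) if time[j] >= time[i]]
        s0 = sum(np.exp(beta * x[j]) for j in at_risk)
        s1 = sum(x[j] * np.exp(beta * x[j]) for j in at_risk)
        s2 = sum(x[j] ** 2 * np.exp(beta * x[j]) for j in at_risk)
        u += x[i] - s1 / s0
        info += s2 / s0 - (s1 / s0) ** 2
    return u, info


def brute_force_cindex(risk, time, event) -> float:
    """Harrell's C by exhaustive pair enumeration."""
    num = 0.0
    den = 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def hand_km(time, event) -> list[tuple[float, float]]:
    """Product-limit estimate as (event_time, survival) pairs."""
    order = sorted(set(t for t, e in zip(time, event) if e == 1))
    surv = 1.0
    out = []
    for t in order:
        at_risk = sum(1 for tt in time if tt >= t)
        deaths = sum(1 for tt, ee in zip(time, event) if tt == t and ee == 1)
        surv *= 1.0 - deaths / at_risk
        out.append((t, surv))
    return out


def hand_logrank_chi2(group, time, event) -> float:
    """Two-sample log-rank chi-square from the O−E / V table."""
    levels = sorted(set(group))
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(tt for tt, ee in zip(time, event) if ee == 1)):
        n_at = sum(1 for tt in time if tt >= t)
        n1_at = sum(1 for tt, g in zip(time, group) if tt >= t and g == levels[0])
        d = sum(1 for tt, ee in zip(time, event) if tt == t and ee == 1)
        d1 = sum(
            1 for tt, ee, g in zip(time, event, group)
            if tt == t and ee == 1 and g == levels[0]
        )
        o_minus_e += d1 - d * n1_at / n_at
        if n_at > 1:
            var += d * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d) / (n_at - 1)
    return o_minus_e**2 / var


def enumerate_hypergeom_tail(N: int, M: int, n: int, i_min: int) -> float:
    """P(overlap >= i_min) by exhaustive enumeration of all C(N, n) draws."""
    universe = list(range(N))
    term = set(range(M))
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(term.intersection(draw)) >= i_min:
            hits += 1
    return hits / total


def hypergeom_tail_exact(N: int, M: int, n: int, i_min: int) -> float:
    """Same tail via exact binomial coefficients (independent closed form)."""
    total = comb(N, n)
    hits = sum(
        comb(M, j) * comb(N - M, n - j)
        for j in range(max(i_min, 0), min(M, n) + 1)
        if 0 <= n - j <= N - M
    )
    return hits / total
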