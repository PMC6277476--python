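"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written the slow, explicit way — loops over
individuals and alleles, textbook formulas, exhaustive path enumeration — so
the fast vectorized implementations in the package are checked against a
genuinely different computational route.
"""

from __future__ import annotations

import itertools
import math


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta, longhand
# ---------------------------------------------------------------------------

def wc_theta_longhand(pop_calls: list[list[tuple[int, int]]]) -> float:
    """Two-or-more population, single-locus theta from the printed equations.

    ``pop_calls[i]`` is the list of (a1, a2) genotypes scored in population i.
    """
    r = len(pop_calls)
    n = [len(calls) for calls in pop_calls]
    alleles = sorted({a for calls in pop_calls for pair in calls for a in pair})
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    a_sum = b_sum = c_sum = 0.0
    for allele in alleles:
        p = []
        h = []
        for calls in pop_calls:
            copies = sum(int(pair[0] == allele) + int(pair[1] == allele)
                         for pair in calls)
            het = sum(1 for pair in calls
                      if bool(pair[0] == allele) != bool(pair[1] == allele))
            p.append(copies / (2 * len(calls)))
            h.append(het / len(calls))
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum / (a_sum + b_sum + c_sum)


# ---------------------------------------------------------------------------
# Balanced nested ANOVA (textbook expected-mean-square coefficients)
# ---------------------------------------------------------------------------

def balanced_nested_components(y):
    """Variance components of a balanced 4-level nested design.

    ``y[g][p][i]`` is the pair (y1, y2) of observations for individual i of
    population p in group g; every group has the same number of populations
    and every population the same number of individuals.  Returns
    (sigma2_group, sigma2_pop, sigma2_ind, sigma2_within) from the classical
    mean-square recursion for the balanced case.
    """
    G = len(y)
    P = len(y[0])
    I = len(y[0][0])
    W = 2
    N = G * P * I * W
    grand = sum(v for g in y for p in g for i in p for v in i) / N

    def mean_ind(i):
        return sum(i) / W

    def mean_pop(p):
        return sum(v for i in p for v in i) / (I * W)

    def mean_grp(g):
        return sum(v for p in g for i in p for v in i) / (P * I * W)

    ss_w = sum((v - mean_ind(i)) ** 2 for g in y for p in g for i in p for v in i)
    ss_i = W * sum((mean_ind(i) - mean_pop(p)) ** 2
                   for g in y for p in g for i in p)
    ss_p = I * W * sum((mean_pop(p) - mean_grp(g)) ** 2 for g in y for p in g)
    ss_g = P * I * W * sum((mean_grp(g) - grand) ** 2 for g in y)
    ms_w = ss_w / (G * P * I * (W - 1))
    ms_i = ss_i / (G * P * (I - 1))
    ms_p = ss_p / (G * (P - 1))
    ms_g = ss_g / (G - 1)
    s_w = ms_w
    s_i = (ms_i - ms_w) / W
    s_p = (ms_p - ms_i) / (I * W)
    s_g = (ms_g - ms_p) / (P * I * W)
    return s_g, s_p, s_i, s_w


# ---------------------------------------------------------------------------
# Pearson / residual correlation, longhand
# ---------------------------------------------------------------------------

def pearson_longhand(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def residuals_longhand(y, x):
    """OLS residuals of y on [1, x] via the normal equations."""
    n = len(y)
    mx = sum(x) / n
    my = sum(y) / n
    beta = sum((a - mx) * (b - my) for a, b in zip(x, y)) / \
        sum((a - mx) ** 2 for a in x)
    alpha = my - beta * mx
    return [b - (alpha + beta * a) for a, b in zip(x, y)]


def partial_r_longhand(g, a, b):
    """Residual correlation r(g, a | b) over already-vectorized entries."""
    return pearson_longhand(residuals_longhand(g, b), residuals_longhand(a, b))


# ---------------------------------------------------------------------------
# Least-cost by exhaustive simple-path enumeration
# ---------------------------------------------------------------------------

def least_cost_enumerate(passable, start, goal, dx=1.0, dy=1.0):
    """Minimal accumulated cost between two cells on a small grid.

    Enumerates every simple path using the eight neighbor moves; a step costs
    the metric step length (``dx`` east-west, ``dy`` north-south, their
    hypotenuse diagonally).  Only viable for tiny grids.
    """
    n_rows, n_cols = len(passable), len(passable[0])
    best = [math.inf]

    def step_cost(dr, dc):
        if dr and dc:
            return math.hypot(dx, dy)
        return dy if dr else dx

    def walk(cell, cost, seen):
        if cost >= best[0]:
            return
        if cell == goal:
            best[0] = cost
            return
        r, c = cell
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols and \
                        passable[rr][cc] and (rr, cc) not in seen:
                    walk((rr, cc), cost + step_cost(dr, dc), seen | {(rr, cc)})

    walk(start, 0.0, {start})
    return best[0]


def haversine_longhand(lat1, lon1, lat2, lon2, radius_km=6371.0088):
    """Great-circle distance by the spherical law of cosines (not haversine)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    central = math.acos(
        min(1.0, max(-1.0, math.sin(p1) * math.sin(p2)
                     + math.cos(p1) * math.cos(p2) * math.cos(dl)))
    )
    return radius_km * central
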