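"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's vectorised code paths: quintile
membership is recomputed by scanning the weighted ECDF, index totals by a
plain per-unit loop, and jackknife variance by an explicit replicate loop.
"""

import numpy as np

from plantdex.food_composition import CONTEXTS, DEFAULT_GROUPS


def ecdf_quantile_lower(values, weights, p):
    """Smallest observed value whose cumulative weight share reaches p."""
    pairs = sorted(zip(values, weights))
    total = sum(w for _, w in pairs)
    acc = 0.0
    for v, w in pairs:
        acc += w
        if acc / total >= p - 1e-12:
            return v
    return pairs[-1][0]


def brute_quintile(intake, values, weights):
    """Quintile of one intake against the weighted distribution, ties low."""
    cuts = [ecdf_quantile_lower(values, weights, p) for p in (0.2, 0.4, 0.6, 0.8)]
    q = 1
    for c in cuts:
        if intake > c:
            q += 1
    return q


def brute_index_totals(cube, weights, scoring_matrix):
    """Index totals for every participant by enumerating all 46 units and
    recomputing quintile membership from the weighted ECDF each time."""
    n = cube.shape[0]
    totals = {name: np.zeros(n, dtype=int) for name in ("pdi", "hpdi", "updi")}
    for g in DEFAULT_GROUPS:
        for ci, ctx in enumerate(CONTEXTS):
            col = cube[:, g.group_id - 1, ci]
            for i in range(n):
                q = brute_quintile(col[i], col, weights)
                for name in totals:
                    rule = scoring_matrix[(name, g.category, ctx)]
                    s = 6 - q if rule.orientation == "reverse" else q
                    totals[name][i] += rule.weight * s
    return totals


def naive_jackknife_variance(stat_fn, weights, rep_weights, variance_factor):
    """Replicate-rule variance by an explicit loop."""
    theta = stat_fn(weights)
    acc = 0.0
    for r in range(rep_weights.shape[1]):
        acc += (stat_fn(rep_weights[:, r]) - theta) ** 2
    return variance_factor * acc
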