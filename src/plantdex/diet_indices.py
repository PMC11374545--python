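"""Plant-based diet index scoring: PDI, hPDI and uPDI.

Each of the 23 food groups crossed with {core, discretionary} context forms a
*scoring unit*. Per unit, the weighted consumption distribution of the
analysis sample is cut into quintiles; a participant's quintile membership
yields a base score 1-5 (1 below the lowest cut, 5 above the highest), which
is reversed (s -> 6 - s) for categories the index penalises and multiplied by
a context weight of 1 or 2. Summing the unit scores gives the index total:

* PDI  — all plant units positive, all animal units reverse, all weights 1
         (46 weight units, theoretical total 46-230);
* hPDI — healthy-plant units positive with weight 2 in core and 1 in
         discretionary context; unhealthy-plant and animal units reverse
         (53 weight units, total 53-265);
* uPDI — unhealthy-plant units positive with weight 2 in discretionary and
         1 in core context; healthy-plant and animal units reverse
         (51 weight units, total 51-255).

Quintile cuts use the inverse weighted ECDF (type "lower"): the k-th cut is
the smallest observed intake whose cumulative weight share reaches k/5.
Ties take the lower quintile (half-open bins), so zero-heavy units put all
non-consumers in Q1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .food_composition import (
    CONTEXTS,
    DEFAULT_GROUPS,
    N_GROUPS,
    Category,
    Context,
    FoodGroupIntakeMatrix,
)

INDICES = ("pdi", "hpdi", "updi")
N_QUINTILES = 5
N_CUTS = 4


class SampleSizeError(ValueError):
    """Raised when too few participants exist to define quintiles."""


class DesignError(ValueError):
    """Raised for invalid survey weights."""


@dataclass(frozen=True)
class ScoringRule:
    orientation: str  # "positive" | "reverse"
    weight: int  # 1 | 2

    def __post_init__(self) -> None:
        if self.orientation not in ("positive", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.weight not in (1, 2):
            raise ValueError(f"bad weight {self.weight!r}")


# keyed (index, category, context)
ScoringMatrix = dict[tuple[str, Category, Context], ScoringRule]


def default_scoring_matrix() -> ScoringMatrix:
    sm: ScoringMatrix = {}
    for ctx in CONTEXTS:
        sm[("pdi", Category.HEALTHY_PLANT, ctx)] = ScoringRule("positive", 1)
        sm[("pdi", Category.UNHEALTHY_PLANT, ctx)] = ScoringRule("positive", 1)
        sm[("pdi", Category.ANIMAL, ctx)] = ScoringRule("reverse", 1)

        sm[("hpdi", Category.HEALTHY_PLANT, ctx)] = ScoringRule(
            "positive", 2 if ctx is Context.CORE else 1
        )
        sm[("hpdi", Category.UNHEALTHY_PLANT, ctx)] = ScoringRule("reverse", 1)
        sm[("hpdi", Category.ANIMAL, ctx)] = ScoringRule("reverse", 1)

        sm[("updi", Category.UNHEALTHY_PLANT, ctx)] = ScoringRule(
            "positive", 2 if ctx is Context.DISCRETIONARY else 1
        )
        sm[("updi", Category.HEALTHY_PLANT, ctx)] = ScoringRule("reverse", 1)
        sm[("updi", Category.ANIMAL, ctx)] = ScoringRule("reverse", 1)
    return sm


def unit_weight_total(sm: ScoringMatrix, index: str) -> int:
    """Sum of unit weights for an index (46 for PDI, 53 hPDI, 51 uPDI)."""
    return sum(
        sm[(index, g.category, ctx)].weight for g in DEFAULT_GROUPS for ctx in CONTEXTS
    )


def theoretical_range(sm: ScoringMatrix, index: str) -> tuple[int, int]:
    """Min/max attainable totals: every unit scores in [w, 5w]."""
    w = unit_weight_total(sm, index)
    return w, 5 * w


def scoring_matrix_to_frame(sm: ScoringMatrix) -> pd.DataFrame:
    rows = [
        (idx, cat.value, ctx.value, rule.orientation, rule.weight)
        for (idx, cat, ctx), rule in sorted(
            sm.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2].value)
        )
    ]
    return pd.DataFrame(
        rows, columns=["index", "category", "context", "orientation", "weight"]
    )


def scoring_matrix_from_frame(df: pd.DataFrame) -> ScoringMatrix:
    return {
        (r["index"], Category(r.category), Context(r.context)): ScoringRule(
            r.orientation, int(r.weight)
        )
        for r in df.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# Weighted quintile cutpoints
# ---------------------------------------------------------------------------

def weighted_quantile_lower(
    values: np.ndarray, weights: np.ndarray, probs: np.ndarray
) -> np.ndarray:
    """Inverse weighted ECDF ("lower" type): smallest observed value whose
    cumulative weight share is >= p. Zeros count as observations."""
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, float)[order]
    cw = np.cumsum(np.asarray(weights, float)[order])
    shares = cw / cw[-1]
    idx = np.searchsorted(shares, np.asarray(probs, float) - 1e-12, side="left")
    return v[np.minimum(idx, len(v) - 1)]


def _stack(matrices) -> np.ndarray:
    if isinstance(matrices, np.ndarray):
        cube = np.asarray(matrices, float)
    else:
        cube = np.stack([m.values for m in matrices])
    if cube.ndim != 3 or cube.shape[1:] != (N_GROUPS, 2):
        raise ValueError(f"expected (n, {N_GROUPS}, 2) intakes, got {cube.shape}")
    return cube


def compute_cutpoints(matrices, weights) -> np.ndarray:
    """Quintile cuts (20/40/60/80 weighted percentiles, zeros included) per
    scoring unit. Returns an array of shape (23, 2, 4) with non-decreasing
    cuts along the last axis."""
    cube = _stack(matrices)
    w = np.asarray(weights, float)
    if cube.shape[0] < N_QUINTILES:
        raise SampleSizeError(
            f"need at least {N_QUINTILES} participants to form quintiles, "
            f"got {cube.shape[0]}"
        )
    if w.shape != (cube.shape[0],):
        raise DesignError("weights not aligned with participants")
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise DesignError("survey weights must be positive and finite")
    probs = np.array([0.2, 0.4, 0.6, 0.8])
    cuts = np.empty((N_GROUPS, 2, N_CUTS))
    for g in range(N_GROUPS):
        for c in range(2):
            cuts[g, c] = weighted_quantile_lower(cube[:, g, c], w, probs)
    return cuts


# ---------------------------------------------------------------------------
# Unit and participant scoring
# ---------------------------------------------------------------------------

def quintile_of(intake: float, cuts: np.ndarray) -> int:
    """Half-open bins with ties to the lower quintile:
    intake <= cut1 -> Q1, cut1 < intake <= cut2 -> Q2, ..., intake > cut4 -> Q5."""
    cuts = np.asarray(cuts, float)
    if np.any(np.diff(cuts) < 0):
        raise ValueError("cut values must be non-decreasing")
    return 1 + int(np.sum(cuts < intake))


def assign_unit_score(
    intake: float, cuts: np.ndarray, orientation: str, weight: int
) -> int:
    """Quintile base score 1-5, reversed for penalised categories, times the
    context weight."""
    s = quintile_of(intake, cuts)
    if orientation == "reverse":
        s = 6 - s
    return weight * s


@dataclass
class DietIndexScores:
    participant_id: object
    pdi: int
    hpdi: int
    updi: int

    def __post_init__(self) -> None:
        sm = default_scoring_matrix()
        for name in INDICES:
            lo, hi = theoretical_range(sm, name)
            val = getattr(self, name)
            if not lo <= val <= hi:
                raise ValueError(f"{name}={val} outside theoretical range [{lo},{hi}]")


def score_participant(
    matrix: FoodGroupIntakeMatrix,
    cuts: np.ndarray,
    sm: ScoringMatrix | None = None,
) -> DietIndexScores:
    """Sum unit scores over all 46 (group, context) cells for each index."""
    sm = sm or default_scoring_matrix()
    totals = {name: 0 for name in INDICES}
    for g in DEFAULT_GROUPS:
        for ci, ctx in enumerate(CONTEXTS):
            intake = matrix.values[g.group_id - 1, ci]
            for name in INDICES:
                rule = sm[(name, g.category, ctx)]
                totals[name] += assign_unit_score(
                    intake, cuts[g.group_id - 1, ci], rule.orientation, rule.weight
                )
    return DietIndexScores(matrix.participant_id, **totals)


def score_cohort(
    matrices,
    weights,
    sm: ScoringMatrix | None = None,
    participant_ids=None,
    cuts: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score a whole cohort (vectorised); cutpoints are computed on the same
    weighted sample unless supplied.

    Returns a frame with participant_id, pdi/hpdi/updi totals and the weighted
    quintile of each total (for Table-1-style summaries).
    """
    sm = sm or default_scoring_matrix()
    cube = _stack(matrices)
    n = cube.shape[0]
    if cuts is None:
        cuts = compute_cutpoints(cube, weights)
    if participant_ids is None:
        if not isinstance(matrices, np.ndarray):
            participant_ids = [m.participant_id for m in matrices]
        else:
            participant_ids = np.arange(n)

    # base quintiles per unit: 1 + #cuts strictly below the intake
    base = 1 + np.sum(cuts[None, :, :, :] < cube[:, :, :, None], axis=3)  # (n,23,2)
    out = {"participant_id": np.asarray(participant_ids)}
    cat_rows = {
        cat: np.array([g.category is cat for g in DEFAULT_GROUPS]) for cat in Category
    }
    for name in INDICES:
        total = np.zeros(n, dtype=int)
        for cat in Category:
            for ci, ctx in enumerate(CONTEXTS):
                rule = sm[(name, cat, ctx)]
                s = base[:, cat_rows[cat], ci]
                if rule.orientation == "reverse":
                    s = 6 - s
                total += rule.weight * s.sum(axis=1)
        out[name] = total
    df = pd.DataFrame(out)
    w = np.asarray(weights, float)
    probs = np.array([0.2, 0.4, 0.6, 0.8])
    for name in INDICES:
        tcuts = weighted_quantile_lower(df[name].to_numpy(float), w, probs)
        df[f"{name}_quintile"] = 1 + np.sum(
            tcuts[None, :] < df[name].to_numpy(float)[:, None], axis=1
        )
    return df


def extreme_cohort_score(
    index: str, extreme: str, seed: int = 0, n_fillers: int = 9
) -> int:
    """Attainable extreme of an index total, computed through the engine.

    Builds an adversarial cohort: filler participants with strictly increasing
    intakes in every unit, plus one target participant placed above the top
    cut in every unit the index rewards (for ``extreme="max"``; penalised
    units at zero) or vice versa for ``"min"``. Cutpoints and scores are then
    computed exactly as for a real cohort, so the result is the engine's own
    theoretical bound, not a formula. The seed jitters the filler scale and
    survey weights, which cannot move the quintile memberships.
    """
    if index not in INDICES:
        raise ValueError(f"unknown index {index!r}")
    if extreme not in ("min", "max"):
        raise ValueError("extreme must be 'min' or 'max'")
    rng = np.random.default_rng(seed)
    sm = default_scoring_matrix()
    scale = rng.uniform(0.9, 1.1)
    weights = rng.uniform(0.5, 1.5, n_fillers + 1)

    cube = np.zeros((n_fillers + 1, N_GROUPS, 2))
    for i in range(n_fillers):
        cube[i + 1, :, :] = (i + 1) * scale
    big = 100.0 * scale
    target = np.zeros((N_GROUPS, 2))
    for g in DEFAULT_GROUPS:
        for ci, ctx in enumerate(CONTEXTS):
            positive = sm[(index, g.category, ctx)].orientation == "positive"
            if (extreme == "max") == positive:
                target[g.group_id - 1, ci] = big
    cube[0] = target

    cuts = compute_cutpoints(cube, weights)
    scores = score_participant(FoodGroupIntakeMatrix("target", target), cuts, sm)
    return int(getattr(scores, index))
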