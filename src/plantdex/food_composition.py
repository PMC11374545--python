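"""Food-group taxonomy and ingredient-level decomposition of 24-h recall records.

The diet-index scoring system rests on a fixed taxonomy of 23 food groups —
7 "healthy plant", 5 "unhealthy plant" and 11 "animal" — crossed with a
core/discretionary context inherited from the Australian Dietary Guidelines.
Multi-ingredient foods and mixed dishes are decomposed into per-group gram
contributions via a composition table mapping each 8-digit food code to a
set of (group, fraction) pairs; the context is a property of the parent
product, so a fruit fraction inside a discretionary cake counts as fruit
consumed in discretionary context.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_GROUPS = 23
FRACTION_TOL = 1e-9


class Category(str, enum.Enum):
    HEALTHY_PLANT = "healthy_plant"
    UNHEALTHY_PLANT = "unhealthy_plant"
    ANIMAL = "animal"


class Context(str, enum.Enum):
    CORE = "core"
    DISCRETIONARY = "discretionary"


CONTEXTS: tuple[Context, Context] = (Context.CORE, Context.DISCRETIONARY)
CONTEXT_COL = {Context.CORE: 0, Context.DISCRETIONARY: 1}


class CompositionError(ValueError):
    """Raised when a food record's ingredient fractions are inconsistent."""


class InputError(ValueError):
    """Raised for physically impossible inputs (negative grams, bad ids)."""


class PairingError(ValueError):
    """Raised when two per-day objects belong to different participants."""


@dataclass(frozen=True)
class FoodGroup:
    group_id: int
    name: str
    category: Category


# The 7 healthy-plant and 5 unhealthy-plant groups and 9 of the animal groups
# carry their conventional labels; the final two animal groups are placeholders
# whose labels are configurable (only the counts are structural).
DEFAULT_GROUPS: tuple[FoodGroup, ...] = (
    FoodGroup(1, "whole grains", Category.HEALTHY_PLANT),
    FoodGroup(2, "fruits", Category.HEALTHY_PLANT),
    FoodGroup(3, "vegetables", Category.HEALTHY_PLANT),
    FoodGroup(4, "nuts and seeds", Category.HEALTHY_PLANT),
    FoodGroup(5, "legumes", Category.HEALTHY_PLANT),
    FoodGroup(6, "unsaturated plant oils and spreads", Category.HEALTHY_PLANT),
    FoodGroup(7, "tea and coffee", Category.HEALTHY_PLANT),
    FoodGroup(8, "refined grains", Category.UNHEALTHY_PLANT),
    FoodGroup(9, "fruit juices", Category.UNHEALTHY_PLANT),
    FoodGroup(10, "saturated plant fats", Category.UNHEALTHY_PLANT),
    FoodGroup(11, "sugars and syrups", Category.UNHEALTHY_PLANT),
    FoodGroup(12, "miscellaneous plant products", Category.UNHEALTHY_PLANT),
    FoodGroup(13, "animal fats", Category.ANIMAL),
    FoodGroup(14, "low-fat dairy", Category.ANIMAL),
    FoodGroup(15, "moderate-fat dairy", Category.ANIMAL),
    FoodGroup(16, "high-fat dairy", Category.ANIMAL),
    FoodGroup(17, "eggs", Category.ANIMAL),
    FoodGroup(18, "fish and seafood", Category.ANIMAL),
    FoodGroup(19, "processed or non-lean red meat and poultry", Category.ANIMAL),
    FoodGroup(20, "unprocessed lean red meat and poultry", Category.ANIMAL),
    FoodGroup(21, "miscellaneous animal products", Category.ANIMAL),
    FoodGroup(22, "animal-based sauces and condiments", Category.ANIMAL),
    FoodGroup(23, "animal-based mixed-dish bases", Category.ANIMAL),
)

GROUP_BY_NAME = {g.name: g for g in DEFAULT_GROUPS}
CATEGORY_OF_GROUP = np.array(
    [g.category for g in DEFAULT_GROUPS], dtype=object
)  # row index = group_id - 1


def validate_taxonomy(groups: tuple[FoodGroup, ...] = DEFAULT_GROUPS) -> None:
    """Enforce the structural constraints: 23 groups, a 7/5/11 category split,
    and consecutive 1-based ids."""
    if len(groups) != N_GROUPS:
        raise ValueError(f"expected {N_GROUPS} food groups, got {len(groups)}")
    if sorted(g.group_id for g in groups) != list(range(1, N_GROUPS + 1)):
        raise ValueError("group ids must be 1..23 with no gaps")
    counts = {c: sum(g.category is c for g in groups) for c in Category}
    expected = {Category.HEALTHY_PLANT: 7, Category.UNHEALTHY_PLANT: 5, Category.ANIMAL: 11}
    if counts != expected:
        raise ValueError(f"category split {counts} != required {expected}")


validate_taxonomy()


@dataclass
class FoodRecord:
    """One consumed food: code, mass, context, and its group composition."""

    food_code: int
    grams: float
    context: Context
    composition: list[tuple[int, float]]

    def __post_init__(self) -> None:
        if self.grams < 0:
            raise InputError(f"food {self.food_code}: negative grams {self.grams}")
        total = sum(f for _, f in self.composition)
        if abs(total - 1.0) > FRACTION_TOL:
            raise CompositionError(
                f"food {self.food_code}: composition fractions sum to {total!r}, not 1"
            )
        for gid, frac in self.composition:
            if not 1 <= gid <= N_GROUPS:
                raise InputError(f"food {self.food_code}: unknown group id {gid}")
            if not 0.0 <= frac <= 1.0:
                raise CompositionError(
                    f"food {self.food_code}: fraction {frac} outside [0, 1]"
                )


@dataclass
class FoodGroupIntakeMatrix:
    """Grams/day for 23 food groups x {core, discretionary} for one participant."""

    participant_id: object
    values: np.ndarray = field(
        default_factory=lambda: np.zeros((N_GROUPS, 2))
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_GROUPS, 2):
            raise InputError(f"intake matrix must be {N_GROUPS}x2, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("intake matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise InputError("intake matrix contains negative grams")

    def get(self, group_id: int, context: Context) -> float:
        return float(self.values[group_id - 1, CONTEXT_COL[context]])

    def total_grams(self) -> float:
        return float(self.values.sum())


def decompose_foods(
    records: list[FoodRecord], participant_id: object = None
) -> FoodGroupIntakeMatrix:
    """Decompose a list of food records into the 23x2 gram matrix.

    Entry (g, c) accumulates grams x fraction over all records consumed in
    context c; total mass is conserved because each record's fractions sum
    to one.
    """
    values = np.zeros((N_GROUPS, 2))
    for rec in records:
        col = CONTEXT_COL[rec.context]
        for gid, frac in rec.composition:
            values[gid - 1, col] += rec.grams * frac
    return FoodGroupIntakeMatrix(participant_id, values)


def average_days(
    day1: FoodGroupIntakeMatrix, day2: FoodGroupIntakeMatrix
) -> FoodGroupIntakeMatrix:
    """Entry-wise mean of the two recall days for one participant."""
    if day1.participant_id != day2.participant_id:
        raise PairingError(
            f"cannot average days of participants "
            f"{day1.participant_id!r} and {day2.participant_id!r}"
        )
    return FoodGroupIntakeMatrix(day1.participant_id, (day1.values + day2.values) / 2.0)


# ---------------------------------------------------------------------------
# Composition-table and recall-file interfaces (CSV schemas)
# ---------------------------------------------------------------------------

def pure_code(group_id: int, context: Context) -> int:
    """Synthetic 8-digit code for a single-ingredient food of one group."""
    return int(f"1{group_id:02d}0000{1 if context is Context.CORE else 2}")


# Multi-ingredient synthetic codes (context is the parent product's):
# fractions must sum to 1 within each dish.
COMPOSITE_FOODS: dict[int, tuple[Context, tuple[tuple[int, float], ...]]] = {
    90000001: (  # discretionary cake
        Context.DISCRETIONARY,
        ((8, 0.50), (11, 0.25), (17, 0.15), (2, 0.10)),
    ),
    90000002: (  # core stir-fry
        Context.CORE,
        ((3, 0.50), (20, 0.30), (6, 0.10), (1, 0.10)),
    ),
    90000003: (  # discretionary pizza
        Context.DISCRETIONARY,
        ((8, 0.45), (16, 0.30), (19, 0.15), (3, 0.10)),
    ),
    90000004: (  # core muesli
        Context.CORE,
        ((1, 0.60), (4, 0.20), (2, 0.20)),
    ),
}


def synthetic_composition_table() -> pd.DataFrame:
    """Build the fixture composition table: 46 single-ingredient codes (one per
    group x context) plus 4 multi-ingredient dishes; 50 codes in total.

    Columns: food_code, context, group_id, fraction (one row per ingredient).
    """
    rows: list[tuple[int, str, int, float]] = []
    for g in DEFAULT_GROUPS:
        for ctx in CONTEXTS:
            rows.append((pure_code(g.group_id, ctx), ctx.value, g.group_id, 1.0))
    for code, (ctx, comp) in COMPOSITE_FOODS.items():
        for gid, frac in comp:
            rows.append((code, ctx.value, gid, frac))
    return pd.DataFrame(rows, columns=["food_code", "context", "group_id", "fraction"])


def records_from_table(
    recalls: pd.DataFrame, composition: pd.DataFrame
) -> dict[tuple[object, int], list[FoodRecord]]:
    """Join a recall file (participant_id, day, food_code, grams) against the
    composition table and return validated FoodRecord lists per (participant, day)."""
    comp: dict[int, tuple[Context, list[tuple[int, float]]]] = {}
    for code, sub in composition.groupby("food_code"):
        ctxs = sub["context"].unique()
        if len(ctxs) != 1:
            raise CompositionError(f"food {code}: inconsistent context labels {ctxs}")
        comp[int(code)] = (
            Context(ctxs[0]),
            list(zip(sub["group_id"].astype(int), sub["fraction"].astype(float))),
        )
    out: dict[tuple[object, int], list[FoodRecord]] = {}
    for (pid, day), sub in recalls.groupby(["participant_id", "day"], sort=False):
        recs = []
        for code, grams in zip(sub["food_code"].astype(int), sub["grams"].astype(float)):
            if code not in comp:
                raise CompositionError(f"food {code}: not in composition table")
            ctx, parts = comp[code]
            recs.append(FoodRecord(code, grams, ctx, list(parts)))
        out[(pid, int(day))] = recs
    return out


def intake_matrices_from_tables(
    recalls: pd.DataFrame, composition: pd.DataFrame
) -> dict[tuple[object, int], FoodGroupIntakeMatrix]:
    """Vectorised decomposition of a whole recall file.

    Equivalent to running :func:`decompose_foods` per (participant, day) but a
    single merged multiply-scatter, which matters at cohort scale.
    """
    merged = recalls.merge(composition, on="food_code", how="left", validate="m:m")
    if merged["group_id"].isna().any():
        bad = recalls.loc[
            ~recalls["food_code"].isin(composition["food_code"]), "food_code"
        ].unique()
        raise CompositionError(f"food codes missing from composition table: {bad[:5]}")
    contrib = merged["grams"].to_numpy(float) * merged["fraction"].to_numpy(float)
    if np.any(merged["grams"].to_numpy(float) < 0):
        raise InputError("recall file contains negative grams")

    keys = pd.MultiIndex.from_frame(merged[["participant_id", "day"]])
    key_codes, key_index = pd.factorize(keys)
    rows = merged["group_id"].to_numpy(int) - 1
    cols = np.where(merged["context"].to_numpy() == Context.CORE.value, 0, 1)
    cube = np.zeros((len(key_index), N_GROUPS, 2))
    np.add.at(cube, (key_codes, rows, cols), contrib)
    return {
        (pid, int(day)): FoodGroupIntakeMatrix(pid, cube[i])
        for i, (pid, day) in enumerate(key_index)
    }
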