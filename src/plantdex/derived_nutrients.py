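"""Nutrient-derived diet metrics: two-day mean profiles, protein-to-fibre
ratio and potential renal acid load (PRAL).

PRAL estimates the diet's net acid load in mEq/d from five nutrients:

    PRAL = 0.49 x protein (g/d) + 0.037 x phosphorus (mg/d)
           - 0.021 x potassium (mg/d) - 0.026 x magnesium (mg/d)
           - 0.013 x calcium (mg/d)

Negative values indicate an alkalising (typically plant-rich) diet.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .food_composition import PairingError

PRAL_COEFFICIENTS = {
    "protein": 0.49,
    "phosphorus": 0.037,
    "potassium": -0.021,
    "magnesium": -0.026,
    "calcium": -0.013,
}

#: below this fibre intake (g/d) the protein:fibre ratio is numerically absurd
FIBRE_FLOOR = 0.1

NUTRIENT_FIELDS = (
    "energy_kj",
    "protein",
    "fibre",
    "phosphorus",
    "potassium",
    "magnesium",
    "calcium",
    "sodium",
    "sat_fat",
    "poly_fat",
    "alcohol",
)


class UndefinedRatioError(ValueError):
    """Raised when a ratio denominator is (effectively) zero."""


@dataclass
class NutrientProfile:
    """Daily nutrient intakes. Energy in kJ/d; protein, fibre, fats, alcohol
    in g/d; minerals in mg/d."""

    participant_id: object = None
    energy_kj: float = 0.0
    protein: float = 0.0
    fibre: float = 0.0
    phosphorus: float = 0.0
    potassium: float = 0.0
    magnesium: float = 0.0
    calcium: float = 0.0
    sodium: float = 0.0
    sat_fat: float = 0.0
    poly_fat: float = 0.0
    alcohol: float = 0.0

    def __post_init__(self) -> None:
        for name in NUTRIENT_FIELDS:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"nutrient {name}={v!r} must be finite and >= 0")


def pral(p: NutrientProfile) -> float:
    """Potential renal acid load in mEq/d (may be negative)."""
    return sum(coef * getattr(p, name) for name, coef in PRAL_COEFFICIENTS.items())


def protein_fibre_ratio(p: NutrientProfile) -> float:
    if p.fibre < FIBRE_FLOOR:
        raise UndefinedRatioError(
            f"fibre {p.fibre} g/d below {FIBRE_FLOOR}; protein:fibre ratio undefined"
        )
    return p.protein / p.fibre


def mean_profile(day1: NutrientProfile, day2: NutrientProfile) -> NutrientProfile:
    """Field-wise mean of the two recall days."""
    if day1.participant_id != day2.participant_id:
        raise PairingError(
            f"cannot average profiles of participants "
            f"{day1.participant_id!r} and {day2.participant_id!r}"
        )
    means = {
        name: (getattr(day1, name) + getattr(day2, name)) / 2.0
        for name in NUTRIENT_FIELDS
    }
    return NutrientProfile(day1.participant_id, **means)


# --- vectorised frame versions used by the pipeline -----------------------

def pral_frame(df: pd.DataFrame) -> pd.Series:
    out = pd.Series(0.0, index=df.index)
    for name, coef in PRAL_COEFFICIENTS.items():
        out = out + coef * df[name]
    return out


def protein_fibre_ratio_frame(df: pd.DataFrame) -> pd.Series:
    """Ratio per row; rows with fibre below the floor are NaN (flagged, not
    infinite) and excluded from downstream ratio summaries."""
    ratio = df["protein"] / df["fibre"]
    return ratio.where(df["fibre"] >= FIBRE_FLOOR)


def mean_profile_frame(nutrients: pd.DataFrame) -> pd.DataFrame:
    """Two-day mean per participant from a long nutrient table with columns
    participant_id, day, and one column per nutrient."""
    return (
        nutrients.groupby("participant_id", sort=False)[list(NUTRIENT_FIELDS)]
        .mean()
        .reset_index()
    )
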