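"""Synthetic national-nutrition-survey cohort generator.

Emulates the record structure of a two-recall nutrition survey linked to a
biomedical measures survey: per participant, two 24-h recall food-record
lists (8-digit codes against a synthetic composition table), a nutrient
profile per day, biomarkers (eGFR, urinary ACR, lipids, glycaemia),
anthropometrics, 2-3 blood-pressure readings, demographics/lifestyle, and a
calibration weight with 60 delete-a-group jackknife replicate weights.

The statistical backbone is a scalar latent "diet healthfulness" trait per
participant. Food-group intakes are zero-inflated log-normals whose
log-median and consumption probability shift with the trait (healthy-plant
groups up, unhealthy-plant and animal groups down), recall days are
independent draws around the participant's latent level, and nutrients are
linear in the group intakes with multiplicative noise — so fibre, potassium
and magnesium fall as the unhealthy plant-based diet index (uPDI) rises.

Disease is injected on the *scored* exposure: the generator computes each
participant's uPDI with the package's own scoring engine and draws
moderate-severe CKD from a logistic model whose uPDI slope is the configured
log odds ratio, with the intercept solved numerically so the marginal
prevalence hits its target. Stage 1-2 CKD (albuminuria with preserved eGFR)
is then topped up so total CKD prevalence matches its target. Biomarkers are
drawn consistently with the assigned stage, so the rule-based classifier
recovers the generated truth exactly.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import diet_indices as di
from . import food_composition as fc
from .food_composition import Category, Context, DEFAULT_GROUPS, N_GROUPS

CKD_N, CKD_TOTAL = 250, 2060
MODERATE_SEVERE_N = 103


class CalibrationFailureError(RuntimeError):
    """The prevalence target is unreachable given the injected effects."""


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    n: int = 2060
    seed: int = 0
    ckd_prevalence_target: float = CKD_N / CKD_TOTAL
    moderate_severe_fraction: float = MODERATE_SEVERE_N / CKD_N
    updi_ckd_log_or: float = float(np.log(1.037))
    covariate_effects: dict = field(
        default_factory=lambda: {
            "age": 0.03,        # per year, centred at 48
            "male": 0.25,
            "diabetes": 0.6,
            "hypertension": 0.4,
            "bmi": 0.02,        # per kg/m2, centred at 27
        }
    )
    nutrient_noise: float = 0.10      # log-sd of multiplicative nutrient noise
    biomarker_noise: float = 1.0      # scales biomarker residual sd
    rep_groups: int = 60
    population_total: float = 8_769_986.0
    health_loading: float = 0.35      # log-median shift per sd of the trait
    intake_overrides: dict = field(default_factory=dict)  # (gid, ctx) -> (pi0, med, sd)

    def __post_init__(self) -> None:
        if self.n < 50:
            raise ConfigError("n must be >= 50")
        for p in (self.ckd_prevalence_target, self.moderate_severe_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if self.rep_groups < 2:
            raise ConfigError("need at least 2 replicate groups")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["intake_overrides"] = {
            f"{gid}:{ctx}": list(v) for (gid, ctx), v in self.intake_overrides.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        d["intake_overrides"] = {
            (int(k.split(":")[0]), k.split(":")[1]): tuple(v)
            for k, v in d.get("intake_overrides", {}).items()
        }
        return cls(**d)


# ---------------------------------------------------------------------------
# Intake distribution defaults: per group, (core, discretionary) tuples of
# (zero-inflation pi0, median grams/day among consumers, log-sd between people)
# ---------------------------------------------------------------------------

_INTAKE_DEFAULTS: dict[int, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    1: ((0.20, 90, 0.55), (0.75, 25, 0.7)),    # whole grains
    2: ((0.15, 160, 0.55), (0.70, 30, 0.7)),   # fruits
    3: ((0.08, 210, 0.50), (0.65, 40, 0.7)),   # vegetables
    4: ((0.55, 18, 0.7), (0.80, 12, 0.8)),     # nuts and seeds
    5: ((0.60, 40, 0.7), (0.90, 15, 0.8)),     # legumes (zero-heavy)
    6: ((0.35, 15, 0.6), (0.80, 6, 0.8)),      # unsaturated plant oils/spreads
    7: ((0.15, 420, 0.6), (0.85, 150, 0.8)),   # tea and coffee
    8: ((0.12, 130, 0.5), (0.30, 70, 0.6)),    # refined grains
    9: ((0.70, 180, 0.6), (0.60, 130, 0.7)),   # fruit juices
    10: ((0.80, 10, 0.7), (0.60, 9, 0.7)),     # saturated plant fats
    11: ((0.45, 18, 0.7), (0.30, 28, 0.7)),    # sugars and syrups
    12: ((0.60, 25, 0.7), (0.50, 45, 0.7)),    # miscellaneous plant products
    13: ((0.70, 6, 0.7), (0.75, 5, 0.7)),      # animal fats
    14: ((0.50, 160, 0.6), (0.85, 40, 0.8)),   # low-fat dairy
    15: ((0.40, 170, 0.6), (0.75, 60, 0.8)),   # moderate-fat dairy
    16: ((0.50, 30, 0.7), (0.55, 35, 0.7)),    # high-fat dairy
    17: ((0.50, 55, 0.6), (0.80, 20, 0.7)),    # eggs
    18: ((0.62, 85, 0.6), (0.85, 40, 0.7)),    # fish and seafood
    19: ((0.40, 85, 0.6), (0.45, 60, 0.7)),    # processed / non-lean meat
    20: ((0.30, 130, 0.55), (0.75, 50, 0.7)),  # unprocessed lean meat
    21: ((0.70, 22, 0.7), (0.70, 25, 0.7)),    # miscellaneous animal products
    22: ((0.65, 16, 0.7), (0.60, 18, 0.7)),    # animal-based sauces/condiments
    23: ((0.70, 35, 0.7), (0.65, 40, 0.7)),    # animal-based mixed-dish bases
}

# medians above are round per-group portion figures; scaled so the implied
# mean energy intake lands near 8.7 MJ/d, typical of adult two-recall surveys
_PORTION_SCALE = 0.72

_CATEGORY_SIGN = {
    Category.HEALTHY_PLANT: +1.0,
    Category.UNHEALTHY_PLANT: -1.0,
    Category.ANIMAL: -0.6,
}

# nutrient densities per gram of food-group intake (context-independent)
# rows: group 1..23; values chosen to be order-of-magnitude realistic.
_DENS = {
    # group:      prot  fibre   K    Mg    Ca    P    Na  sat  poly  kJ/g
    1:  (0.10, 0.090, 1.5, 1.00, 0.30, 2.0, 0.5, 0.005, 0.010, 12.0),
    2:  (0.010, 0.022, 1.8, 0.10, 0.10, 0.2, 0.0, 0.000, 0.000, 2.5),
    3:  (0.020, 0.028, 2.6, 0.20, 0.40, 0.4, 0.3, 0.000, 0.000, 1.5),
    4:  (0.200, 0.080, 6.0, 2.50, 0.70, 4.0, 0.2, 0.060, 0.250, 25.0),
    5:  (0.080, 0.070, 3.0, 0.50, 0.50, 1.5, 0.1, 0.002, 0.005, 5.0),
    6:  (0.000, 0.000, 0.1, 0.00, 0.00, 0.1, 0.6, 0.100, 0.350, 34.0),
    7:  (0.002, 0.000, 0.3, 0.03, 0.02, 0.1, 0.0, 0.000, 0.000, 0.4),
    8:  (0.090, 0.025, 0.8, 0.25, 0.20, 1.0, 4.0, 0.005, 0.010, 11.0),
    9:  (0.005, 0.002, 1.5, 0.10, 0.10, 0.2, 0.0, 0.000, 0.000, 2.0),
    10: (0.000, 0.000, 0.1, 0.00, 0.00, 0.1, 0.3, 0.450, 0.020, 33.0),
    11: (0.000, 0.000, 0.2, 0.00, 0.00, 0.0, 0.1, 0.000, 0.000, 16.0),
    12: (0.020, 0.030, 1.0, 0.30, 0.50, 0.8, 3.0, 0.030, 0.010, 8.0),
    13: (0.000, 0.000, 0.1, 0.00, 0.00, 0.1, 0.7, 0.500, 0.030, 36.0),
    14: (0.040, 0.000, 1.5, 0.11, 1.20, 1.0, 0.5, 0.005, 0.001, 2.0),
    15: (0.035, 0.000, 1.5, 0.11, 1.20, 1.0, 0.5, 0.035, 0.001, 3.0),
    16: (0.060, 0.000, 1.0, 0.25, 5.00, 4.0, 6.0, 0.200, 0.005, 14.0),
    17: (0.130, 0.000, 1.3, 0.12, 0.50, 2.0, 1.4, 0.030, 0.015, 6.5),
    18: (0.200, 0.000, 3.3, 0.30, 0.20, 2.4, 0.8, 0.010, 0.020, 7.0),
    19: (0.150, 0.000, 2.5, 0.22, 0.10, 2.0, 9.0, 0.080, 0.010, 11.0),
    20: (0.220, 0.000, 3.3, 0.25, 0.05, 2.0, 0.7, 0.020, 0.008, 7.0),
    21: (0.100, 0.000, 1.0, 0.10, 0.30, 1.2, 4.0, 0.040, 0.005, 8.0),
    22: (0.030, 0.000, 0.5, 0.05, 0.30, 0.5, 12.0, 0.020, 0.010, 5.0),
    23: (0.080, 0.000, 1.5, 0.15, 0.40, 1.2, 4.0, 0.040, 0.010, 7.0),
}
_NUTRIENT_ORDER = (
    "protein", "fibre", "potassium", "magnesium", "calcium",
    "phosphorus", "sodium", "sat_fat", "poly_fat", "energy_kj",
)
_DENS_MATRIX = np.array([_DENS[g] for g in range(1, N_GROUPS + 1)])  # (23, 10)

ALCOHOL_KJ_PER_G = 29.0


@dataclass
class SyntheticCohort:
    config: GeneratorConfig
    demographics: pd.DataFrame
    recalls: pd.DataFrame
    nutrients: pd.DataFrame
    biomarkers: pd.DataFrame
    design: pd.DataFrame
    composition: pd.DataFrame
    truth: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.demographics)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "demographics": self.demographics,
            "recalls": self.recalls,
            "nutrients": self.nutrients,
            "biomarkers": self.biomarkers,
            "design": self.design,
            "food_composition": self.composition,
            "truth": self.truth,
        }


def _softmax_choice(rng, base_probs: np.ndarray, tilt: np.ndarray) -> np.ndarray:
    """Sample a category per row: log base probabilities tilted by a per-row
    score that increases the probability of higher-indexed levels."""
    k = len(base_probs)
    grad = np.linspace(-1, 1, k)
    logits = np.log(base_probs)[None, :] + tilt[:, None] * grad[None, :]
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(tilt))[:, None]
    return (p.cumsum(axis=1) < u).sum(axis=1)


def _draw_intakes(rng, cfg: GeneratorConfig, health: np.ndarray) -> np.ndarray:
    """Zero-inflated log-normal intakes, shape (n, 2 days, 23 groups, 2 contexts)."""
    n = cfg.n
    intakes = np.zeros((n, 2, N_GROUPS, 2))
    for g in DEFAULT_GROUPS:
        sign = _CATEGORY_SIGN[g.category]
        for ci in range(2):
            pi0, med, sd = cfg.intake_overrides.get(
                (g.group_id, fc.CONTEXTS[ci].value),
                _INTAKE_DEFAULTS[g.group_id][ci],
            )
            # consumption probability tilted by the healthfulness trait
            p_consume = expit(logit(np.clip(1 - pi0, 1e-6, 1 - 1e-6))
                              + 0.5 * sign * health)
            consumer = rng.random(n) < p_consume
            latent = (np.log(med * _PORTION_SCALE) + cfg.health_loading * sign * health
                      + sd * rng.standard_normal(n))
            for day in range(2):
                vals = np.exp(latent + 0.35 * rng.standard_normal(n))
                if pi0 >= 0.5:  # episodic foods: consumers skip days too
                    vals *= rng.random(n) >= 0.25
                intakes[:, day, g.group_id - 1, ci] = np.where(consumer, vals, 0.0)
    return intakes


def _records_from_intakes(rng, intakes: np.ndarray) -> pd.DataFrame:
    """Express the drawn intakes as recall rows. Part of the discretionary and
    core mass is delivered through multi-ingredient dishes (exactly consistent
    with the composition table), the remainder through single-ingredient codes,
    so decomposition round-trips the intake cube."""
    n = intakes.shape[0]
    work = intakes.copy()
    rows_pid: list[np.ndarray] = []
    rows_day: list[np.ndarray] = []
    rows_code: list[np.ndarray] = []
    rows_grams: list[np.ndarray] = []

    ctx_col = {Context.CORE: 0, Context.DISCRETIONARY: 1}
    for code, (ctx, comp) in fc.COMPOSITE_FOODS.items():
        ci = ctx_col[ctx]
        gids = np.array([gid for gid, _ in comp]) - 1
        fracs = np.array([f for _, f in comp])
        for day in range(2):
            sub = work[:, day, gids, ci]  # (n, k)
            feasible = (sub > 1e-9).all(axis=1)
            chosen = feasible & (rng.random(n) < 0.35)
            if not chosen.any():
                continue
            share = rng.uniform(0.3, 0.8, size=n)
            g_max = (sub / fracs[None, :]).min(axis=1)
            grams = np.where(chosen, share * g_max, 0.0)
            work[:, day, gids, ci] -= grams[:, None] * fracs[None, :]
            idx = np.nonzero(chosen)[0]
            rows_pid.append(idx)
            rows_day.append(np.full(idx.size, day + 1))
            rows_code.append(np.full(idx.size, code))
            rows_grams.append(grams[idx])

    pure_codes = np.array(
        [[fc.pure_code(g.group_id, ctx) for ctx in fc.CONTEXTS] for g in DEFAULT_GROUPS]
    )  # (23, 2)
    for day in range(2):
        pid_i, g_i, c_i = np.nonzero(work[:, day] > 1e-12)
        rows_pid.append(pid_i)
        rows_day.append(np.full(pid_i.size, day + 1))
        rows_code.append(pure_codes[g_i, c_i])
        rows_grams.append(work[pid_i, day, g_i, c_i])

    df = pd.DataFrame(
        {
            "participant_id": np.concatenate(rows_pid) + 1,
            "day": np.concatenate(rows_day).astype(int),
            "food_code": np.concatenate(rows_code).astype(int),
            "grams": np.concatenate(rows_grams),
        }
    )
    return df.sort_values(["participant_id", "day", "food_code"],
                          kind="stable").reset_index(drop=True)


def _solve_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + eta)) == target, by bisection."""
    def f(c):
        return float(np.mean(expit(c + eta))) - target

    lo, hi = -60.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationFailureError(
            f"prevalence target {target} unreachable for the injected effects"
        )
    return brentq(f, lo, hi, xtol=1e-10)


def generate_cohort(cfg: GeneratorConfig | None = None, **overrides) -> SyntheticCohort:
    """Deterministically generate a complete synthetic cohort from the config."""
    if cfg is None:
        cfg = GeneratorConfig(**overrides)
    elif overrides:
        d = cfg.to_dict()
        d.update(overrides)
        cfg = GeneratorConfig.from_dict(d)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    pid = np.arange(1, n + 1)

    # --- demographics and the latent healthfulness trait -------------------
    age = 18.0 + 67.0 * rng.beta(1.7, 2.0, size=n)
    male = rng.random(n) < 928 / 2060
    sex = np.where(male, "male", "female")
    z_age = (age - age.mean()) / age.std()
    health = 0.25 * z_age + np.sqrt(1 - 0.25**2) * rng.standard_normal(n)

    education = pd.Categorical.from_codes(
        _softmax_choice(rng, np.array([0.30, 0.45, 0.25]), 0.35 * health),
        categories=["low", "medium", "high"],
    )
    smoking = pd.Categorical.from_codes(
        _softmax_choice(rng, np.array([0.52, 0.31, 0.17]), -0.45 * health),
        categories=["never", "ex", "current"],
    )
    activity = pd.Categorical.from_codes(
        _softmax_choice(rng, np.array([0.25, 0.30, 0.30, 0.15]), 0.35 * health),
        categories=["sedentary", "low", "moderate", "high"],
    )

    # --- anthropometry, blood pressure, biochemistry ------------------------
    noise = cfg.biomarker_noise
    height = np.where(male, rng.normal(175.0, 7.0, n), rng.normal(162.0, 6.5, n))
    bmi = np.clip(rng.normal(27.5, 5.0 * noise, n) - 0.8 * health, 16.0, 55.0)
    weight = bmi * (height / 100.0) ** 2
    waist = np.clip(
        80.0 + 2.5 * (bmi - 27.0) + 8.0 * male + rng.normal(0, 6.0 * noise, n),
        55.0, 180.0,
    )

    sys_base = 112.0 + 0.45 * (age - 48.0) + 0.35 * (bmi - 27.0) \
        + rng.normal(0, 11.0 * noise, n)
    dia_base = 72.0 + 0.10 * (age - 48.0) + 0.30 * (bmi - 27.0) \
        + rng.normal(0, 7.5 * noise, n)
    sys1 = np.clip(sys_base + 3.0 + rng.normal(0, 4.5, n), 70, 250)
    dia1 = np.clip(dia_base + 1.5 + rng.normal(0, 3.5, n), 40, 150)
    sys2 = np.clip(sys_base + rng.normal(0, 4.5, n), 70, 250)
    dia2 = np.clip(dia_base + rng.normal(0, 3.5, n), 40, 150)
    third = (np.abs(sys1 - sys2) > 10) | (np.abs(dia1 - dia2) > 10)
    sys3 = np.where(third, np.clip(sys_base + rng.normal(0, 4.5, n), 70, 250), np.nan)
    dia3 = np.where(third, np.clip(dia_base + rng.normal(0, 3.5, n), 40, 150), np.nan)

    diabetic = rng.random(n) < expit(-3.3 + 0.03 * (age - 48.0) + 0.08 * (bmi - 27.0))
    hba1c = np.clip(
        5.35 + 0.01 * (age - 48.0) + 0.02 * (bmi - 27.0)
        + rng.normal(0, 0.35 * noise, n)
        + diabetic * (1.2 + rng.exponential(1.0, n)),
        4.0, 15.0,
    )
    total_chol = np.clip(
        4.2 + 0.013 * (age - 48.0) + 0.04 * (bmi - 27.0) + rng.normal(0, 0.9 * noise, n),
        2.0, 12.0,
    )
    hdl = np.clip(
        1.5 - 0.015 * (bmi - 27.0) + 0.15 * (~male) + rng.normal(0, 0.30 * noise, n),
        0.4, 4.0,
    )
    tag = np.clip(
        np.exp(np.log(1.2) + 0.03 * (bmi - 27.0) + rng.normal(0, 0.45 * noise, n)),
        0.3, 15.0,
    )
    ldl = np.clip(total_chol - hdl - 0.45 * tag, 0.3, None)
    glucose = np.clip(
        4.9 + 0.04 * (bmi - 27.0) + 1.8 * diabetic + rng.normal(0, 0.5 * noise, n),
        2.5, 25.0,
    )
    apob = np.clip(0.25 + 0.15 * ldl + rng.normal(0, 0.10 * noise, n), 0.2, 3.0)
    fasted = rng.random(n) < 0.8
    ldl = np.where(fasted, ldl, np.nan)
    tag = np.where(fasted, tag, np.nan)
    glucose = np.where(fasted, glucose, np.nan)

    # --- intakes, recalls, nutrients ----------------------------------------
    intakes = _draw_intakes(rng, cfg, health)
    recalls = _records_from_intakes(rng, intakes)

    drinker = rng.random(n) < 0.55
    alcohol_days = np.where(
        drinker[:, None],
        np.exp(np.log(12.0) + 0.8 * rng.standard_normal((n, 2))),
        0.0,
    )
    nutrient_rows = []
    for day in range(2):
        grams_by_group = intakes[:, day].sum(axis=2)  # (n, 23), core+disc
        base = grams_by_group @ _DENS_MATRIX  # (n, 10)
        jitter = np.exp(cfg.nutrient_noise * rng.standard_normal(base.shape))
        vals = base * jitter
        frame = pd.DataFrame(vals, columns=_NUTRIENT_ORDER)
        frame["alcohol"] = alcohol_days[:, day]
        frame["energy_kj"] += ALCOHOL_KJ_PER_G * frame["alcohol"]
        frame.insert(0, "day", day + 1)
        frame.insert(0, "participant_id", pid)
        nutrient_rows.append(frame)
    nutrients = (
        pd.concat(nutrient_rows)
        .sort_values(["participant_id", "day"], kind="stable")
        .reset_index(drop=True)
    )

    # --- survey design -------------------------------------------------------
    w = np.exp(rng.normal(0, 0.35, n))
    w *= cfg.population_total / w.sum()
    groups = np.arange(n) % cfg.rep_groups
    scale = cfg.rep_groups / (cfg.rep_groups - 1)
    rep = np.where(groups[:, None] == np.arange(cfg.rep_groups)[None, :],
                   0.0, w[:, None] * scale)
    design = pd.DataFrame({"participant_id": pid, "weight": w})
    for r in range(cfg.rep_groups):
        design[f"repwt_{r + 1}"] = rep[:, r]

    # --- CKD injection on the scored exposure --------------------------------
    mean_mat = intakes.mean(axis=1)  # (n, 23, 2)
    scores = di.score_cohort(mean_mat, w, participant_ids=pid)
    updi = scores["updi"].to_numpy(float)

    eff = cfg.covariate_effects
    hypert = (np.where(third, (sys2 + sys3) / 2, sys2) >= 140.0) | (
        np.where(third, (dia2 + dia3) / 2, dia2) >= 90.0
    )
    eta = (
        cfg.updi_ckd_log_or * updi
        + eff.get("age", 0.0) * (age - 48.0)
        + eff.get("male", 0.0) * male
        + eff.get("diabetes", 0.0) * (hba1c >= 6.5)
        + eff.get("hypertension", 0.0) * hypert
        + eff.get("bmi", 0.0) * (bmi - 27.0)
    )
    p_ms_target = cfg.ckd_prevalence_target * cfg.moderate_severe_fraction
    if p_ms_target > 0:
        c = _solve_intercept(eta, p_ms_target)
        stage3 = rng.random(n) < expit(c + eta)
    else:
        stage3 = np.zeros(n, bool)
    n3 = int(stage3.sum())
    want_any = cfg.ckd_prevalence_target * n
    q = np.clip((want_any - n3) / max(n - n3, 1), 0.0, 1.0)
    stage12 = (~stage3) & (rng.random(n) < q)

    thr = np.where(male, 2.5, 3.5)
    egfr = np.where(
        stage3,
        np.clip(rng.normal(46.0, 9.0, n), 8.0, 59.5),
        np.clip(rng.normal(96.0, 14.0, n), 60.5, 140.0),
    )
    albuminuric = stage12 | (stage3 & (rng.random(n) < 0.5))
    acr = np.where(
        albuminuric,
        thr * rng.uniform(1.1, 10.0, n),
        thr * rng.uniform(0.02, 0.85, n),
    )

    demographics = pd.DataFrame(
        {
            "participant_id": pid,
            "age": age,
            "sex": sex,
            "education": education.astype(str),
            "smoking": smoking.astype(str),
            "physical_activity": activity.astype(str),
        }
    )
    biomarkers = pd.DataFrame(
        {
            "participant_id": pid,
            "sex": sex,
            "egfr": egfr,
            "acr": acr,
            "total_chol": total_chol,
            "hdl": hdl,
            "ldl": ldl,
            "tag": tag,
            "glucose": glucose,
            "hba1c": hba1c,
            "apob": apob,
            "fasted_8h": fasted,
            "height_cm": height,
            "weight_kg": weight,
            "waist_cm": waist,
            "sys1": sys1, "dia1": dia1,
            "sys2": sys2, "dia2": dia2,
            "sys3": sys3, "dia3": dia3,
        }
    )
    truth = pd.DataFrame(
        {
            "participant_id": pid,
            "latent_health": health,
            "updi_true": updi,
            "pdi_true": scores["pdi"],
            "hpdi_true": scores["hpdi"],
            "ckd_stage_true": np.where(
                stage3, "stage3_5", np.where(stage12, "stage1_2", "none")
            ),
        }
    )
    return SyntheticCohort(
        cfg, demographics, recalls, nutrients, biomarkers, design,
        fc.synthetic_composition_table(), truth,
    )


def inject_missingness(
    cohort: SyntheticCohort,
    rate: float,
    seed: int,
    fields: tuple[str, ...] = ("egfr", "acr"),
) -> SyntheticCohort:
    """Set the given biomarker/demographic fields missing completely at random."""
    if not 0.0 <= rate < 1.0:
        raise ConfigError(f"missingness rate {rate} outside [0, 1)")
    out = copy.deepcopy(cohort)
    rng = np.random.default_rng(seed)
    for f in fields:
        for tab in (out.biomarkers, out.demographics):
            if f in tab.columns:
                mask = rng.random(len(tab)) < rate
                col = tab[f]
                if col.dtype.kind in "ifu":
                    tab.loc[mask, f] = np.nan
                else:
                    tab[f] = col.astype(object)
                    tab.loc[mask, f] = None
                break
    return out


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(cohort: SyntheticCohort, directory) -> list[Path]:
    """Emit the CSV file set consumed by the pipeline plus the generator
    config, all plain text; regenerable bit-identically from (config, seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in cohort.tables().items():
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    cfg_path = directory / "generator_config.json"
    cfg_path.write_text(json.dumps(cohort.config.to_dict(), indent=2, sort_keys=True))
    written.append(cfg_path)
    return written


def read_fixture(directory) -> SyntheticCohort:
    directory = Path(directory)
    cfg = GeneratorConfig.from_dict(
        json.loads((directory / "generator_config.json").read_text())
    )
    tabs = {
        name: pd.read_csv(directory / f"{name}.csv")
        for name in ("demographics", "recalls", "nutrients", "biomarkers",
                     "design", "food_composition", "truth")
    }
    return SyntheticCohort(
        cfg, tabs["demographics"], tabs["recalls"], tabs["nutrients"],
        tabs["biomarkers"], tabs["design"], tabs["food_composition"], tabs["truth"],
    )
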