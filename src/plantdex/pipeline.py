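"""End-to-end orchestration: exclusions, scoring, classification, model ladder.

The analysis sample is built by applying four exclusion rules sequentially
(each participant counted once, at the first rule that removes them):

1. age < 18 years;
2. only one 24-h recall completed;
3. suspected energy under-reporting — two-day mean energy intake below
   800 kcal/d (3347.2 kJ/d) for men or 500 kcal/d (2092.0 kJ/d) for women;
4. missing data for any required covariate or variable of interest.

Quintile cutpoints are then computed on the retained, survey-weighted sample,
the three diet indices are scored, outcomes are classified, and the
regression ladder is fitted per index with replicate-weight standard errors.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import derived_nutrients as dn
from . import diet_indices as di
from . import food_composition as fc
from . import outcome_classification as oc
from . import survey_inference as si
from .synthetic_data import SyntheticCohort, read_fixture

KCAL_TO_KJ = 4.184
ENERGY_CUTOFF_MALE_KJ = 800.0 * KCAL_TO_KJ    # 3347.2
ENERGY_CUTOFF_FEMALE_KJ = 500.0 * KCAL_TO_KJ  # 2092.0

DEFAULT_REQUIRED_COLUMNS = (
    "age", "sex", "education", "smoking", "physical_activity",
    "energy_kj", "alcohol", "bmi", "waist_cm",
    "egfr", "acr", "hba1c", "systolic_bp", "diastolic_bp",
)
DEFAULT_CONTINUOUS_OUTCOMES = (
    "systolic_bp", "bmi", "waist_cm", "hdl", "tag", "glucose",
    "hba1c", "total_chol", "ldl", "pral", "protein_fibre_ratio",
)
DEFAULT_BINARY_OUTCOMES = ("any_ckd", "moderate_severe")


class PipelineAbortError(RuntimeError):
    """The cohort is unusable (e.g. empty after exclusions)."""


class ValidationError(ValueError):
    """Invalid run configuration or input files."""


@dataclass
class ExclusionReport:
    initial_n: int
    under_18: int
    single_recall: int
    energy_underreport: int
    missing_data: int
    final_n: int

    def __post_init__(self) -> None:
        removed = (self.under_18 + self.single_recall
                   + self.energy_underreport + self.missing_data)
        if self.final_n != self.initial_n - removed:
            raise ValueError("exclusion counts do not sum to the total removed")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    input_dir: str = ""
    output_dir: str = ""
    models: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5", "fig2")
    indices: tuple[str, ...] = ("pdi", "hpdi", "updi")
    continuous_outcomes: tuple[str, ...] = DEFAULT_CONTINUOUS_OUTCOMES
    binary_outcomes: tuple[str, ...] = DEFAULT_BINARY_OUTCOMES
    energy_cutoff_male_kj: float = ENERGY_CUTOFF_MALE_KJ
    energy_cutoff_female_kj: float = ENERGY_CUTOFF_FEMALE_KJ
    acr_threshold_male: float = 2.5
    acr_threshold_female: float = 3.5
    required_columns: tuple[str, ...] = DEFAULT_REQUIRED_COLUMNS
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(si.MODEL_LADDER)
        if unknown:
            raise ValidationError(f"unknown model ids {sorted(unknown)}")
        unknown = set(self.indices) - set(di.INDICES)
        if unknown:
            raise ValidationError(f"unknown indices {sorted(unknown)}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_table(cohort: SyntheticCohort):
    """Merge recalls, nutrients and biomarkers into one row per participant.

    Returns (table, matrices) where matrices maps participant_id to the
    two-day-average intake matrix (present only for participants with both
    recall days).
    """
    per_day = fc.intake_matrices_from_tables(cohort.recalls, cohort.composition)
    days_per_pid: dict[object, set[int]] = {}
    for pid, day in per_day:
        days_per_pid.setdefault(pid, set()).add(day)
    matrices = {
        pid: fc.average_days(per_day[(pid, 1)], per_day[(pid, 2)])
        for pid, days in days_per_pid.items()
        if days == {1, 2}
    }

    nmean = dn.mean_profile_frame(cohort.nutrients)
    nmean["pral"] = dn.pral_frame(nmean)
    nmean["protein_fibre_ratio"] = dn.protein_fibre_ratio_frame(nmean)

    bio = cohort.biomarkers.drop(columns=["sex"], errors="ignore")
    table = cohort.demographics.merge(nmean, on="participant_id", how="left")
    table = table.merge(bio, on="participant_id", how="left")

    have3 = table["sys3"].notna()
    table["systolic_bp"] = np.where(
        have3, (table["sys2"] + table["sys3"]) / 2.0, table["sys2"])
    table["diastolic_bp"] = np.where(
        have3, (table["dia2"] + table["dia3"]) / 2.0, table["dia2"])
    table["bmi"] = table["weight_kg"] / (table["height_cm"] / 100.0) ** 2
    table["n_recall_days"] = (
        table["participant_id"].map(lambda p: len(days_per_pid.get(p, ()))).astype(int)
    )
    return table, matrices


def apply_exclusions(
    table: pd.DataFrame,
    energy_cutoff_male_kj: float = ENERGY_CUTOFF_MALE_KJ,
    energy_cutoff_female_kj: float = ENERGY_CUTOFF_FEMALE_KJ,
    required_columns: tuple[str, ...] = DEFAULT_REQUIRED_COLUMNS,
):
    """Apply the four exclusion rules in order; returns (table, report)."""
    initial_n = len(table)
    alive = np.ones(initial_n, bool)

    r1 = alive & (table["age"].to_numpy(float) < 18.0)
    alive &= ~r1

    r2 = alive & (table["n_recall_days"].to_numpy(int) < 2)
    alive &= ~r2

    cutoff = np.where(
        table["sex"].to_numpy() == "male",
        energy_cutoff_male_kj, energy_cutoff_female_kj,
    )
    energy = table["energy_kj"].to_numpy(float)
    r3 = alive & np.isfinite(energy) & (energy < cutoff)
    alive &= ~r3

    present = [c for c in required_columns if c in table.columns]
    r4 = alive & table[present].isna().any(axis=1).to_numpy()
    alive &= ~r4

    report = ExclusionReport(
        initial_n=initial_n,
        under_18=int(r1.sum()),
        single_recall=int(r2.sum()),
        energy_underreport=int(r3.sum()),
        missing_data=int(r4.sum()),
        final_n=int(alive.sum()),
    )
    if report.final_n == 0:
        raise PipelineAbortError(f"no participants left after exclusions: {report}")
    return table.loc[alive].reset_index(drop=True), report


def score_analysis_sample(table, matrices, design: si.SurveyDesign):
    """Cutpoints on the weighted analysis sample, then index totals per row."""
    cube = np.stack([matrices[p].values for p in table["participant_id"]])
    return di.score_cohort(cube, design.weights,
                           participant_ids=table["participant_id"].to_numpy())


def classify_analysis_sample(table: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    bio = table.rename(columns={})[
        ["participant_id", "sex", "egfr", "acr", "hba1c",
         "height_cm", "weight_kg", "sys1", "dia1", "sys2", "dia2", "sys3", "dia3"]
    ]
    thr = {oc.Sex.MALE: cfg.acr_threshold_male, oc.Sex.FEMALE: cfg.acr_threshold_female}
    return oc.classify_frame(bio, thr)


def run_models(
    data: pd.DataFrame,
    design: si.SurveyDesign,
    indices: tuple[str, ...],
    models: tuple[str, ...],
    continuous_outcomes: tuple[str, ...],
    binary_outcomes: tuple[str, ...],
) -> pd.DataFrame:
    """Fit the ladder for every index; logistic outcomes use the fig2
    covariate set, continuous outcomes the M1-M5 sets. Rows with a missing
    outcome (e.g. non-fasted lipids) are dropped per outcome with the design
    subset accordingly."""
    results = []
    for index in indices:
        for model_id in models:
            outcomes = (
                binary_outcomes if model_id == "fig2" else continuous_outcomes
            )
            for outcome in outcomes:
                spec = si.ModelSpec.from_ladder(model_id, outcome, exposure=index)
                keep = data[outcome].notna().to_numpy()
                sub = data.loc[keep].reset_index(drop=True)
                res = si.fit_survey_glm(sub, spec, design.subset(keep))
                tab = res.table()
                tab.insert(0, "outcome", outcome)
                tab.insert(0, "index", index)
                tab.insert(0, "model_id", model_id)
                tab["n"] = res.n
                results.append(tab)
    return pd.concat(results, ignore_index=True)


def prepare_cohort(cohort: SyntheticCohort, cfg: RunConfig | None = None):
    """Assemble, exclude, score and classify a cohort in memory.

    Returns (data, design, report, scores, classified): ``data`` is the
    model-ready analysis table (one row per retained participant, diet-index
    totals and classified outcomes merged in) aligned with ``design``.
    """
    cfg = cfg or RunConfig()
    table, matrices = assemble_table(cohort)
    table, report = apply_exclusions(
        table, cfg.energy_cutoff_male_kj, cfg.energy_cutoff_female_kj,
        cfg.required_columns,
    )
    missing_matrix = [p for p in table["participant_id"] if p not in matrices]
    if missing_matrix:
        raise PipelineAbortError(
            f"participants without two-day intake matrices survived exclusions: "
            f"{missing_matrix[:5]}"
        )

    design_all = si.SurveyDesign.from_frame(cohort.design)
    keep = np.asarray(pd.Index(design_all.ids).isin(table["participant_id"]))
    design = design_all.subset(keep)

    scores = score_analysis_sample(table, matrices, design)
    classified = classify_analysis_sample(table, cfg)
    data = table.merge(scores, on="participant_id").merge(
        classified.drop(columns=["systolic_bp", "diastolic_bp", "bmi"]),
        on="participant_id",
    )
    return data, design, report, scores, classified


def recover_exposure_effect(
    cohort: SyntheticCohort,
    exposure: str = "updi",
    outcome: str = "moderate_severe",
    model_id: str = "fig2",
) -> pd.Series:
    """End-to-end effect estimation: decompose recalls, score the index,
    classify outcomes and fit the survey-weighted model; returns the fitted
    row for the exposure term (estimate, se, CI, p, odds ratio)."""
    data, design, _, _, _ = prepare_cohort(cohort)
    spec = si.ModelSpec.from_ladder(model_id, outcome, exposure=exposure)
    keep = data[outcome].notna().to_numpy()
    res = si.fit_survey_glm(
        data.loc[keep].reset_index(drop=True), spec, design.subset(keep)
    )
    return res.term(exposure)


def run_analysis(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline from a fixture directory and write results."""
    in_dir = Path(cfg.input_dir)
    if not in_dir.is_dir():
        raise ValidationError(f"input directory {in_dir} does not exist")
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = read_fixture(in_dir)
    data, design, report, scores, classified = prepare_cohort(cohort, cfg)

    results = run_models(
        data, design, cfg.indices, cfg.models,
        cfg.continuous_outcomes, cfg.binary_outcomes,
    )

    paths = {
        "exclusions": out_dir / "exclusion_report.json",
        "scores": out_dir / "scores.csv",
        "classifications": out_dir / "classifications.csv",
        "results": out_dir / "results.csv",
        "scoring_matrix": out_dir / "scoring_matrix.csv",
        "manifest": out_dir / "manifest.json",
    }
    paths["exclusions"].write_text(json.dumps(report.to_dict(), indent=2))
    scores.to_csv(paths["scores"], index=False)
    classified.to_csv(paths["classifications"], index=False)
    results.to_csv(paths["results"], index=False)
    di.scoring_matrix_to_frame(di.default_scoring_matrix()).to_csv(
        paths["scoring_matrix"], index=False
    )
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "final_n": report.final_n,
        "versions": {
            "plantdex": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return paths
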