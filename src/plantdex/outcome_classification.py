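"""Rule-based clinical classification: CKD staging, blood-pressure reading
selection, hypertension, diabetes-risk bands and BMI.

CKD follows the survey's eGFR/ACR staging logic: eGFR < 60 ml/min/1.73 m2 is
moderate-severe disease (stages 3-5) regardless of albuminuria; eGFR >= 60
with albuminuria is stage 1-2; otherwise no CKD. The albuminuria cut-off is
a sex-specific ACR threshold (defaults 2.5 mg/mmol men, 3.5 mg/mmol women),
configurable because national surveys vary in the exact flag definition.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class CkdStage(str, enum.Enum):
    NONE = "none"
    STAGE1_2 = "stage1_2"
    STAGE3_5 = "stage3_5"


class DiabetesRisk(str, enum.Enum):
    NORMAL = "normal"
    AT_RISK = "at_risk"
    DIABETES = "diabetes"


EGFR_MODERATE_SEVERE = 60.0  # ml/min/1.73 m2, strict "< 60"
ACR_THRESHOLDS = {Sex.MALE: 2.5, Sex.FEMALE: 3.5}  # mg/mmol
HYPERTENSION_SYS = 140.0  # mmHg, inclusive
HYPERTENSION_DIA = 90.0
HBA1C_AT_RISK = 6.0  # %
HBA1C_DIABETES = 6.5


class ClassificationMissingError(ValueError):
    """Raised when a biomarker required for classification is absent."""


class ProtocolError(ValueError):
    """Raised when measurements violate the collection protocol."""


@dataclass
class CkdStatus:
    status: CkdStage
    any_ckd: bool
    moderate_severe: bool

    def __post_init__(self) -> None:
        if self.moderate_severe and not self.any_ckd:
            raise ValueError("moderate_severe implies any_ckd")
        if (self.status is CkdStage.NONE) == self.any_ckd:
            raise ValueError("status none iff not any_ckd")


def classify_ckd(
    egfr: float,
    acr: float,
    sex: Sex,
    acr_thresholds: dict[Sex, float] = ACR_THRESHOLDS,
) -> CkdStatus:
    """Partition into none / stage1_2 / stage3_5 from eGFR and urinary ACR."""
    if egfr is None or acr is None or not np.isfinite(egfr) or not np.isfinite(acr):
        raise ClassificationMissingError("egfr and acr are required for CKD staging")
    if egfr < EGFR_MODERATE_SEVERE:
        return CkdStatus(CkdStage.STAGE3_5, True, True)
    if acr >= acr_thresholds[Sex(sex)]:
        return CkdStatus(CkdStage.STAGE1_2, True, False)
    return CkdStatus(CkdStage.NONE, False, False)


def select_bp(readings: list[tuple[float, float]]) -> tuple[float, float]:
    """Analysis blood pressure from 2-3 (systolic, diastolic) readings:
    with two readings the second is used; with three, the mean of the second
    and third. The first reading never enters the analysis value."""
    if len(readings) == 2:
        return tuple(map(float, readings[1]))
    if len(readings) == 3:
        (s2, d2), (s3, d3) = readings[1], readings[2]
        return ((s2 + s3) / 2.0, (d2 + d3) / 2.0)
    raise ProtocolError(f"expected 2 or 3 BP readings, got {len(readings)}")


def classify_hypertension(bp: tuple[float, float]) -> bool:
    """BP >= 140/90 mmHg (either component breaching its threshold)."""
    systolic, diastolic = bp
    return systolic >= HYPERTENSION_SYS or diastolic >= HYPERTENSION_DIA


def classify_diabetes_risk(hba1c: float) -> DiabetesRisk:
    """HbA1c bands: < 6 % normal, 6-6.4 % at risk, >= 6.5 % diabetes."""
    if not np.isfinite(hba1c) or hba1c <= 0:
        raise ClassificationMissingError(f"hba1c={hba1c!r} invalid")
    if hba1c < HBA1C_AT_RISK:
        return DiabetesRisk.NORMAL
    if hba1c < HBA1C_DIABETES:
        return DiabetesRisk.AT_RISK
    return DiabetesRisk.DIABETES


def bmi(height_cm: float, weight_kg: float) -> float:
    """Quetelet's index, kg/m2."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError(f"height {height_cm} cm / weight {weight_kg} kg must be > 0")
    return weight_kg / (height_cm / 100.0) ** 2


# ---------------------------------------------------------------------------
# Frame-level classification for the pipeline
# ---------------------------------------------------------------------------

def classify_frame(
    biomarkers: pd.DataFrame,
    acr_thresholds: dict[Sex, float] = ACR_THRESHOLDS,
) -> pd.DataFrame:
    """Classify every participant in a biomarker table.

    Expects columns: participant_id, sex, egfr, acr, hba1c, height_cm,
    weight_kg and BP readings sys1,dia1,sys2,dia2[,sys3,dia3] (third reading
    NaN when only two were taken). Returns one row per participant with
    ckd_status, any_ckd, moderate_severe, hypertension, diabetes_risk,
    diabetes, bmi and the selected systolic/diastolic pressures.
    """
    df = biomarkers
    sex = df["sex"].map(lambda s: Sex(s))
    thr = sex.map(acr_thresholds)

    if df[["egfr", "acr"]].isna().any().any():
        missing = df.loc[df[["egfr", "acr"]].isna().any(axis=1), "participant_id"]
        raise ClassificationMissingError(
            f"egfr/acr missing for participants {list(missing[:5])}"
        )
    stage3 = df["egfr"].to_numpy(float) < EGFR_MODERATE_SEVERE
    albu = df["acr"].to_numpy(float) >= thr.to_numpy(float)
    status = np.where(
        stage3, CkdStage.STAGE3_5.value,
        np.where(albu, CkdStage.STAGE1_2.value, CkdStage.NONE.value),
    )

    have3 = df["sys3"].notna().to_numpy() if "sys3" in df else np.zeros(len(df), bool)
    sys_sel = np.where(
        have3,
        (df["sys2"].to_numpy(float) + df.get("sys3", df["sys2"]).to_numpy(float)) / 2.0,
        df["sys2"].to_numpy(float),
    )
    dia_sel = np.where(
        have3,
        (df["dia2"].to_numpy(float) + df.get("dia3", df["dia2"]).to_numpy(float)) / 2.0,
        df["dia2"].to_numpy(float),
    )

    hba1c_v = df["hba1c"].to_numpy(float)
    risk = np.where(
        hba1c_v < HBA1C_AT_RISK, DiabetesRisk.NORMAL.value,
        np.where(hba1c_v < HBA1C_DIABETES, DiabetesRisk.AT_RISK.value,
                 DiabetesRisk.DIABETES.value),
    )

    return pd.DataFrame(
        {
            "participant_id": df["participant_id"].to_numpy(),
            "ckd_status": status,
            "any_ckd": stage3 | albu,
            "moderate_severe": stage3,
            "systolic_bp": sys_sel,
            "diastolic_bp": dia_sel,
            "hypertension": (sys_sel >= HYPERTENSION_SYS) | (dia_sel >= HYPERTENSION_DIA),
            "diabetes_risk": risk,
            "diabetes": hba1c_v >= HBA1C_DIABETES,
            "bmi": df["weight_kg"].to_numpy(float)
            / (df["height_cm"].to_numpy(float) / 100.0) ** 2,
        }
    )
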