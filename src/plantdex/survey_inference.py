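"""Complex-survey estimation with replicate weights.

Point estimates use the calibration weights; sampling variance uses a
delete-a-group jackknife: the statistic is recomputed under each of the R
replicate weight sets and

    var(theta_hat) = variance_factor * sum_r (theta_r - theta_hat)^2

with variance_factor = (R - 1) / R by default (the ABS convention for its
60-replicate scheme). 95 % confidence intervals are normal-approximation
(estimate +/- 1.96 se), and survey-weighted regression refits the whole model
under every replicate weight set.

The regression ladder mirrors the published covariate sets:

* M1: age, sex
* M2: age, sex, education, physical activity, smoking
* M3: M2 + BMI
* M4: M2 + energy, alcohol
* M5: M2 + BMI + energy, alcohol
* fig2 (CKD logistic): age, sex, energy, education, physical activity,
  smoking, diabetes, hypertension, BMI, alcohol
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

Z95 = 1.959963984540054  # standard-normal 97.5th percentile


class DesignError(ValueError):
    pass


class SeparationError(RuntimeError):
    """Perfect separation / non-convergence in the logistic fit."""


class CollinearityError(ValueError):
    """Rank-deficient design matrix."""


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined (e.g. constant outcome)."""


@dataclass
class SurveyDesign:
    """Calibration weight plus R replicate weight sets per participant."""

    ids: np.ndarray
    weights: np.ndarray
    rep_weights: np.ndarray  # shape (n, R)
    variance_factor: float | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.weights = np.asarray(self.weights, float)
        self.rep_weights = np.asarray(self.rep_weights, float)
        n = len(self.ids)
        if self.weights.shape != (n,):
            raise DesignError("weights not aligned with ids")
        if np.any(~np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise DesignError("calibration weights must be positive and finite")
        if self.rep_weights.ndim != 2 or self.rep_weights.shape[0] != n:
            raise DesignError("replicate weights must be (n, R)")
        if self.rep_weights.shape[1] < 2:
            raise DesignError("need at least 2 replicate weight sets")
        if np.any(~np.isfinite(self.rep_weights)) or np.any(self.rep_weights < 0):
            raise DesignError("replicate weights must be finite and >= 0")
        if self.variance_factor is None:
            r = self.rep_weights.shape[1]
            self.variance_factor = (r - 1) / r

    @property
    def n_replicates(self) -> int:
        return self.rep_weights.shape[1]

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        return SurveyDesign(
            self.ids[mask], self.weights[mask], self.rep_weights[mask],
            self.variance_factor,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, variance_factor: float | None = None):
        repcols = sorted(
            (c for c in df.columns if c.startswith("repwt_")),
            key=lambda c: int(c.split("_")[1]),
        )
        return cls(
            df["participant_id"].to_numpy(),
            df["weight"].to_numpy(float),
            df[repcols].to_numpy(float),
            variance_factor,
        )

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"participant_id": self.ids, "weight": self.weights})
        for r in range(self.n_replicates):
            out[f"repwt_{r + 1}"] = self.rep_weights[:, r]
        return out


def replicate_variance(stat_fn, design: SurveyDesign):
    """Generic replicate-rule variance of a weight -> statistic functional."""
    theta = np.asarray(stat_fn(design.weights), float)
    dev = np.zeros_like(theta)
    for r in range(design.n_replicates):
        theta_r = np.asarray(stat_fn(design.rep_weights[:, r]), float)
        dev = dev + (theta_r - theta) ** 2
    return theta, design.variance_factor * dev


def weighted_mean(values, design: SurveyDesign) -> tuple[float, float]:
    """Survey-weighted mean with a replicate-jackknife standard error."""
    x = np.asarray(values, float)
    if x.shape != design.weights.shape:
        raise DesignError("values not aligned with the design")
    if np.any(~np.isfinite(x)):
        raise DesignError("values must be finite")

    def stat(w):
        tw = w.sum()
        if tw <= 0:
            raise DesignError("all-zero weights")
        return (w * x).sum() / tw

    est, var = replicate_variance(stat, design)
    return float(est), float(np.sqrt(var))


# ---------------------------------------------------------------------------
# Model specifications
# ---------------------------------------------------------------------------

_M2 = ["age", "sex", "education", "physical_activity", "smoking"]
MODEL_LADDER: dict[str, list[str]] = {
    "M1": ["age", "sex"],
    "M2": list(_M2),
    "M3": _M2 + ["bmi"],
    "M4": _M2 + ["energy_kj", "alcohol"],
    "M5": _M2 + ["bmi", "energy_kj", "alcohol"],
    "fig2": [
        "age", "sex", "energy_kj", "education", "physical_activity",
        "smoking", "diabetes", "hypertension", "bmi", "alcohol",
    ],
}

#: outcomes modelled on the natural-log scale (non-normal distributions)
LOG_OUTCOMES = frozenset(
    {"hdl", "tag", "glucose", "hba1c", "systolic_bp", "waist_cm", "bmi"}
)

CATEGORICAL_COVARIATES = frozenset({"sex", "education", "physical_activity", "smoking"})


@dataclass
class ModelSpec:
    outcome: str
    family: str  # "linear" | "logistic"
    covariates: list[str]
    log_outcome: bool = False
    model_id: str | None = None
    exposure: str | None = None  # the diet-index term, first in the table

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.model_id is not None and self.model_id in MODEL_LADDER:
            if list(self.covariates) != MODEL_LADDER[self.model_id]:
                raise ValueError(
                    f"covariates for {self.model_id} must be "
                    f"{MODEL_LADDER[self.model_id]}"
                )

    @classmethod
    def from_ladder(cls, model_id: str, outcome: str, exposure: str,
                    family: str | None = None) -> "ModelSpec":
        covs = list(MODEL_LADDER[model_id])
        if outcome in ("bmi", "waist_cm") and "bmi" in covs:
            covs.remove("bmi")  # BMI/waist outcomes are not BMI-adjusted
        if family is None:
            family = "logistic" if outcome in ("any_ckd", "moderate_severe") else "linear"
        spec = cls(outcome, family, covs, outcome in LOG_OUTCOMES, None, exposure)
        spec.model_id = model_id
        return spec


@dataclass
class FitResult:
    terms: list[str]
    params: np.ndarray
    se: np.ndarray
    family: str
    n: int

    @property
    def ci95(self) -> np.ndarray:
        lo = self.params - Z95 * self.se
        hi = self.params + Z95 * self.se
        return np.column_stack([lo, hi])

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.params / self.se, np.inf)
        return 2 * stats.norm.sf(np.abs(z))

    @property
    def odds_ratios(self) -> np.ndarray | None:
        return np.exp(self.params) if self.family == "logistic" else None

    def table(self) -> pd.DataFrame:
        ci = self.ci95
        out = pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.params,
                "se": self.se,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "p": self.p_values,
            }
        )
        if self.family == "logistic":
            out["odds_ratio"] = np.exp(out["estimate"])
            out["or_low"] = np.exp(out["ci_low"])
            out["or_high"] = np.exp(out["ci_high"])
        return out

    def term(self, name: str) -> pd.Series:
        t = self.table()
        return t.set_index("term").loc[name]


# ---------------------------------------------------------------------------
# Design matrix and fitters
# ---------------------------------------------------------------------------

def build_design_matrix(df: pd.DataFrame, terms: list[str]):
    """Intercept + requested terms; string/categorical columns are expanded
    into drop-first dummy indicators, booleans become 0/1."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for t in terms:
        if t not in df.columns:
            raise KeyError(f"model term {t!r} not in the data")
        s = df[t]
        if s.isna().any():
            raise ValueError(f"model term {t!r} has missing values")
        if s.dtype == bool:
            cols.append(s.to_numpy(float))
            names.append(t)
        elif s.dtype.kind in "ifu":
            cols.append(s.to_numpy(float))
            names.append(t)
        else:
            levels = sorted(pd.unique(s.astype(str)))
            for lev in levels[1:]:
                cols.append((s.astype(str) == lev).to_numpy(float))
                names.append(f"{t}[{lev}]")
    X = np.column_stack(cols)
    return X, names


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    if rank < X.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    return beta

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, w: np.ndarray,
    names: list[str] | None = None, beta0: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted logistic ML via iteratively reweighted least squares.

    Convergence: relative deviance change < 1e-8, at most 100 iterations.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise CollinearityError("design matrix is rank deficient")
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    dev = np.inf
    for _ in range(IRLS_MAX_ITER):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        new_dev = -2.0 * np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        wls_w = w * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        sw = np.sqrt(wls_w)
        beta_new, _, _, _ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        if not np.all(np.isfinite(beta_new)):
            raise SeparationError("logistic fit diverged (non-finite coefficients)")
        beta = beta_new
        if new_dev / w.sum() <= 1e-6:  # perfect fit: the data are separated
            j = int(np.argmax(np.abs(beta[1:]))) + 1 if p > 1 else 0
            raise SeparationError(
                "perfect separation in the logistic fit on term "
                f"{names[j] if names else j!r}"
            )
        if abs(dev - new_dev) <= IRLS_TOL * (abs(new_dev) + 1e-12):
            return beta
        dev = new_dev
    # non-convergence: name the most extreme term as the likely separator
    j = int(np.argmax(np.abs(beta[1:]))) + 1 if p > 1 else 0
    term = names[j] if names else f"column {j}"
    raise SeparationError(
        f"logistic fit did not converge in {IRLS_MAX_ITER} iterations; "
        f"possible perfect separation on term {term!r}"
    )


def fit_survey_glm(df: pd.DataFrame, spec: ModelSpec, design: SurveyDesign) -> FitResult:
    """Survey-weighted linear (WLS) or logistic (IRLS) regression with
    replicate-jackknife standard errors from full refits under every
    replicate weight set."""
    if len(df) != len(design.ids):
        raise DesignError("data and design have different lengths")
    terms = ([spec.exposure] if spec.exposure else []) + list(spec.covariates)
    X, names = build_design_matrix(df, terms)
    y = df[spec.outcome]
    if y.isna().any():
        raise ValueError(f"outcome {spec.outcome!r} has missing values")
    y = y.to_numpy(float)
    if spec.log_outcome:
        if np.any(y <= 0):
            raise ValueError(f"log transform of non-positive outcome {spec.outcome!r}")
        y = np.log(y)
    if spec.family == "logistic" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("logistic outcome must be binary 0/1")

    if spec.family == "linear":
        fit = lambda w, b0=None: _wls(X, y, w)  # noqa: E731
    else:
        fit = lambda w, b0=None: _irls_logistic(X, y, w, names, b0)  # noqa: E731

    beta = fit(design.weights)
    dev = np.zeros_like(beta)
    for r in range(design.n_replicates):
        beta_r = fit(design.rep_weights[:, r], beta)
        dev += (beta_r - beta) ** 2
    se = np.sqrt(design.variance_factor * dev)
    return FitResult(names, beta, se, spec.family, len(df))


def trend_test(
    df: pd.DataFrame,
    outcome: str,
    quintile_col: str,
    design: SurveyDesign,
    covariates: list[str] | None = None,
    family: str = "linear",
    log_outcome: bool = False,
) -> float:
    """P value for a linear trend across quintiles: the total-score quintile
    enters the survey-weighted model as a numeric 1-5 term."""
    y = df[outcome].to_numpy(float)
    if np.all(y == y[0]):
        raise DegenerateTestError(f"outcome {outcome!r} is constant")
    work = df.copy()
    work["_trend"] = df[quintile_col].astype(float)
    spec = ModelSpec(outcome, family, list(covariates or []), log_outcome,
                     exposure="_trend")
    res = fit_survey_glm(work, spec, design)
    return float(res.term("_trend")["p"])


def categorical_test(
    var_a, var_b, design: SurveyDesign | None = None, correction: bool = True
):
    """Design-based Pearson chi-squared on the weighted contingency table.

    The Pearson statistic is computed on weighted cell proportions scaled to
    the unweighted sample size, then divided by a first-order design-effect
    correction: the mean replicate-estimated design effect of the cell
    proportions. With equal weights and degenerate replicates the correction
    is 1 and the statistic equals the textbook Pearson chi-squared.

    Returns (statistic, dof, p_value).
    """
    a = pd.Series(np.asarray(var_a)).astype(str)
    b = pd.Series(np.asarray(var_b)).astype(str)
    if a.nunique() < 2 or b.nunique() < 2:
        raise DegenerateTestError("both variables need >= 2 observed levels")
    n = len(a)
    w = design.weights if design is not None else np.ones(n)

    lev_a, ia = np.unique(a, return_inverse=True)
    lev_b, ib = np.unique(b, return_inverse=True)
    R, C = len(lev_a), len(lev_b)

    def cell_props(wvec):
        tab = np.zeros((R, C))
        np.add.at(tab, (ia, ib), wvec)
        return tab / wvec.sum()

    p_hat = cell_props(w)
    # collapse empty margins (possible only with zero weights in a level)
    keep_r = p_hat.sum(axis=1) > 0
    keep_c = p_hat.sum(axis=0) > 0
    p_hat = p_hat[np.ix_(keep_r, keep_c)]
    R, C = p_hat.shape
    if R < 2 or C < 2:
        raise DegenerateTestError("contingency table collapsed below 2x2")

    expected = np.outer(p_hat.sum(axis=1), p_hat.sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        x2 = n * np.nansum((p_hat - expected) ** 2 / expected)
    dof = (R - 1) * (C - 1)

    deff = 1.0
    if correction and design is not None:
        dev = np.zeros_like(p_hat)
        for r in range(design.n_replicates):
            pr = cell_props(design.rep_weights[:, r])[np.ix_(keep_r, keep_c)]
            dev += (pr - p_hat) ** 2
        v = design.variance_factor * dev
        srs = p_hat * (1 - p_hat) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            d_cells = np.where(srs > 0, v / srs, np.nan)
        d_bar = np.nanmean(d_cells)
        if np.isfinite(d_bar) and d_bar > 0:
            deff = d_bar

    stat = x2 / deff
    return float(stat), int(dof), float(stats.chi2.sf(stat, dof))
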