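"""Cohort-level statistics relating glycaemic biomarkers to covariates.

Spearman rank correlations (pairwise deletion of missing values, asymptotic
p-values), ordinary least squares regressions of each biomarker on BMI,
illness duration and total eating-disorder-inventory score (complete cases),
and a comparison of biomarkers across the DSM-5 BMI severity bands
(Kruskal–Wallis). No multiple-testing correction is applied; the significance
level convention is 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

BIOMARKERS = ("mean_glycaemia", "min_glycaemia", "cv", "hypo_auc")
PREDICTORS = ("bmi", "illness_duration", "edi2_total")

#: DSM-5 severity bands for anorexia nervosa by current BMI (kg/m²),
#: as half-open intervals partitioning BMI < 18.5.
DEFAULT_SEVERITY_BOUNDS: dict[str, tuple[float, float]] = {
    "extreme": (-np.inf, 15.0),
    "severe": (15.0, 16.0),
    "moderate": (16.0, 17.0),
    "mild": (17.0, 18.5),
}


class CollinearDesignError(ValueError):
    """Raised when the regression design matrix is rank-deficient."""


@dataclass
class CorrelationResult:
    x_name: str
    y_name: str
    rho: float
    p_value: float
    n: int
    note: str = ""

    @property
    def defined(self) -> bool:
        return not np.isnan(self.rho)


@dataclass
class RegressionFit:
    outcome: str
    coefficients: dict  # name -> {"beta", "se", "t", "p"}
    r_squared: float
    adj_r_squared: float
    model_p: float
    n: int


@dataclass
class CohortResults:
    """Bundle of every statistic the analysis stage produces."""

    correlations: list[CorrelationResult]
    regressions: list[RegressionFit]
    severity: dict
    n_subjects: int

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "correlations": [
                {
                    "x": c.x_name, "y": c.y_name, "rho": _jsonable(c.rho),
                    "p_value": _jsonable(c.p_value), "n": c.n, "note": c.note,
                }
                for c in self.correlations
            ],
            "regressions": [
                {
                    "outcome": r.outcome,
                    "coefficients": {
                        k: {kk: _jsonable(vv) for kk, vv in v.items()}
                        for k, v in r.coefficients.items()
                    },
                    "r_squared": _jsonable(r.r_squared),
                    "adj_r_squared": _jsonable(r.adj_r_squared),
                    "model_p": _jsonable(r.model_p),
                    "n": r.n,
                }
                for r in self.regressions
            ],
            "severity_groups": self.severity,
        }

    def correlation(self, x_name: str, y_name: str) -> CorrelationResult:
        for c in self.correlations:
            if c.x_name == x_name and c.y_name == y_name:
                return c
        raise KeyError((x_name, y_name))

    def correlations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"x": c.x_name, "y": c.y_name, "rho": c.rho,
                 "p_value": c.p_value, "n": c.n, "note": c.note}
                for c in self.correlations
            ]
        )


def _jsonable(x):
    if x is None:
        return None
    x = float(x)
    return None if np.isnan(x) else x


def spearman(x: Sequence[float], y: Sequence[float],
             x_name: str = "x", y_name: str = "y") -> CorrelationResult:
    """Spearman rank correlation with pairwise deletion.

    Uses midranks for ties and the asymptotic t approximation for the
    p-value. With fewer than 3 complete pairs the coefficient is reported
    without a p-value; zero variance in either vector yields an undefined
    result flagged in ``note``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 2:
        return CorrelationResult(x_name, y_name, np.nan, np.nan, n, "too few pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(x_name, y_name, np.nan, np.nan, n, "zero variance")
    rho, p = stats.spearmanr(x, y)
    if n < 3:
        return CorrelationResult(x_name, y_name, float(rho), np.nan, n,
                                 "p-value unavailable (n < 3)")
    return CorrelationResult(x_name, y_name, float(rho), float(p), n)


def fit_regression(table: pd.DataFrame, outcome: str,
                   predictors: Sequence[str] = PREDICTORS) -> RegressionFit:
    """OLS of one biomarker on the covariates, complete cases, with intercept.

    Reports per-coefficient beta, SE, t and two-sided p, plus R², adjusted R²
    and the overall F-test p-value. A rank-deficient design raises
    :class:`CollinearDesignError` naming the offending columns.
    """
    cols = [outcome, *predictors]
    data = table[cols].dropna()
    n = len(data)
    if n <= 5:
        raise ValueError(f"need more than 5 complete cases, found {n}")
    X = sm.add_constant(data[list(predictors)], has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        bad = [c for c in predictors
               if np.isclose(data[c].std(ddof=0), 0.0)
               or np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy())
               == np.linalg.matrix_rank(X.to_numpy())]
        raise CollinearDesignError(
            f"design matrix is rank-deficient (suspect columns: {bad or list(predictors)})"
        )
    fit = sm.OLS(data[outcome], X).fit()
    coefficients = {
        name: {
            "beta": float(fit.params[name]),
            "se": float(fit.bse[name]),
            "t": float(fit.tvalues[name]),
            "p": float(fit.pvalues[name]),
        }
        for name in X.columns
    }
    return RegressionFit(
        outcome=outcome,
        coefficients=coefficients,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        model_p=float(fit.f_pvalue),
        n=n,
    )


def assign_severity(bmi: float, bounds: dict | None = None) -> str | None:
    """DSM-5 severity band for a BMI, or None when BMI ≥ 18.5 or missing."""
    bounds = bounds or DEFAULT_SEVERITY_BOUNDS
    if np.isnan(bmi):
        return None
    for label, (lo, hi) in bounds.items():
        if lo <= bmi < hi:
            return label
    return None


def severity_group_compare(table: pd.DataFrame, biomarker: str,
                           bounds: dict | None = None) -> dict:
    """Biomarker summaries per BMI severity band plus a Kruskal–Wallis test.

    Returns per-group n, median and IQR; the test is reported only when at
    least two non-empty groups exist. Identical values everywhere give H = 0
    and p = 1.
    """
    bounds = bounds or DEFAULT_SEVERITY_BOUNDS
    data = table[["bmi", biomarker]].dropna()
    labels = data["bmi"].map(lambda b: assign_severity(b, bounds))
    groups = {}
    samples = []
    for label in bounds:
        values = data.loc[labels == label, biomarker].to_numpy()
        q1, med, q3 = (np.percentile(values, [25, 50, 75])
                       if values.size else (np.nan,) * 3)
        groups[label] = {
            "n": int(values.size),
            "median": _jsonable(med),
            "iqr": [_jsonable(q1), _jsonable(q3)],
        }
        if values.size:
            samples.append(values)
    if len(samples) < 2:
        test = {"available": False, "statistic": None, "p_value": None}
    else:
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            # identical values everywhere: no evidence of a group effect
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*samples)
        test = {"available": True, "statistic": float(h), "p_value": float(p)}
    return {"biomarker": biomarker, "groups": groups, "kruskal_wallis": test}


def run_full_analysis(table: pd.DataFrame,
                      nocturnal_table: pd.DataFrame | None = None,
                      severity_bounds: dict | None = None) -> CohortResults:
    """Run the complete statistical stage on the joined subject table.

    ``table`` holds one row per eligible subject with the four biomarkers and
    the covariates (bmi, illness_duration, edi2_total). Correlations of each
    biomarker with BMI and with illness duration are computed for the 24-h
    biomarkers and, when given, the nocturnal variants; all four biomarkers
    are regressed on the three covariates; the severity-band comparison uses
    mean glycaemia and hypoglycaemic AUC as outcomes.
    """
    correlations: list[CorrelationResult] = []
    for covariate in ("bmi", "illness_duration"):
        for biomarker in BIOMARKERS:
            correlations.append(
                spearman(table[covariate], table[biomarker],
                         covariate, biomarker)
            )
    if nocturnal_table is not None:
        for covariate in ("bmi", "illness_duration"):
            for biomarker in BIOMARKERS:
                correlations.append(
                    spearman(nocturnal_table[covariate],
                             nocturnal_table[biomarker],
                             covariate, f"nocturnal_{biomarker}")
                )
    regressions = []
    for biomarker in BIOMARKERS:
        try:
            regressions.append(fit_regression(table, biomarker))
        except ValueError:
            continue  # too few complete cases or degenerate design
    severity = {
        biomarker: severity_group_compare(table, biomarker, severity_bounds)
        for biomarker in BIOMARKERS
    }
    return CohortResults(
        correlations=correlations,
        regressions=regressions,
        severity=severity,
        n_subjects=len(table),
    )
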