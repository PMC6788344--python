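"""Covariate adjustment of the network's output probability.

A main-effects logistic model relates the binary group indicator to the
time between sessions (years), gender (0/1, reference level 0), baseline
age (years), and the network probability:

    logit E(Y) = b0 + b1*X1 + b2*X2 + b3*X3 + b4*X4

fit by maximum likelihood (IRLS/Newton via statsmodels), reporting each
coefficient with its Wald 95% confidence interval and two-sided p-value.
Complete or quasi-complete separation is detected (exploding coefficient
norm or a perfect-prediction condition) and reported as an error rather
than returning meaningless estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import InputError, SeparationError, TrainingError

__all__ = ["ConfounderRecord", "AdjustmentResult", "adjust", "records_from_frame"]

COEF_NAMES = ("beta0", "beta1_time", "beta2_gender", "beta3_age", "beta4_probability")
_SEPARATION_NORM = 50.0  # |coef| beyond this on standardized-scale data means divergence


@dataclass(frozen=True)
class ConfounderRecord:
    """One subject's outcome, covariates, and network probability."""

    Y: int
    X1_time_years: float
    X2_gender: int
    X3_age_years: float
    X4_probability: float

    def __post_init__(self) -> None:
        if self.Y not in (0, 1):
            raise InputError("Y must be binary 0/1")
        if self.X2_gender not in (0, 1):
            raise InputError("gender must be encoded 0/1")
        if not 0.0 <= self.X4_probability <= 1.0:
            raise InputError("network probability must lie in [0, 1]")


@dataclass(frozen=True)
class CoefficientEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise InputError("CI must bracket the estimate")


@dataclass
class AdjustmentResult:
    coefficients: dict[str, CoefficientEstimate]
    converged: bool
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "coefficient": name,
                    "estimate": c.estimate,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "p_value": c.p_value,
                }
                for name, c in self.coefficients.items()
            ]
        )


def records_from_frame(df: pd.DataFrame) -> list[ConfounderRecord]:
    """Build records from a table with columns Y, X1, X2, X3, X4 (or long names)."""
    alias = {
        "X1": "X1_time_years",
        "X2": "X2_gender",
        "X3": "X3_age_years",
        "X4": "X4_probability",
        "time_between_sessions_years": "X1_time_years",
        "gender": "X2_gender",
        "age": "X3_age_years",
        "probability": "X4_probability",
    }
    df = df.rename(columns=alias)
    return [
        ConfounderRecord(
            Y=int(r["Y"]),
            X1_time_years=float(r["X1_time_years"]),
            X2_gender=int(r["X2_gender"]),
            X3_age_years=float(r["X3_age_years"]),
            X4_probability=float(r["X4_probability"]),
        )
        for _, r in df.iterrows()
    ]


def adjust(records: list[ConfounderRecord]) -> AdjustmentResult:
    """Maximum-likelihood logistic fit with Wald 95% CIs and p-values."""
    if len(records) < 20:
        raise InputError("confounder adjustment needs at least 20 records")
    y = np.array([r.Y for r in records], dtype=float)
    if len(set(y)) < 2:
        raise TrainingError("both outcome classes must be present")
    X = np.column_stack(
        [
            [r.X1_time_years for r in records],
            [r.X2_gender for r in records],
            [r.X3_age_years for r in records],
            [r.X4_probability for r in records],
        ]
    )
    X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-10)
        except (PerfectSeparationError, PerfectSeparationWarning) as exc:
            raise SeparationError(f"separation detected in logistic fit: {exc}") from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
    scale = np.concatenate([[1.0], np.maximum(np.std(X[:, 1:], axis=0), 1e-12)])
    if np.any(np.abs(fit.params * scale) > _SEPARATION_NORM):
        raise SeparationError(
            "coefficient norm explosion indicates complete or quasi-complete separation"
        )
    conf = fit.conf_int(alpha=0.05)
    coefficients = {
        name: CoefficientEstimate(
            estimate=float(fit.params[i]),
            ci_low=float(conf[i, 0]),
            ci_high=float(conf[i, 1]),
            p_value=float(fit.pvalues[i]),
        )
        for i, name in enumerate(COEF_NAMES)
    }
    return AdjustmentResult(
        coefficients=coefficients,
        converged=bool(fit.mle_retvals.get("converged", True)),
        n=len(records),
    )
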