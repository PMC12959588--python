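"""Treatment-blinded multivariable logistic risk model.

The first stage of the risk-based heterogeneity analysis is a logistic
regression of the favorable outcome on the baseline covariates only — the
allocated treatment is deliberately excluded, so the model predicts each
patient's baseline probability of a favorable outcome regardless of arm
("treatment-blinded"). The model's linear predictor (log-odds scale) and
predicted probability drive every later stage: the interaction test, the
quantile risk strata and the stratum-level benefit estimates.

Continuous predictors enter linearly and untransformed; each categorical
predictor contributes one indicator per non-reference level, named
``"variable=Level"``. Fitting is maximum likelihood via iteratively
reweighted least squares (statsmodels GLM, binomial family, logit link),
with explicit separation detection: any coefficient exceeding 15 in absolute
value on the log-odds scale is treated as (quasi-)complete separation rather
than a usable estimate.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .errors import (
    ConvergenceError,
    DegenerateDesignError,
    SeparationError,
    UndefinedMetricError,
)
from .schema import TrialTable, VariableSchema

__all__ = [
    "build_design",
    "RiskModel",
    "RiskModelResults",
    "PerformanceMetrics",
    "fit_logistic",
    "c_statistic",
    "brier_score",
    "calibration",
]

logger = logging.getLogger(__name__)

#: |coefficient| beyond which a logistic fit is declared separated.
SEPARATION_BOUND = 15.0
#: Wald z for conventional 95% confidence intervals.
Z_95 = 1.959964


def build_design(table: TrialTable, schema: VariableSchema | None = None) -> pd.DataFrame:
    """Build the risk-model design matrix from a complete-case table.

    Columns: ``intercept``, one column per continuous predictor, one 0/1
    indicator per non-reference level of each categorical predictor (named
    ``"var=Level"``), in schema order. Treatment and outcome never appear.

    Raises
    ------
    DegenerateDesignError
        If a categorical predictor has a single observed level or a
        continuous predictor is constant.
    """
    schema = schema or table.schema
    df = table.data
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    for v in schema.predictors:
        col = df[v.name]
        if col.isna().any():
            raise DegenerateDesignError(
                f"predictor {v.name!r} has missing values; apply the "
                "complete-case filter first"
            )
        if v.kind == "continuous":
            vals = col.to_numpy(dtype=float)
            if len(df) > 1 and np.ptp(vals) == 0:
                raise DegenerateDesignError(f"continuous predictor {v.name!r} is constant")
            cols[v.name] = vals
        else:
            observed = set(col.unique())
            if len(observed) < 2:
                raise DegenerateDesignError(
                    f"categorical predictor {v.name!r} has a single observed "
                    f"level {sorted(map(str, observed))}"
                )
            for lv in v.nonreference_levels():
                cols[f"{v.name}={lv}"] = (col == lv).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def fit_logistic(
    design: pd.DataFrame,
    outcome: np.ndarray,
    tol: float = 1e-10,
    maxiter: int = 100,
) -> sm.GLM:
    """Maximum-likelihood Bernoulli-logit fit of `outcome` on `design`.

    Returns the fitted statsmodels GLM results object. Raises
    :class:`SeparationError` when a coefficient diverges beyond the
    separation bound and :class:`ConvergenceError` (carrying the last
    iterate) when IRLS does not converge within `maxiter`.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateDesignError("outcome has a single class; logistic fit undefined")
    if len(y) <= design.shape[1]:
        raise DegenerateDesignError(
            f"n rows ({len(y)}) must exceed number of terms ({design.shape[1]})"
        )
    model = sm.GLM(y, design, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation/convergence handled below
        res = model.fit(maxiter=maxiter, tol=tol)
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.abs(params).max() > SEPARATION_BOUND:
        raise SeparationError(
            "perfect or quasi-complete separation detected "
            f"(max |coefficient| = {np.nanmax(np.abs(params)):.3g})"
        )
    if not getattr(res, "converged", True):
        raise ConvergenceError(
            f"IRLS did not converge within {maxiter} iterations",
            last_params=dict(zip(design.columns, params)),
        )
    return res


@dataclass
class PerformanceMetrics:
    """Discrimination and calibration summary of a fitted risk model."""

    c_statistic: float
    brier_score: float
    calibration_intercept: float
    calibration_slope: float

    def to_dict(self) -> dict:
        return {
            "c_statistic": self.c_statistic,
            "brier_score": self.brier_score,
            "calibration_intercept": self.calibration_intercept,
            "calibration_slope": self.calibration_slope,
        }


class RiskModel:
    """Treatment-blinded logistic risk model for a binary trial outcome.

    Parameters
    ----------
    table : TrialTable
        Complete-case table (no missing predictor or outcome values).
    schema : VariableSchema, optional
        Defaults to the table's schema.

    Examples
    --------
    >>> results = RiskModel(table).fit()
    >>> results.odds_ratios()          # the machine twin of a model table
    >>> results.performance()          # c statistic, Brier, calibration
    """

    def __init__(self, table: TrialTable, schema: VariableSchema | None = None):
        self.table = table
        self.schema = schema or table.schema
        self.design = build_design(table, self.schema)
        y = table.outcome_array()
        if np.isnan(y).any():
            raise DegenerateDesignError(
                "outcome has missing values; apply the complete-case filter first"
            )
        self.outcome = y.astype(float)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, schema: VariableSchema) -> "RiskModel":
        return cls(TrialTable(data, schema), schema)

    def fit(self, tol: float = 1e-10, maxiter: int = 100) -> "RiskModelResults":
        res = fit_logistic(self.design, self.outcome, tol=tol, maxiter=maxiter)
        return RiskModelResults(self, res)


class RiskModelResults:
    """Results of a :class:`RiskModel` fit.

    Attributes
    ----------
    params : pandas.Series
        Log-odds coefficients per design term (``intercept`` first).
    bse : pandas.Series
        Standard errors (inverse observed information at the optimum).
    linear_predictor : numpy.ndarray
        Per-patient log-odds of a favorable outcome.
    predicted_probability : numpy.ndarray
        ``expit(linear_predictor)``, elementwise.
    """

    def __init__(self, model: RiskModel, glm_results):
        self.model = model
        self._res = glm_results
        self.params = pd.Series(
            np.asarray(glm_results.params, dtype=float), index=model.design.columns
        )
        self.bse = pd.Series(
            np.asarray(glm_results.bse, dtype=float), index=model.design.columns
        )
        self.cov_params = pd.DataFrame(
            np.asarray(glm_results.cov_params(), dtype=float),
            index=model.design.columns,
            columns=model.design.columns,
        )
        self.linear_predictor = model.design.to_numpy() @ self.params.to_numpy()
        self.predicted_probability = scipy.stats.logistic.cdf(self.linear_predictor)
        self.converged = bool(getattr(glm_results, "converged", True))
        self.n_used = len(model.outcome)
        self.llf = float(glm_results.llf)

    @property
    def terms(self) -> list[str]:
        return list(self.params.index)

    def score_vector(self) -> np.ndarray:
        """Gradient of the log-likelihood at the optimum, X'(y - p)."""
        resid = self.model.outcome - self.predicted_probability
        return self.model.design.to_numpy().T @ resid

    def odds_ratios(self) -> pd.DataFrame:
        """Per-term odds ratios with Wald 95% CIs and p-values."""
        coef = self.params
        se = self.bse
        z = coef / se
        p = 2 * scipy.stats.norm.sf(np.abs(z))
        df = pd.DataFrame(
            {
                "coefficient": coef,
                "se": se,
                "odds_ratio": np.exp(coef),
                "ci_low": np.exp(coef - Z_95 * se),
                "ci_high": np.exp(coef + Z_95 * se),
                "p_value": p,
            }
        )
        return df.drop(index="intercept")

    def performance(self) -> PerformanceMetrics:
        ci, cs = calibration(self.linear_predictor, self.model.outcome)
        return PerformanceMetrics(
            c_statistic=c_statistic(self.predicted_probability, self.model.outcome),
            brier_score=brier_score(self.predicted_probability, self.model.outcome),
            calibration_intercept=ci,
            calibration_slope=cs,
        )

    def condition_number(self) -> float:
        """Condition number of the (standardized) design; large values flag
        near-collinearity, e.g. total GCS entered alongside its components."""
        X = self.model.design.to_numpy()
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        return float(np.linalg.cond(X / scale))

    def summary(self) -> str:
        perf = self.performance()
        orr = self.odds_ratios()
        lines = [
            "Treatment-blinded logistic risk model",
            f"  n = {self.n_used}, terms = {len(self.terms)}, converged = {self.converged}",
            f"  c statistic = {perf.c_statistic:.2f}   Brier score = {perf.brier_score:.2f}",
            f"  calibration intercept = {perf.calibration_intercept:.3f}, "
            f"slope = {perf.calibration_slope:.3f}",
            "",
            f"  {'term':<28}{'OR':>8}{'95% CI':>18}{'p':>9}",
        ]
        for term, row in orr.iterrows():
            ci = f"({row.ci_low:.2f}, {row.ci_high:.2f})"
            lines.append(
                f"  {term:<28}{row.odds_ratio:>8.2f}{ci:>18}{row.p_value:>9.3g}"
            )
        cond = self.condition_number()
        if cond > 1e3:
            lines.append(f"  warning: design condition number {cond:.3g} (collinearity)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        orr = self.odds_ratios()
        return {
            "terms": self.terms,
            "coefficients": {t: float(v) for t, v in self.params.items()},
            "se": {t: float(v) for t, v in self.bse.items()},
            "odds_ratios": {
                t: {
                    "or": float(r.odds_ratio),
                    "ci_low": float(r.ci_low),
                    "ci_high": float(r.ci_high),
                    "p_value": float(r.p_value),
                }
                for t, r in orr.iterrows()
            },
            "performance": self.performance().to_dict(),
            "n_used": self.n_used,
            "converged": self.converged,
            "log_likelihood": self.llf,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


# ---------------------------------------------------------------------------
# performance metrics
# ---------------------------------------------------------------------------

def c_statistic(predicted: np.ndarray, outcome: np.ndarray) -> float:
    """Concordance (c) statistic / area under the ROC curve.

    The proportion of (favorable, unfavorable) patient pairs in which the
    favorable patient received the higher predicted probability, ties counted
    one half.
    """
    y = np.asarray(outcome, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("c statistic undefined: single-class outcome")
    return float(roc_auc_score(y, p))


def brier_score(predicted: np.ndarray, outcome: np.ndarray) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(predicted, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("predictions must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def calibration(linear_predictor: np.ndarray, outcome: np.ndarray) -> tuple[float, float]:
    """Calibration intercept and slope of predictions against outcomes.

    Slope: coefficient of the linear predictor in a logistic regression of
    the outcome on it. Intercept: intercept of a logistic regression with the
    linear predictor as a fixed offset. (1, 0) is perfect calibration;
    slope < 1 indicates overfitting/overdispersion of the predictions.
    """
    lp = np.asarray(linear_predictor, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if np.ptp(lp) == 0:
        raise DegenerateDesignError("constant linear predictor; calibration undefined")
    X = pd.DataFrame({"intercept": np.ones_like(lp), "lp": lp})
    slope = float(np.asarray(fit_logistic(X, y).params)[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        offset_fit = sm.GLM(
            y, X[["intercept"]], family=sm.families.Binomial(), offset=lp
        ).fit()
    intercept = float(np.asarray(offset_fit.params)[0])
    return intercept, slope
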