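"""Likelihood-ratio test for treatment-effect heterogeneity.

The presence of heterogeneity is assessed with a likelihood-ratio test of
the interaction between treatment and the risk model's linear predictor
(LP). Two nested logistic models are fit with the same engine as the risk
model itself:

    null:        logit P(Y=1) = b0 + b1*T + b2*LP
    alternative: logit P(Y=1) = b0 + b1*T + b2*LP + b3*(T x LP)

and the statistic is the drop in deviance, referred to a 1-df chi-square.
The LP is treated as a fixed, known covariate — its estimation uncertainty
is not propagated, matching the usual in-sample ("apparent") application of
the risk-modeling workflow. The test uses the full continuous LP, never the
binned risk groups; its result is invariant to affine rescaling of the LP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DegenerateDesignError
from .riskmodel import RiskModelResults, fit_logistic
from .schema import TrialTable

__all__ = ["InteractionTest", "lr_interaction_test"]


@dataclass
class InteractionTest:
    """Result of the treatment x linear-predictor likelihood-ratio test."""

    deviance_null: float
    deviance_alt: float
    lr_statistic: float
    df: int
    p_value: float
    interaction_coefficient: float
    interaction_se: float

    def __post_init__(self):
        assert self.lr_statistic >= -1e-8
        assert self.df == 1
        assert 0 < self.p_value <= 1

    def summary(self) -> str:
        return (
            "LR test for treatment x linear-predictor interaction: "
            f"chi2(1) = {self.lr_statistic:.2f}, p = {self.p_value:.4f} "
            f"(interaction coefficient {self.interaction_coefficient:+.3f} "
            f"+/- {self.interaction_se:.3f})"
        )

    def to_dict(self) -> dict:
        return {
            "deviance_null": self.deviance_null,
            "deviance_alt": self.deviance_alt,
            "lr_statistic": self.lr_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "interaction_coefficient": self.interaction_coefficient,
            "interaction_se": self.interaction_se,
        }


def lr_interaction_test(
    table: TrialTable, fit: RiskModelResults | np.ndarray
) -> InteractionTest:
    """Likelihood-ratio test of treatment x linear-predictor interaction.

    Parameters
    ----------
    table : TrialTable
        Complete-case table; supplies the treatment indicator and outcome.
    fit : RiskModelResults or array
        The fitted treatment-blinded risk model (its in-sample linear
        predictor is used), or a raw linear-predictor array aligned to the
        table rows.
    """
    lp = np.asarray(
        fit.linear_predictor if isinstance(fit, RiskModelResults) else fit, dtype=float
    )
    if len(lp) != table.n:
        raise ValueError(
            f"linear predictor length {len(lp)} does not match table rows {table.n}"
        )
    t = table.treatment_indicator().astype(float)
    y = table.outcome_array()
    if np.isnan(y).any():
        raise DegenerateDesignError("outcome has missing values")
    if t.min() == t.max():
        raise DegenerateDesignError("treatment is constant; interaction test undefined")
    if np.ptp(lp) == 0:
        raise DegenerateDesignError("linear predictor is constant; interaction test undefined")

    ones = np.ones_like(lp)
    X_null = pd.DataFrame({"intercept": ones, "treatment": t, "lp": lp})
    X_alt = X_null.assign(**{"treatment:lp": t * lp})

    res_null = fit_logistic(X_null, y)
    res_alt = fit_logistic(X_alt, y)
    dev_null = -2.0 * float(res_null.llf)
    dev_alt = -2.0 * float(res_alt.llf)
    lr = max(dev_null - dev_alt, 0.0)
    return InteractionTest(
        deviance_null=dev_null,
        deviance_alt=dev_alt,
        lr_statistic=lr,
        df=1,
        p_value=max(float(scipy.stats.chi2.sf(lr, df=1)), 5e-324) if lr > 0 else 1.0,
        interaction_coefficient=float(np.asarray(res_alt.params)[3]),
        interaction_se=float(np.asarray(res_alt.bse)[3]),
    )
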