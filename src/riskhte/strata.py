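"""Quantile risk strata and absolute-risk-difference treatment benefit.

After the risk model is fit, patients are binned into quantile-based risk
groups (quartiles Q1-Q4 by default, Q1 = lowest predicted probability of a
favorable outcome) and the treatment benefit is estimated on the absolute
risk difference (RD) scale: overall, per risk stratum, and per traditional
one-variable-at-a-time subgroup (e.g. sex, or age dichotomized at 80
years). RDs are empirical (count-based) with unpooled-variance Wald 95%
confidence intervals; the overall estimate also carries a two-sided
pooled-variance two-proportion z-test p-value.

Binning is presentation only — the heterogeneity *test* uses the full
continuous linear predictor (see :mod:`riskhte.interaction`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import (
    ArgumentError,
    DegenerateStrataError,
    StratificationError,
    UndefinedEstimateError,
)
from .schema import TrialTable

__all__ = [
    "RiskStrata",
    "EffectEstimate",
    "SubgroupDefinition",
    "quantile_bins",
    "risk_difference",
    "stratified_effects",
    "subgroup_distributions",
    "DistributionSummary",
    "overlap_coefficient",
]

Z_95 = 1.959964
#: Shared evaluation grid for probability densities on [0, 1].
DENSITY_GRID = np.linspace(0.0, 1.0, 201)


@dataclass
class RiskStrata:
    """Quantile-based risk groups.

    ``edges`` are the n_bins + 1 predicted-probability cut points (empirical
    quantiles, linear-interpolation definition); ``assignments`` maps each
    patient to a stratum index 0..n_bins-1 (label ``Q1``..``Qk``); a patient
    falls in the lowest stratum whose half-open interval ``[low, high)``
    contains its probability, with the top interval closed.
    """

    n_bins: int
    edges: np.ndarray
    assignments: np.ndarray
    labels: list[str] = field(init=False)

    def __post_init__(self):
        self.labels = [f"Q{i + 1}" for i in range(self.n_bins)]
        sizes = np.bincount(self.assignments, minlength=self.n_bins)
        assert sizes.sum() == len(self.assignments)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_bins)

    def label_series(self) -> pd.Series:
        return pd.Series(pd.Categorical.from_codes(self.assignments, self.labels))

    def to_dict(self) -> dict:
        return {
            "n_bins": self.n_bins,
            "edges": [float(e) for e in self.edges],
            "labels": self.labels,
            "sizes": [int(s) for s in self.sizes],
        }


def quantile_bins(probabilities: np.ndarray, n_bins: int = 4) -> RiskStrata:
    """Bin predicted probabilities into quantile-based risk groups.

    Raises
    ------
    StratificationError
        If there are fewer observations than bins.
    DegenerateStrataError
        If more than half the probabilities are tied at a single value.
    """
    p = np.asarray(probabilities, dtype=float)
    if n_bins < 1:
        raise ArgumentError("n_bins must be >= 1")
    if len(p) < n_bins:
        raise StratificationError(
            f"cannot form {n_bins} strata from {len(p)} observations"
        )
    if np.any(~np.isfinite(p)) or p.min() <= 0 or p.max() >= 1:
        raise ArgumentError("probabilities must lie strictly inside (0, 1)")
    _, counts = np.unique(p, return_counts=True)
    if counts.max() > 0.5 * len(p):
        raise DegenerateStrataError(
            f"{counts.max()} of {len(p)} probabilities tied at one value; "
            "quantile strata would be degenerate"
        )
    edges = np.quantile(p, np.linspace(0.0, 1.0, n_bins + 1))
    if n_bins > 1 and np.any(np.diff(edges) <= 0):
        raise DegenerateStrataError(
            f"non-increasing quantile edges {edges.round(4).tolist()}; "
            "ties collapse adjacent strata"
        )
    assignments = np.searchsorted(edges[1:-1], p, side="right")
    return RiskStrata(n_bins=n_bins, edges=edges, assignments=assignments)


@dataclass
class EffectEstimate:
    """Absolute-risk-difference treatment effect for one scope.

    ``scope`` is ``"overall"``, a stratum label (``"Q1"``...) or a subgroup
    label. ``defined`` is False when an arm was empty (the estimate is
    flagged rather than failing the pipeline). ``mean_predicted`` is the
    group's mean predicted probability of a favorable outcome (the
    x-coordinate of a benefit-versus-baseline-risk plot), when available.
    """

    scope: str
    n_treated: int
    events_treated: int
    n_control: int
    events_control: int
    risk_treated: float
    risk_control: float
    risk_difference: float
    ci_low: float
    ci_high: float
    p_value: float | None = None
    mean_predicted: float | None = None
    defined: bool = True

    def __post_init__(self):
        if self.defined:
            assert -1.0 <= self.risk_difference <= 1.0
            assert self.ci_low <= self.risk_difference <= self.ci_high

    def to_dict(self) -> dict:
        d = {
            "scope": self.scope,
            "n_treated": self.n_treated,
            "events_treated": self.events_treated,
            "n_control": self.n_control,
            "events_control": self.events_control,
            "risk_treated": self.risk_treated,
            "risk_control": self.risk_control,
            "risk_difference": self.risk_difference,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "defined": self.defined,
        }
        if self.p_value is not None:
            d["p_value"] = self.p_value
        if self.mean_predicted is not None:
            d["mean_predicted"] = self.mean_predicted
        return d


def risk_difference(
    n_treated: int,
    events_treated: int,
    n_control: int,
    events_control: int,
    scope: str = "overall",
    include_p: bool = True,
) -> EffectEstimate:
    """Absolute risk difference with Wald 95% CI and two-proportion z test.

    RD = e_t/n_t - e_c/n_c. The CI uses the unpooled-variance Wald formula
    RD +/- 1.959964 * sqrt(p_t(1-p_t)/n_t + p_c(1-p_c)/n_c); the p-value the
    pooled-variance z statistic, no continuity correction.
    """
    for label, n, e in (("treated", n_treated, events_treated), ("control", n_control, events_control)):
        if n < 0 or e < 0 or e > n:
            raise ArgumentError(f"invalid {label} counts: {e} events of {n}")
    if n_treated == 0 or n_control == 0:
        raise UndefinedEstimateError(
            f"risk difference undefined for {scope!r}: an arm is empty"
        )
    p_t = events_treated / n_treated
    p_c = events_control / n_control
    rd = p_t - p_c
    se = np.sqrt(p_t * (1 - p_t) / n_treated + p_c * (1 - p_c) / n_control)
    p_value = None
    if include_p:
        pooled = (events_treated + events_control) / (n_treated + n_control)
        se_pooled = np.sqrt(pooled * (1 - pooled) * (1 / n_treated + 1 / n_control))
        if se_pooled == 0:
            p_value = 1.0
        else:
            z = rd / se_pooled
            p_value = float(2 * scipy.stats.norm.sf(abs(z)))
    return EffectEstimate(
        scope=scope,
        n_treated=n_treated,
        events_treated=events_treated,
        n_control=n_control,
        events_control=events_control,
        risk_treated=p_t,
        risk_control=p_c,
        risk_difference=rd,
        ci_low=rd - Z_95 * se,
        ci_high=rd + Z_95 * se,
        p_value=p_value,
    )


def _undefined_estimate(scope, n_t, e_t, n_c, e_c, mean_predicted) -> EffectEstimate:
    return EffectEstimate(
        scope=scope,
        n_treated=n_t,
        events_treated=e_t,
        n_control=n_c,
        events_control=e_c,
        risk_treated=e_t / n_t if n_t else float("nan"),
        risk_control=e_c / n_c if n_c else float("nan"),
        risk_difference=float("nan"),
        ci_low=float("nan"),
        ci_high=float("nan"),
        mean_predicted=mean_predicted,
        defined=False,
    )


def stratified_effects(
    table: TrialTable,
    labels,
    predicted: np.ndarray | None = None,
) -> list[EffectEstimate]:
    """Per-group absolute risk differences from within-group counts.

    Parameters
    ----------
    table : TrialTable
        Complete-case table (treatment and outcome fully observed).
    labels : RiskStrata or sequence
        Risk strata, or a length-n sequence of group labels (traditional
        subgroups). Group order: stratum order for RiskStrata, first
        appearance otherwise.
    predicted : array, optional
        Predicted probabilities; when given, each estimate records the
        group's mean predicted probability.

    A group with an empty arm yields a flagged (``defined=False``) estimate
    rather than an error.
    """
    if isinstance(labels, RiskStrata):
        series = labels.label_series().to_numpy()
        order = list(labels.labels)
    else:
        series = np.asarray(labels)
        if len(series) != table.n:
            raise ArgumentError("labels length does not match table rows")
        order = list(dict.fromkeys(series.tolist()))
    t = table.treatment_indicator()
    y = table.outcome_array()
    if np.isnan(y).any():
        raise ArgumentError("outcome has missing values; filter first")
    pred = None if predicted is None else np.asarray(predicted, dtype=float)

    out: list[EffectEstimate] = []
    for g in order:
        m = series == g
        n_t = int((m & (t == 1)).sum())
        n_c = int((m & (t == 0)).sum())
        e_t = int(y[m & (t == 1)].sum())
        e_c = int(y[m & (t == 0)].sum())
        mp = float(pred[m].mean()) if pred is not None and m.any() else None
        if n_t == 0 or n_c == 0:
            out.append(_undefined_estimate(str(g), n_t, e_t, n_c, e_c, mp))
            continue
        est = risk_difference(n_t, e_t, n_c, e_c, scope=str(g), include_p=False)
        est.mean_predicted = mp
        out.append(est)
    return out


@dataclass(frozen=True)
class SubgroupDefinition:
    """A traditional one-variable-at-a-time subgroup split.

    For a categorical variable each level is a subgroup; for a continuous
    variable patients are split at ``threshold`` into ``"<threshold>"`` and
    ``">=threshold"`` groups. Every complete-case patient lands in exactly
    one group.
    """

    variable: str
    threshold: float | None = None
    label: str | None = None

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        if self.threshold is not None:
            return f"{self.variable}@{self.threshold:g}"
        return self.variable

    def assign(self, table: TrialTable) -> np.ndarray:
        if self.variable not in table.schema:
            raise ArgumentError(f"unknown subgroup variable {self.variable!r}")
        var = table.schema[self.variable]
        col = table.data[self.variable]
        if col.isna().any():
            raise ArgumentError(
                f"subgroup variable {self.variable!r} has missing values; filter first"
            )
        if var.kind == "continuous":
            if self.threshold is None:
                raise ArgumentError(
                    f"continuous subgroup variable {self.variable!r} needs a threshold"
                )
            vals = col.to_numpy(dtype=float)
            lo = f"{self.variable}<{self.threshold:g}"
            hi = f"{self.variable}>={self.threshold:g}"
            return np.where(vals < self.threshold, lo, hi)
        return np.array([f"{self.variable}={v}" for v in col], dtype=object)


# ---------------------------------------------------------------------------
# probability-distribution summaries (ridgeline-figure data)
# ---------------------------------------------------------------------------

@dataclass
class DistributionSummary:
    """Summary of one group's predicted-probability distribution."""

    group: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    grid: np.ndarray
    density: np.ndarray | None
    values: np.ndarray

    def to_dict(self, include_grid: bool = True) -> dict:
        d = {
            "group": self.group,
            "n": self.n,
            "mean": self.mean,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
        }
        if include_grid:
            d["grid"] = [float(x) for x in self.grid]
            d["density"] = (
                None if self.density is None else [float(x) for x in self.density]
            )
        return d


def _kde_on_grid(values: np.ndarray) -> np.ndarray | None:
    if len(values) < 2 or np.ptp(values) == 0:
        return None
    dens = scipy.stats.gaussian_kde(values)(DENSITY_GRID)
    mass = np.trapezoid(dens, DENSITY_GRID)
    return dens / mass if mass > 0 else None  # renormalize after [0,1] truncation


def subgroup_distributions(
    probabilities: np.ndarray, grouping
) -> tuple[dict[str, DistributionSummary], pd.DataFrame]:
    """Per-group predicted-probability distributions and pairwise overlap.

    Returns the per-group summaries (mean, median, quartiles, Gaussian-kernel
    density on a fixed grid over [0, 1]) and a symmetric matrix of pairwise
    overlap coefficients — the integral of the pointwise minimum of two
    normalized densities, 1 for identical distributions, near 0 for disjoint
    ones. The overlap quantifies how little traditional one-variable
    subgroups separate patients by baseline risk, compared with risk-based
    strata.

    Groups with fewer than 2 members keep their summary but omit the density.
    """
    p = np.asarray(probabilities, dtype=float)
    if isinstance(grouping, RiskStrata):
        series = grouping.label_series().to_numpy()
        order = list(grouping.labels)
    else:
        series = np.asarray(grouping)
        order = list(dict.fromkeys(series.tolist()))
    if len(series) != len(p):
        raise ArgumentError("grouping length does not match probabilities")

    summaries: dict[str, DistributionSummary] = {}
    for g in order:
        vals = p[series == g]
        q1, med, q3 = np.percentile(vals, [25, 50, 75]) if len(vals) else (np.nan,) * 3
        summaries[str(g)] = DistributionSummary(
            group=str(g),
            n=len(vals),
            mean=float(vals.mean()) if len(vals) else float("nan"),
            median=float(med),
            q1=float(q1),
            q3=float(q3),
            grid=DENSITY_GRID,
            density=_kde_on_grid(vals),
            values=vals,
        )
    names = list(summaries)
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            da, db = summaries[a].density, summaries[b].density
            ovl = float("nan") if da is None or db is None else overlap_coefficient(da, db)
            mat.loc[a, b] = mat.loc[b, a] = ovl
    return summaries, mat


def overlap_coefficient(density_a: np.ndarray, density_b: np.ndarray) -> float:
    """Integral of the pointwise minimum of two densities on the shared grid."""
    return float(
        np.trapezoid(np.minimum(density_a, density_b), DENSITY_GRID)
    )
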