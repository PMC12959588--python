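"""End-to-end risk-based heterogeneity analysis.

:class:`HTEAnalysis` is the top-level model object. Built from a patient
table, its :meth:`~HTEAnalysis.fit` runs the four-step risk-modeling
workflow in order —

1. complete-case filter on the analysis variables,
2. treatment-blinded multivariable logistic risk model,
3. likelihood-ratio test of the treatment x linear-predictor interaction,
4. quantile risk strata and absolute-risk-difference benefit estimates
   (overall, per stratum, per traditional subgroup) —

and returns an :class:`HTEResults` carrying every intermediate product, a
human-readable :meth:`~HTEResults.summary` and machine-readable report
writers. :func:`run_operating_characteristics` wraps repeated synthetic
runs into type-I-error / power / CI-coverage summaries for the interaction
test and the stratum estimates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import __version__
from .errors import ArgumentError, ConfigurationError
from .interaction import InteractionTest, lr_interaction_test
from .io import CompleteCaseReport, complete_case_filter, read_trial_csv
from .riskmodel import RiskModel, RiskModelResults
from .schema import TrialTable, VariableSchema
from .strata import (
    EffectEstimate,
    RiskStrata,
    SubgroupDefinition,
    quantile_bins,
    risk_difference,
    stratified_effects,
    subgroup_distributions,
)
from .synthetic import SyntheticTrialConfig, generate_trial

__all__ = [
    "AnalysisConfig",
    "HTEAnalysis",
    "HTEResults",
    "run_analysis",
    "run_operating_characteristics",
    "default_subgroups",
]

logger = logging.getLogger(__name__)


def default_subgroups() -> list[SubgroupDefinition]:
    """Traditional one-variable comparison subgroups: age (split at 80 years,
    a configurable convention near the cohort median) and sex."""
    return [SubgroupDefinition("age", threshold=80.0), SubgroupDefinition("sex")]


@dataclass
class AnalysisConfig:
    """Configuration of one end-to-end analysis run."""

    input_path: str | None = None
    schema_path: str | None = None
    mapping_path: str | None = None
    synthetic: SyntheticTrialConfig | None = None
    n_bins: int = 4
    subgroups: list[SubgroupDefinition] = field(default_factory=default_subgroups)
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if self.n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")
        if (self.input_path is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one of input_path or synthetic must be given"
            )

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "schema_path": self.schema_path,
            "mapping_path": self.mapping_path,
            "synthetic": None if self.synthetic is None else self.synthetic.to_dict(),
            "n_bins": self.n_bins,
            "subgroups": [
                {"variable": s.variable, "threshold": s.threshold, "label": s.label}
                for s in self.subgroups
            ],
            "seed": self.seed,
        }

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class HTEAnalysis:
    """Risk-based heterogeneous-treatment-effect analysis of one trial.

    Parameters
    ----------
    table : TrialTable
        Patient-level table (may contain missing covariate/outcome values;
        the complete-case filter is applied at fit time).
    n_bins : int
        Number of quantile risk groups (4 = quartiles).
    subgroups : list of SubgroupDefinition, optional
        Traditional subgroups to contrast with the risk strata.

    Examples
    --------
    >>> from riskhte import default_ist3_config, generate_trial, HTEAnalysis
    >>> table = generate_trial(default_ist3_config(seed=7))
    >>> results = HTEAnalysis(table).fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        table: TrialTable,
        n_bins: int = 4,
        subgroups: list[SubgroupDefinition] | None = None,
    ):
        if n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")
        self.table = table
        self.n_bins = n_bins
        self.subgroups = default_subgroups() if subgroups is None else subgroups

    @classmethod
    def from_csv(
        cls,
        path,
        schema: VariableSchema,
        mapping: dict[str, str] | None = None,
        **kwargs,
    ) -> "HTEAnalysis":
        return cls(read_trial_csv(path, schema, mapping=mapping), **kwargs)

    def fit(self) -> "HTEResults":
        logger.info("stage complete_case: %d rows in", self.table.n)
        cc_table, cc_report = complete_case_filter(self.table)
        logger.info("stage complete_case: %d rows retained", cc_table.n)

        logger.info("stage risk_model: fitting on %d rows", cc_table.n)
        risk = RiskModel(cc_table).fit()
        logger.info("stage interaction: LR test")
        interaction = lr_interaction_test(cc_table, risk)

        logger.info("stage strata: %d quantile bins", self.n_bins)
        strata = quantile_bins(risk.predicted_probability, self.n_bins)

        t = cc_table.treatment_indicator()
        y = cc_table.outcome_array().astype(int)
        overall = risk_difference(
            int(t.sum()), int(y[t == 1].sum()), int((t == 0).sum()), int(y[t == 0].sum())
        )
        overall.mean_predicted = float(risk.predicted_probability.mean())
        stratum_effects = stratified_effects(
            cc_table, strata, predicted=risk.predicted_probability
        )
        subgroup_effects: dict[str, list[EffectEstimate]] = {}
        subgroup_dists: dict[str, dict] = {}
        groupings: dict[str, np.ndarray] = {}
        for sg in self.subgroups:
            labels = sg.assign(cc_table)
            groupings[sg.name] = labels
            subgroup_effects[sg.name] = stratified_effects(
                cc_table, labels, predicted=risk.predicted_probability
            )
        strata_dists, strata_overlap = subgroup_distributions(
            risk.predicted_probability, strata
        )
        for name, labels in groupings.items():
            dists, overlap = subgroup_distributions(risk.predicted_probability, labels)
            subgroup_dists[name] = {"distributions": dists, "overlap": overlap}
        logger.info("stage effects: overall RD %.4f", overall.risk_difference)

        return HTEResults(
            model=self,
            complete_case=cc_report,
            cc_table=cc_table,
            risk=risk,
            interaction=interaction,
            strata=strata,
            overall_effect=overall,
            stratum_effects=stratum_effects,
            subgroup_effects=subgroup_effects,
            strata_distributions=strata_dists,
            strata_overlap=strata_overlap,
            subgroup_distributions=subgroup_dists,
        )


class HTEResults:
    """Fitted results of an :class:`HTEAnalysis`."""

    def __init__(
        self,
        model: HTEAnalysis,
        complete_case: CompleteCaseReport,
        cc_table: TrialTable,
        risk: RiskModelResults,
        interaction: InteractionTest,
        strata: RiskStrata,
        overall_effect: EffectEstimate,
        stratum_effects: list[EffectEstimate],
        subgroup_effects: dict[str, list[EffectEstimate]],
        strata_distributions: dict,
        strata_overlap: pd.DataFrame,
        subgroup_distributions: dict,
    ):
        self.model = model
        self.complete_case = complete_case
        self.cc_table = cc_table
        self.risk = risk
        self.interaction = interaction
        self.strata = strata
        self.overall_effect = overall_effect
        self.stratum_effects = stratum_effects
        self.subgroup_effects = subgroup_effects
        self.strata_distributions = strata_distributions
        self.strata_overlap = strata_overlap
        self.subgroup_distributions = subgroup_distributions

    # -- model-based benefit curve ----------------------------------------
    def model_based_rd(self, lp: np.ndarray) -> np.ndarray:
        """Risk difference predicted by the interaction model at given LPs.

        Complements the empirical (count-based) stratum RDs: this is the
        smooth curve implied by the treatment + LP + interaction logistic
        model.
        """
        t = self.cc_table.treatment_indicator().astype(float)
        y = self.cc_table.outcome_array()
        from .riskmodel import fit_logistic

        lp_fit = np.asarray(self.risk.linear_predictor, dtype=float)
        X = pd.DataFrame(
            {
                "intercept": np.ones_like(lp_fit),
                "treatment": t,
                "lp": lp_fit,
                "treatment:lp": t * lp_fit,
            }
        )
        b = np.asarray(fit_logistic(X, y).params, dtype=float)
        p1 = expit(b[0] + b[1] + (b[2] + b[3]) * lp)
        p0 = expit(b[0] + b[2] * lp)
        return p1 - p0

    # -- tables ------------------------------------------------------------
    def stratum_table(self) -> pd.DataFrame:
        """Per-stratum summary: edges, arm counts/events, RD with 95% CI."""
        rows = []
        for i, est in enumerate(self.stratum_effects):
            rows.append(
                {
                    "stratum": est.scope,
                    "edge_low": float(self.strata.edges[i]),
                    "edge_high": float(self.strata.edges[i + 1]),
                    "n_treated": est.n_treated,
                    "events_treated": est.events_treated,
                    "n_control": est.n_control,
                    "events_control": est.events_control,
                    "mean_predicted": est.mean_predicted,
                    "risk_difference": est.risk_difference,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cc = self.complete_case
        ov = self.overall_effect
        lines = [
            "Risk-based heterogeneous-treatment-effect analysis",
            "=" * 52,
            f"Complete cases: {cc.n_retained} of {cc.n_input} "
            f"({cc.n_dropped} dropped)",
            "",
            self.risk.summary(),
            "",
            self.interaction.summary(),
            "",
            f"Overall risk difference: {100 * ov.risk_difference:.1f}% "
            f"(95% CI {100 * ov.ci_low:.1f} to {100 * ov.ci_high:.1f}; "
            f"P = {ov.p_value:.2f})",
            "",
            "Quantile risk strata (absolute risk difference, treated - control):",
            f"  {'stratum':<9}{'n':>6}{'mean p':>9}{'RD %':>8}{'95% CI':>20}",
        ]
        for est in self.stratum_effects:
            n = est.n_treated + est.n_control
            if est.defined:
                ci = f"({100 * est.ci_low:.1f}, {100 * est.ci_high:.1f})"
                lines.append(
                    f"  {est.scope:<9}{n:>6}{est.mean_predicted:>9.3f}"
                    f"{100 * est.risk_difference:>8.1f}{ci:>20}"
                )
            else:
                lines.append(f"  {est.scope:<9}{n:>6}  (undefined: empty arm)")
        for name, effects in self.subgroup_effects.items():
            lines.append("")
            lines.append(f"Traditional subgroup: {name}")
            for est in effects:
                n = est.n_treated + est.n_control
                if est.defined:
                    ci = f"({100 * est.ci_low:.1f}, {100 * est.ci_high:.1f})"
                    lines.append(
                        f"  {est.scope:<22}{n:>6}{est.mean_predicted:>9.3f}"
                        f"{100 * est.risk_difference:>8.1f}{ci:>20}"
                    )
                else:
                    lines.append(f"  {est.scope:<22}{n:>6}  (undefined: empty arm)")
        return "\n".join(lines)

    # -- reports -----------------------------------------------------------
    def to_dict(self, config: AnalysisConfig | None = None) -> dict:
        report = {
            "provenance": {
                "version": __version__,
                "timestamp": datetime.now(timezone.utc).isoformat(),
                "config_hash": config.content_hash() if config else None,
                "seed": config.seed if config else None,
            },
            "complete_case": self.complete_case.to_dict(),
            "risk_model": self.risk.to_dict(),
            "interaction_test": self.interaction.to_dict(),
            "strata": self.strata.to_dict(),
            "overall_effect": self.overall_effect.to_dict(),
            "stratum_effects": [e.to_dict() for e in self.stratum_effects],
            "subgroup_effects": {
                name: [e.to_dict() for e in effects]
                for name, effects in self.subgroup_effects.items()
            },
        }
        return report

    def figure_data(self) -> dict:
        """Data sufficient to redraw the distribution and benefit figures:
        per-group probability densities, stratum means, empirical and
        model-based stratum RDs, and the overall-effect band."""
        lp_grid = np.linspace(
            float(np.min(self.risk.linear_predictor)),
            float(np.max(self.risk.linear_predictor)),
            101,
        )
        p_grid = expit(lp_grid)
        rd_curve = self.model_based_rd(lp_grid)
        stratum_mean_lp = np.array(
            [
                float(np.mean(self.risk.linear_predictor[self.strata.assignments == i]))
                for i in range(self.strata.n_bins)
            ]
        )
        return {
            "risk_group_distributions": {
                g: d.to_dict() for g, d in self.strata_distributions.items()
            },
            "risk_group_overlap": self.strata_overlap.to_dict(),
            "subgroup_distributions": {
                name: {
                    "distributions": {
                        g: d.to_dict() for g, d in block["distributions"].items()
                    },
                    "overlap": block["overlap"].to_dict(),
                }
                for name, block in self.subgroup_distributions.items()
            },
            "benefit": {
                "overall": self.overall_effect.to_dict(),
                "strata": [e.to_dict() for e in self.stratum_effects],
                "subgroups": {
                    name: [e.to_dict() for e in effects]
                    for name, effects in self.subgroup_effects.items()
                },
                "model_based_curve": {
                    "baseline_probability": [float(x) for x in p_grid],
                    "risk_difference": [float(x) for x in rd_curve],
                },
                "model_based_at_stratum_means": [
                    float(x) for x in self.model_based_rd(stratum_mean_lp)
                ],
            },
        }

    def save(self, outdir, config: AnalysisConfig | None = None) -> dict[str, Path]:
        """Write report.json, model_fit.json, stratum_table.csv,
        complete_case.json and figure_data.json under `outdir`."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "report": outdir / "report.json",
            "model_fit": outdir / "model_fit.json",
            "stratum_table": outdir / "stratum_table.csv",
            "complete_case": outdir / "complete_case.json",
            "figure_data": outdir / "figure_data.json",
            "summary": outdir / "summary.txt",
        }
        paths["report"].write_text(
            json.dumps(self.to_dict(config), indent=2), encoding="utf-8"
        )
        self.risk.to_json(paths["model_fit"])
        self.stratum_table().to_csv(paths["stratum_table"], index=False)
        self.complete_case.to_json(paths["complete_case"])
        paths["figure_data"].write_text(
            json.dumps(self.figure_data(), indent=2), encoding="utf-8"
        )
        paths["summary"].write_text(self.summary() + "\n", encoding="utf-8")
        return paths


def run_analysis(config: AnalysisConfig) -> HTEResults:
    """Execute the full pipeline from a configuration; write reports if
    `config.outdir` is set. Partial outputs are removed on failure."""
    if config.synthetic is not None:
        table = generate_trial(config.synthetic)
    else:
        schema = (
            VariableSchema.from_yaml(config.schema_path)
            if config.schema_path
            else _default_schema()
        )
        mapping = None
        if config.mapping_path:
            from .io import load_mapping

            mapping = load_mapping(config.mapping_path)
        table = read_trial_csv(config.input_path, schema, mapping=mapping)
    analysis = HTEAnalysis(table, n_bins=config.n_bins, subgroups=config.subgroups)
    results = analysis.fit()
    if config.outdir:
        written = []
        try:
            written = list(results.save(config.outdir, config).values())
        except Exception:
            for p in written:
                Path(p).unlink(missing_ok=True)
            raise
    return results


def _default_schema() -> VariableSchema:
    from .schema import ist3_schema

    return ist3_schema()


# ---------------------------------------------------------------------------
# operating characteristics
# ---------------------------------------------------------------------------

def true_stratum_effects(
    truth: pd.DataFrame, assignments: np.ndarray, n_bins: int
) -> np.ndarray:
    """Generative-truth risk difference per stratum.

    Averages the patient-level true outcome probabilities (treated minus
    control) over each stratum's members — Monte-Carlo integration over the
    stratum's covariate/linear-predictor distribution.
    """
    deltas = truth["p_treated"].to_numpy() - truth["p_control"].to_numpy()
    return np.array([float(deltas[assignments == i].mean()) for i in range(n_bins)])


def run_operating_characteristics(
    grid: list[SyntheticTrialConfig],
    alpha: float = 0.05,
    n_replicates: int = 100,
    seed: int = 0,
    n_bins: int = 4,
) -> pd.DataFrame:
    """Simulation study of the interaction test and the stratum estimates.

    For each configuration in `grid`, generates `n_replicates` trials (seeds
    derived from `seed`), runs risk model -> LR test -> strata -> effects on
    each, and summarizes: LR-test rejection rate at `alpha`, mean stratum-CI
    width, and coverage of the generative-truth stratum RDs, all with
    Monte-Carlo standard errors.
    """
    if n_replicates < 1:
        raise ArgumentError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    rows = []
    for gi, cfg in enumerate(grid):
        child_seeds = ss.spawn(1)[0].generate_state(n_replicates) % (2**31)
        rejections = []
        widths = []
        covered = []
        for r in range(n_replicates):
            rep_cfg = cfg.replace(seed=int(child_seeds[r]))
            table, truth = generate_trial(rep_cfg, return_truth=True)
            risk = RiskModel(table).fit()
            test = lr_interaction_test(table, risk)
            rejections.append(test.p_value < alpha)
            strata = quantile_bins(risk.predicted_probability, n_bins)
            effects = stratified_effects(table, strata)
            truths = true_stratum_effects(truth, strata.assignments, n_bins)
            for est, tr in zip(effects, truths):
                if est.defined:
                    widths.append(est.ci_high - est.ci_low)
                    covered.append(est.ci_low <= tr <= est.ci_high)
        rej = float(np.mean(rejections))
        cov = float(np.mean(covered))
        rows.append(
            {
                "grid_index": gi,
                "n_patients": cfg.n_patients,
                "interaction_strength": cfg.interaction_strength,
                "treatment_main_effect": cfg.treatment_main_effect,
                "n_replicates": n_replicates,
                "rejection_rate": rej,
                "rejection_rate_mcse": float(
                    np.sqrt(rej * (1 - rej) / n_replicates)
                ),
                "mean_ci_width": float(np.mean(widths)),
                "coverage": cov,
                "coverage_mcse": float(np.sqrt(cov * (1 - cov) / len(covered))),
            }
        )
        logger.info(
            "oc grid %d: rejection %.3f, coverage %.3f", gi, rej, cov
        )
    return pd.DataFrame(rows)
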