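"""Risk strata, risk differences, subgroup splits and density overlap."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm
from statsmodels.stats.proportion import confint_proportions_2indep, proportions_ztest

from riskhte import (
    RiskModel,
    SubgroupDefinition,
    generate_trial,
    overlap_coefficient,
    quantile_bins,
    risk_difference,
    stratified_effects,
    subgroup_distributions,
)
from riskhte.errors import (
    ArgumentError,
    DegenerateStrataError,
    StratificationError,
    UndefinedEstimateError,
)
from riskhte.strata import DENSITY_GRID

from conftest import small_config


class TestQuantileBins:
    def test_eight_values_quartiles(self):
        strata = quantile_bins(np.arange(0.1, 0.81, 0.1), n_bins=4)
        assert strata.sizes.tolist() == [2, 2, 2, 2]
        assert strata.labels == ["Q1", "Q2", "Q3", "Q4"]

    def test_nine_values_hand_computed(self):
        """p = 0.1..0.9: interpolated quartile edges are (0.3, 0.5, 0.7), so
        the half-open assignment gives sizes (2, 2, 2, 3)."""
        strata = quantile_bins(np.arange(0.1, 0.91, 0.1), n_bins=4)
        assert np.allclose(strata.edges, [0.1, 0.3, 0.5, 0.7, 0.9])
        assert strata.sizes.tolist() == [2, 2, 2, 3]

    def test_single_bin_contains_everyone(self):
        p = np.random.default_rng(0).uniform(0.05, 0.95, 37)
        strata = quantile_bins(p, n_bins=1)
        assert strata.sizes.tolist() == [37]

    def test_partition_property(self):
        p = np.random.default_rng(5).uniform(0.01, 0.99, 1003)
        strata = quantile_bins(p, n_bins=4)
        assert strata.sizes.sum() == 1003
        assert set(strata.assignments) == {0, 1, 2, 3}
        assert np.all(np.diff(strata.edges) > 0)

    def test_equal_sizes_when_divisible(self):
        p = np.random.default_rng(6).uniform(0.01, 0.99, 1000)
        assert quantile_bins(p, 4).sizes.tolist() == [250] * 4

    def test_too_few_observations(self):
        with pytest.raises(StratificationError):
            quantile_bins(np.array([0.2, 0.4, 0.6]), n_bins=4)

    def test_heavy_ties_degenerate(self):
        p = np.array([0.5] * 60 + list(np.linspace(0.1, 0.9, 40)))
        with pytest.raises(DegenerateStrataError):
            quantile_bins(p, n_bins=4)

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(ArgumentError):
            quantile_bins(np.array([0.0, 0.5, 0.7, 0.9]), n_bins=2)


class TestRiskDifference:
    def test_equal_proportions_zero_rd(self):
        est = risk_difference(100, 30, 100, 30)
        assert est.risk_difference == 0.0
        assert np.isclose(est.ci_low, -est.ci_high)
        assert est.p_value == 1.0

    def test_wald_formula_hand_case(self):
        """30/100 vs 40/100: RD = -0.10 with the closed-form Wald CI."""
        est = risk_difference(100, 30, 100, 40)
        assert np.isclose(est.risk_difference, -0.10)
        se = np.sqrt(0.3 * 0.7 / 100 + 0.4 * 0.6 / 100)
        assert np.isclose(est.ci_low, -0.10 - 1.959964 * se)
        assert np.isclose(est.ci_high, -0.10 + 1.959964 * se)

    def test_against_statsmodels(self):
        """Cross-check CI and z-test against the independent implementations
        in statsmodels.stats.proportion."""
        est = risk_difference(120, 30, 140, 52)
        lo, hi = confint_proportions_2indep(
            30, 120, 52, 140, method="wald", compare="diff"
        )
        assert np.isclose(est.ci_low, lo, atol=1e-10)
        assert np.isclose(est.ci_high, hi, atol=1e-10)
        _, p = proportions_ztest([30, 52], [120, 140])
        assert np.isclose(est.p_value, p, atol=1e-10)

    def test_bootstrap_se_agrees_with_wald(self):
        """Parametric bootstrap of the 30/100 vs 40/100 case: the bootstrap
        SD of the RD matches the Wald SE within Monte-Carlo error."""
        rng = np.random.default_rng(42)
        boot = (
            rng.binomial(100, 0.3, size=50_000) / 100
            - rng.binomial(100, 0.4, size=50_000) / 100
        )
        se_wald = np.sqrt(0.3 * 0.7 / 100 + 0.4 * 0.6 / 100)
        assert abs(boot.std() - se_wald) < 0.003

    @given(
        nt=st.integers(10, 500),
        nc=st.integers(10, 500),
        pt=st.floats(0.05, 0.95),
        pc=st.floats(0.05, 0.95),
    )
    def test_estimate_invariants(self, nt, nc, pt, pc):
        et, ec = int(round(nt * pt)), int(round(nc * pc))
        est = risk_difference(nt, et, nc, ec)
        assert -1 <= est.risk_difference <= 1
        assert est.ci_low <= est.risk_difference <= est.ci_high
        assert 0 <= est.p_value <= 1

    def test_ci_width_shrinks_at_root_n(self):
        """Fixed proportions, doubling n: CI width shrinks by exactly
        1/sqrt(2) per doubling."""
        widths = []
        for n in (100, 200, 400, 800):
            est = risk_difference(n, int(0.3 * n), n, int(0.4 * n))
            widths.append(est.ci_high - est.ci_low)
        ratios = np.array(widths[:-1]) / np.array(widths[1:])
        assert np.allclose(ratios, np.sqrt(2), rtol=1e-12)

    def test_empty_arm_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            risk_difference(0, 0, 100, 30)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ArgumentError):
            risk_difference(10, 12, 10, 3)


class TestStratifiedEffects:
    @staticmethod
    def _fit(n=6000, seed=3, interaction=0.0, main=0.0):
        table = generate_trial(
            small_config(n=n, seed=seed, interaction=interaction, main=main)
        )
        risk = RiskModel(table).fit()
        return table, risk

    def test_identical_strata_equal_pooled(self):
        """Two strata with identical arm counts and events both reproduce
        the pooled RD."""
        from riskhte import TrialTable

        table, risk = self._fit(n=400, seed=1)
        half = np.array(["A"] * 200 + ["B"] * 200)
        # engineer identical (treatment, outcome) blocks
        block = table.data.iloc[:200]
        doubled = block.copy()
        doubled["patient_id"] = [f"X{i}" for i in range(200)]
        import pandas as pd

        table2 = TrialTable(
            pd.concat([block, doubled], ignore_index=True), table.schema
        )
        effects = stratified_effects(table2, half)
        t = table2.treatment_indicator()
        y = table2.outcome_array().astype(int)
        pooled = risk_difference(
            int(t.sum()), int(y[t == 1].sum()), int((t == 0).sum()), int(y[t == 0].sum())
        )
        for est in effects:
            assert np.isclose(est.risk_difference, pooled.risk_difference)

    def test_pooling_consistency_exact(self):
        """RD on summed counts across strata equals the overall estimate
        exactly."""
        table, risk = self._fit()
        strata = quantile_bins(risk.predicted_probability, 4)
        effects = stratified_effects(table, strata)
        nt = sum(e.n_treated for e in effects)
        et = sum(e.events_treated for e in effects)
        nc = sum(e.n_control for e in effects)
        ec = sum(e.events_control for e in effects)
        t = table.treatment_indicator()
        y = table.outcome_array().astype(int)
        overall = risk_difference(
            int(t.sum()), int(y[t == 1].sum()), int((t == 0).sum()), int(y[t == 0].sum())
        )
        assert (nt, et, nc, ec) == (
            overall.n_treated,
            overall.events_treated,
            overall.n_control,
            overall.events_control,
        )
        assert risk_difference(nt, et, nc, ec).risk_difference == overall.risk_difference

    def test_stratum_rds_near_generative_truth(self):
        """With a real generative interaction, empirical stratum RDs fall
        within 3 SE of the truth computed by integrating the generative
        probabilities over each stratum."""
        cfg = small_config(n=20_000, seed=77, interaction=-0.5, main=0.0)
        table, truth = generate_trial(cfg, return_truth=True)
        risk = RiskModel(table).fit()
        strata = quantile_bins(risk.predicted_probability, 4)
        effects = stratified_effects(table, strata)
        deltas = truth["p_treated"] - truth["p_control"]
        for i, est in enumerate(effects):
            true_rd = float(deltas[strata.assignments == i].mean())
            se = (est.ci_high - est.ci_low) / (2 * 1.959964)
            assert abs(est.risk_difference - true_rd) < 3 * se
        # heterogeneity visible: Q1 and Q4 truths differ
        d1 = float(deltas[strata.assignments == 0].mean())
        d4 = float(deltas[strata.assignments == 3].mean())
        assert d1 > d4

    def test_empty_arm_flagged_not_fatal(self):
        table, _ = self._fit(n=200, seed=9)
        labels = np.array(
            ["solo" if (i == 0) else "rest" for i in range(table.n)]
        )
        # force the 'solo' group to hold a single control patient
        table.data.loc[table.data.index[0], "treatment"] = "control"
        effects = stratified_effects(table, labels)
        solo = [e for e in effects if e.scope == "solo"][0]
        assert not solo.defined
        assert np.isnan(solo.risk_difference)
        rest = [e for e in effects if e.scope == "rest"][0]
        assert rest.defined


class TestSubgroupDefinition:
    def test_threshold_split_assigns_everyone(self, small_trial):
        sg = SubgroupDefinition("x", threshold=0.0)
        labels = sg.assign(small_trial)
        assert len(labels) == small_trial.n
        assert set(labels) == {"x<0", "x>=0"}

    def test_categorical_levels(self, small_trial):
        labels = SubgroupDefinition("g").assign(small_trial)
        assert set(labels) == {"g=a", "g=b"}

    def test_unknown_variable_rejected(self, small_trial):
        with pytest.raises(ArgumentError):
            SubgroupDefinition("bogus").assign(small_trial)

    def test_continuous_without_threshold_rejected(self, small_trial):
        with pytest.raises(ArgumentError):
            SubgroupDefinition("x").assign(small_trial)


class TestSubgroupDistributions:
    def test_identical_groups_full_overlap(self):
        rng = np.random.default_rng(2)
        p = np.tile(rng.uniform(0.1, 0.9, 500), 2)
        groups = np.array(["a"] * 500 + ["b"] * 500)
        _, overlap = subgroup_distributions(p, groups)
        assert overlap.loc["a", "b"] > 0.999

    def test_disjoint_groups_near_zero_overlap(self):
        rng = np.random.default_rng(3)
        p = np.concatenate(
            [rng.uniform(0.05, 0.15, 500), rng.uniform(0.85, 0.95, 500)]
        )
        groups = np.array(["lo"] * 500 + ["hi"] * 500)
        _, overlap = subgroup_distributions(p, groups)
        assert overlap.loc["lo", "hi"] < 0.02

    def test_normal_overlap_analytic_oracle(self):
        """Two Normal samples, means 0.4 / 0.5, common sd 0.05: overlap
        matches the closed form 2*Phi(-|mu1-mu2| / (2*sigma)) within 0.02."""
        rng = np.random.default_rng(4)
        a = rng.normal(0.40, 0.05, 10_000)
        b = rng.normal(0.50, 0.05, 10_000)
        p = np.clip(np.concatenate([a, b]), 1e-4, 1 - 1e-4)
        groups = np.array(["a"] * 10_000 + ["b"] * 10_000)
        _, overlap = subgroup_distributions(p, groups)
        analytic = 2 * norm.cdf(-0.10 / (2 * 0.05))
        assert abs(overlap.loc["a", "b"] - analytic) < 0.02

    def test_small_group_density_omitted_summary_kept(self):
        p = np.array([0.2, 0.4, 0.6, 0.8])
        groups = np.array(["big", "big", "big", "tiny"])
        dists, _ = subgroup_distributions(p, groups)
        assert dists["tiny"].density is None
        assert dists["tiny"].n == 1
        assert np.isclose(dists["tiny"].mean, 0.8)
        assert dists["big"].density is not None
        # densities integrate to ~1 on the grid
        assert np.isclose(
            np.trapezoid(dists["big"].density, DENSITY_GRID), 1.0, atol=1e-6
        )

    def test_overlap_coefficient_bounds(self):
        d = np.ones_like(DENSITY_GRID)
        assert np.isclose(overlap_coefficient(d, d), 1.0)
        assert overlap_coefficient(d, np.zeros_like(d)) == 0.0


class TestRiskStrataSpanContrast:
    def test_risk_strata_span_wider_than_single_variable_splits(self):
        """Quartile risk groups span a wider range of mean predicted
        probability than any single-covariate split — the core argument for
        multivariable risk stratification over one-variable subgroups."""
        table = generate_trial(small_config(n=8000, seed=15))
        risk = RiskModel(table).fit()
        p = risk.predicted_probability
        strata = quantile_bins(p, 4)
        means = [float(p[strata.assignments == i].mean()) for i in range(4)]
        risk_span = max(means) - min(means)
        for sg in (SubgroupDefinition("x", threshold=0.0), SubgroupDefinition("g")):
            labels = sg.assign(table)
            g_means = [float(p[labels == g].mean()) for g in set(labels)]
            assert risk_span > max(g_means) - min(g_means)
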