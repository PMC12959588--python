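import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from riskhte import (
    CovariateSpec,
    SyntheticTrialConfig,
    TrialTable,
    Variable,
    VariableSchema,
    generate_trial,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_schema() -> VariableSchema:
    """Two-predictor schema: one continuous, one binary."""
    return VariableSchema(
        [
            Variable("treatment", "binary", "treatment", levels=("control", "treated")),
            Variable("outcome", "binary", "outcome", levels=("0", "1")),
            Variable("age", "continuous"),
            Variable("sex", "binary", levels=("Female", "Male")),
        ]
    )


def small_config(
    n: int = 500,
    seed: int = 0,
    interaction: float = 0.0,
    main: float = 0.0,
    intercept: float = -0.5,
) -> SyntheticTrialConfig:
    """A fast two-covariate trial configuration for unit tests."""
    return SyntheticTrialConfig(
        n_patients=n,
        outcome_coefficients={"intercept": intercept, "x": 0.8, "g=b": -0.5},
        covariate_spec=[
            CovariateSpec("x", "continuous", "normal", {"mean": 0.0, "sd": 1.0}),
            CovariateSpec(
                "g", "binary", "categorical", {"levels": ["a", "b"], "probs": [0.6, 0.4]}
            ),
        ],
        treatment_main_effect=main,
        interaction_strength=interaction,
        seed=seed,
        treatment_levels=("control", "treated"),
    )


@pytest.fixture
def small_trial() -> TrialTable:
    return generate_trial(small_config(n=400, seed=11))


def make_table(
    schema: VariableSchema, treatment, outcome, **covariates
) -> TrialTable:
    """Hand-build a TrialTable from parallel value lists."""
    n = len(treatment)
    data = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            schema.treatment.name: treatment,
            schema.outcome.name: pd.array(outcome, dtype="Int64"),
        }
    )
    for name, values in covariates.items():
        data[name] = values
    return TrialTable(data, schema)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
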