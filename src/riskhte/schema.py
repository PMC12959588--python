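"""Variable schemas and the patient-level trial table.

A :class:`VariableSchema` declares, for every column of a randomized-trial
table, its name, kind (continuous / binary / categorical), role (treatment /
outcome / predictor / ignored) and — for categorical variables — the allowed
levels with an explicit reference level. A :class:`TrialTable` couples a typed
:class:`pandas.DataFrame` with its schema and enforces the basic invariants
(unique patient ids, non-missing treatment, category values within levels).

The default schema, :func:`ist3_schema`, mirrors the baseline-variable set of
the IST-3 thrombolysis trial: a binary treatment (placebo vs alteplase), the
binary primary outcome (alive and independent, Oxford Handicap Score 0-2 at
6 months) and fifteen baseline predictors. Reference levels are the first
level listed for each variable, which reproduces the direction of the
conventionally reported odds ratios (e.g. Male vs Female).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError, ValidationError

__all__ = [
    "Variable",
    "VariableSchema",
    "TrialTable",
    "ist3_schema",
    "ID_COLUMN",
]

#: Name of the patient identifier column in every trial table.
ID_COLUMN = "patient_id"

_KINDS = ("continuous", "binary", "categorical")
_ROLES = ("treatment", "outcome", "predictor", "ignored")


@dataclass(frozen=True)
class Variable:
    """One column declaration.

    Parameters
    ----------
    name : str
        Column name.
    kind : {"continuous", "binary", "categorical"}
        Statistical kind. Binary categorical variables use ``"binary"``.
    role : {"treatment", "outcome", "predictor", "ignored"}
        How the analysis uses the column.
    levels : tuple of str, optional
        Allowed levels for binary/categorical variables, in declaration order.
    reference : str, optional
        Reference level; defaults to the first declared level.
    """

    name: str
    kind: str
    role: str = "predictor"
    levels: tuple[str, ...] | None = None
    reference: str | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for variable {self.name!r}")
        if self.role not in _ROLES:
            raise SchemaError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.kind in ("binary", "categorical"):
            if not self.levels or len(self.levels) < 2:
                raise SchemaError(
                    f"variable {self.name!r} is {self.kind} and needs >= 2 levels"
                )
            if self.kind == "binary" and len(self.levels) != 2:
                raise SchemaError(f"binary variable {self.name!r} needs exactly 2 levels")
            ref = self.reference if self.reference is not None else self.levels[0]
            if ref not in self.levels:
                raise SchemaError(
                    f"reference level {ref!r} of {self.name!r} not among levels"
                )
            object.__setattr__(self, "reference", ref)
            object.__setattr__(self, "levels", tuple(self.levels))
        elif self.levels is not None:
            raise SchemaError(f"continuous variable {self.name!r} cannot declare levels")

    @property
    def is_categorical(self) -> bool:
        return self.kind in ("binary", "categorical")

    def nonreference_levels(self) -> tuple[str, ...]:
        return tuple(lv for lv in self.levels if lv != self.reference)


@dataclass
class VariableSchema:
    """Ordered collection of :class:`Variable` declarations.

    Invariants: exactly one treatment and one outcome variable; variable
    names unique.
    """

    variables: list[Variable] = field(default_factory=list)

    def __post_init__(self):
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        if len([v for v in self.variables if v.role == "treatment"]) != 1:
            raise SchemaError("schema must declare exactly one treatment variable")
        if len([v for v in self.variables if v.role == "outcome"]) != 1:
            raise SchemaError("schema must declare exactly one outcome variable")
        t = self.treatment
        if t.kind != "binary":
            raise SchemaError("treatment variable must be binary")

    # -- accessors ---------------------------------------------------------
    @property
    def treatment(self) -> Variable:
        return next(v for v in self.variables if v.role == "treatment")

    @property
    def outcome(self) -> Variable:
        return next(v for v in self.variables if v.role == "outcome")

    @property
    def predictors(self) -> list[Variable]:
        return [v for v in self.variables if v.role == "predictor"]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    @property
    def control_level(self) -> str:
        """Reference (control) level of the treatment variable."""
        return self.treatment.reference

    @property
    def treated_level(self) -> str:
        return self.treatment.nonreference_levels()[0]

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": v.name,
                    "kind": v.kind,
                    "role": v.role,
                    **({"levels": list(v.levels)} if v.levels else {}),
                    **({"reference": v.reference} if v.reference else {}),
                }
                for v in self.variables
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        try:
            variables = [
                Variable(
                    name=e["name"],
                    kind=e["kind"],
                    role=e.get("role", "predictor"),
                    levels=tuple(e["levels"]) if e.get("levels") else None,
                    reference=e.get("reference"),
                )
                for e in d["variables"]
            ]
        except KeyError as exc:
            raise SchemaError(f"schema entry missing key: {exc}") from exc
        return cls(variables)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "VariableSchema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


class TrialTable:
    """Typed patient-level trial table.

    Wraps a :class:`pandas.DataFrame` whose columns are ``patient_id``, the
    treatment, the outcome (0 = unfavorable, 1 = favorable, <NA> = missing)
    and covariates in schema order. Continuous covariates are float64 (NaN =
    missing); categorical covariates hold level strings (NaN/None = missing).
    """

    def __init__(self, data: pd.DataFrame, schema: VariableSchema, validate: bool = True):
        self.schema = schema
        cols = [ID_COLUMN, schema.treatment.name, schema.outcome.name] + [
            v.name for v in schema.predictors
        ]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise SchemaError(f"table missing required columns: {missing}")
        self.data = data.loc[:, cols].copy()
        self.data[schema.outcome.name] = self.data[schema.outcome.name].astype("Int64")
        for v in schema.predictors:
            if v.kind == "continuous":
                self.data[v.name] = self.data[v.name].astype("float64")
        if validate:
            self.validate()

    # -- invariant checks --------------------------------------------------
    def validate(self) -> None:
        sch = self.schema
        ids = self.data[ID_COLUMN]
        if ids.isna().any() or ids.duplicated().any():
            raise ValidationError("patient_id must be present and unique")
        tcol = self.data[sch.treatment.name]
        if tcol.isna().any():
            raise ValidationError("treatment must never be missing")
        bad = ~tcol.isin(sch.treatment.levels)
        if bad.any():
            offenders = sorted(tcol[bad].unique().tolist())
            raise ValidationError(
                f"treatment values outside declared levels: {offenders}"
            )
        ocol = self.data[sch.outcome.name]
        if not ocol.dropna().isin([0, 1]).all():
            raise ValidationError("outcome must be 0, 1 or missing")
        for v in sch.predictors:
            if v.is_categorical:
                col = self.data[v.name]
                bad = col.notna() & ~col.isin(v.levels)
                if bad.any():
                    rows = self.data.index[bad].tolist()[:5]
                    vals = sorted(map(str, col[bad].unique().tolist()))
                    raise ValidationError(
                        f"variable {v.name!r}: values {vals} outside declared "
                        f"levels {list(v.levels)} (first offending rows: {rows})"
                    )

    # -- convenience -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    def treatment_indicator(self) -> np.ndarray:
        """0/1 array, 1 = treated (non-reference level)."""
        return (
            self.data[self.schema.treatment.name] == self.schema.treated_level
        ).to_numpy(dtype=int)

    def outcome_array(self) -> np.ndarray:
        """float array of outcomes, NaN where missing."""
        return self.data[self.schema.outcome.name].astype("float64").to_numpy()

    def is_missing(self, name: str) -> pd.Series:
        """Boolean missingness mask for one schema variable."""
        return self.data[name].isna()

    def copy(self) -> "TrialTable":
        return TrialTable(self.data.copy(), self.schema, validate=False)

    def equals(self, other: "TrialTable") -> bool:
        return self.data.equals(other.data) and self.schema.to_dict() == other.schema.to_dict()

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:
        return (
            f"<TrialTable n={self.n} treatment={self.schema.treatment.name!r} "
            f"outcome={self.schema.outcome.name!r} "
            f"predictors={len(self.schema.predictors)}>"
        )


def ist3_schema() -> VariableSchema:
    """Schema of the IST-3-style baseline variable set.

    Fifteen baseline predictors as collected at randomization in an acute
    ischemic stroke thrombolysis trial, plus the binary treatment arm and the
    6-month favorable-outcome indicator.
    """
    V = Variable
    return VariableSchema(
        [
            V("treatment", "binary", "treatment", levels=("Placebo", "Alteplase")),
            V("outcome", "binary", "outcome", levels=("0", "1")),
            V("age", "continuous"),
            V("sex", "binary", levels=("Female", "Male")),
            V("lived_alone", "binary", levels=("Yes", "No")),
            V(
                "ischemic_change",
                "categorical",
                levels=("No", "Possibly yes", "Definitely yes"),
            ),
            V("antiplatelet_48h", "binary", levels=("Yes", "No")),
            V("atrial_fibrillation", "binary", levels=("Yes", "No")),
            V("sbp", "continuous"),
            V("dbp", "continuous"),
            V("weight", "continuous"),
            V("gcs_eye", "binary", levels=("Nonspontaneously", "Spontaneously")),
            V("gcs_motor", "binary", levels=("Normal", "Not normal")),
            V(
                "gcs_verbal",
                "categorical",
                levels=(
                    "None",
                    "Noises only",
                    "Inappropriate words",
                    "Confused",
                    "Orientated",
                ),
            ),
            V("gcs_total", "continuous"),
            V("nihss", "continuous"),
            V("stroke_subtype", "categorical", levels=("LACI", "PACI", "POCI", "TACI")),
        ]
    )
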