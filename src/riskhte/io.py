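"""Reading, writing and filtering patient-level trial tables.

CSV conventions: UTF-8, header row, one row per patient, empty cell = missing.
``""``, ``"NA"`` and ``"NaN"`` (case-insensitive) are all accepted as missing
on read, which covers the common CSV dialects including exports of the
deposited IST-3 table. Column order on write is ``patient_id``, treatment,
outcome, then covariates in schema order.

A user-editable column-name mapping (YAML/JSON: raw name -> schema name)
translates raw dataset field names — e.g. those of the deposited IST-3
download — to schema names without touching code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ArgumentError, InputError, SchemaError, ValidationError
from .schema import ID_COLUMN, TrialTable, VariableSchema

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "complete_case_filter",
    "CompleteCaseReport",
    "load_mapping",
]

logger = logging.getLogger(__name__)

#: Cell contents treated as missing on read (compared case-insensitively).
MISSING_TOKENS = {"", "na", "nan"}


@dataclass
class CompleteCaseReport:
    """Accounting for a complete-case filter pass."""

    n_input: int
    n_retained: int
    n_dropped: int
    dropped_by_variable: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        assert self.n_input == self.n_retained + self.n_dropped
        assert all(c >= 0 for c in self.dropped_by_variable.values())

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_dropped": self.n_dropped,
            "dropped_by_variable": dict(self.dropped_by_variable),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


def load_mapping(path) -> dict[str, str]:
    """Load a raw-name -> schema-name column mapping from YAML or JSON."""
    text = Path(path).read_text(encoding="utf-8")
    mapping = yaml.safe_load(text)
    if not isinstance(mapping, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in mapping.items()
    ):
        raise SchemaError(f"mapping file {path} must be a flat name -> name map")
    return mapping


def _is_missing_token(value: str) -> bool:
    return value.strip().lower() in MISSING_TOKENS


def read_trial_csv(path, schema: VariableSchema, mapping: dict[str, str] | None = None) -> TrialTable:
    """Read and validate a patient-level trial CSV.

    Parameters
    ----------
    path : path-like
        CSV file with a header containing every schema variable (after
        applying `mapping`, if given).
    schema : VariableSchema
        Declared types, levels and roles.
    mapping : dict, optional
        Raw column name -> schema name translation applied before validation.

    Returns
    -------
    TrialTable
        Typed table. Unparseable continuous cells are flagged missing with a
        logged warning; categorical values outside the declared levels raise
        :class:`~riskhte.errors.ValidationError` naming rows and values.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"input file is empty: {path}") from exc
    if mapping:
        raw = raw.rename(columns=mapping)
    required = [ID_COLUMN, schema.treatment.name, schema.outcome.name] + [
        v.name for v in schema.predictors
    ]
    absent = [c for c in required if c not in raw.columns]
    if absent:
        raise SchemaError(f"{path}: missing required columns {absent}")
    if raw.empty:
        raise InputError(f"input file has a header but no rows: {path}")

    out = pd.DataFrame(index=raw.index)
    out[ID_COLUMN] = raw[ID_COLUMN].astype(str)

    tname = schema.treatment.name
    tvals = raw[tname].astype(str)
    if tvals.map(_is_missing_token).any():
        raise ValidationError(f"{tname}: treatment must never be missing")
    out[tname] = tvals

    oname = schema.outcome.name
    out[oname] = _parse_outcome(raw[oname], oname)

    for v in schema.predictors:
        col = raw[v.name].astype(str)
        miss = col.map(_is_missing_token)
        if v.kind == "continuous":
            vals = col.where(~miss)
            probe = pd.to_numeric(vals, errors="coerce")
            parsed = pd.Series(np.nan, index=col.index, dtype="float64")
            ok = probe.notna()
            # python float() parsing is exact for %.17g-formatted doubles
            parsed[ok] = vals[ok].astype("float64")
            bad = parsed.isna() & ~miss
            if bad.any():
                logger.warning(
                    "%s: %d unparseable numeric cells in %r flagged missing "
                    "(first rows: %s)",
                    path.name,
                    int(bad.sum()),
                    v.name,
                    raw.index[bad].tolist()[:5],
                )
            out[v.name] = parsed
        else:
            vals = col.where(~miss)
            bad = vals.notna() & ~vals.isin(v.levels)
            if bad.any():
                offenders = [
                    f"row {i}: {vals.loc[i]!r}" for i in raw.index[bad].tolist()[:10]
                ]
                raise ValidationError(
                    f"{v.name!r}: values outside declared levels "
                    f"{list(v.levels)} — " + "; ".join(offenders)
                )
            out[v.name] = vals.astype(object).where(vals.notna(), np.nan)
    return TrialTable(out, schema)


def _parse_outcome(col: pd.Series, name: str) -> pd.Series:
    col = col.astype(str)
    miss = col.map(_is_missing_token)
    parsed = pd.to_numeric(col.where(~miss), errors="coerce")
    bad = (parsed.isna() & ~miss) | (~parsed.isin([0, 1]) & parsed.notna())
    if bad.any():
        offenders = [f"row {i}: {col.loc[i]!r}" for i in col.index[bad].tolist()[:10]]
        raise ValidationError(
            f"{name!r}: outcome must be 0, 1 or missing — " + "; ".join(offenders)
        )
    return parsed.astype("Int64")


def write_trial_csv(table: TrialTable, path) -> None:
    """Write a trial table to CSV (empty cell = missing)."""
    df = table.data.copy()
    # keep integers integral in the CSV so the round trip is exact
    for v in table.schema.predictors:
        if v.kind == "continuous":
            col = df[v.name]
            if col.notna().any() and np.allclose(
                col.dropna() % 1, 0, rtol=0, atol=0
            ):
                df[v.name] = col.astype("Int64")
    # %.17g round-trips float64 exactly through text
    df.to_csv(path, index=False, na_rep="", encoding="utf-8", float_format="%.17g")


def complete_case_filter(
    table: TrialTable, variables: list[str] | None = None
) -> tuple[TrialTable, CompleteCaseReport]:
    """Retain only rows with no missing value among `variables`.

    Defaults to the analysis variable set: treatment, outcome and every
    predictor. Row order of retained patients is preserved; the operation is
    idempotent.
    """
    sch = table.schema
    if variables is None:
        variables = [sch.treatment.name, sch.outcome.name] + [
            v.name for v in sch.predictors
        ]
    unknown = [v for v in variables if v not in sch]
    if unknown:
        raise ArgumentError(f"unknown variables for complete-case filter: {unknown}")

    miss = pd.DataFrame({v: table.data[v].isna() for v in variables})
    drop_row = miss.any(axis=1)
    dropped_by_variable = {
        v: int(miss[v].sum()) for v in variables if int(miss[v].sum()) > 0
    }
    kept = table.data.loc[~drop_row].copy()
    report = CompleteCaseReport(
        n_input=len(table.data),
        n_retained=len(kept),
        n_dropped=int(drop_row.sum()),
        dropped_by_variable=dropped_by_variable,
    )
    logger.info(
        "complete-case filter: %d in, %d retained, %d dropped",
        report.n_input,
        report.n_retained,
        report.n_dropped,
    )
    return TrialTable(kept, sch, validate=False), report
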