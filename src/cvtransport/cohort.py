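"""Subject-level cohort tables: validation, I/O, complete-case filtering.

A :class:`CohortTable` is a thin, validated wrapper around a pandas DataFrame
holding one row per subject: a ``subject_id``, a ``source`` label (which
study the subject comes from), a treatment ``arm`` (``treated`` / ``control``
for longitudinal cohorts, ``none`` for a cross-sectional target population),
the baseline covariates of a :class:`~cvtransport.schema.CovariateSchema`,
and — when follow-up exists — ``time`` (years) and ``event`` (0/1) for the
composite cardiovascular endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schema import CovariateSchema

ARMS = ("treated", "control", "none")
ID_COLS = ["subject_id", "source", "arm"]
OUTCOME_COLS = ["time", "event"]


class SchemaError(ValueError):
    """A column required by the schema is missing or unknown."""


class ValidationError(ValueError):
    """A value violates a schema invariant (range, uniqueness, coding)."""


@dataclass
class CohortTable:
    """Validated subject-level table.

    Parameters
    ----------
    df : DataFrame
        Columns: ``subject_id``, ``source``, ``arm``, the schema covariates,
        and (iff any ``arm != 'none'``) ``time`` and ``event``. Missing
        values are allowed in covariates until complete-case filtering.
    schema : CovariateSchema
    """

    df: pd.DataFrame
    schema: CovariateSchema

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        for col in ID_COLS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        for name in self.schema.names:
            if name not in df.columns:
                raise SchemaError(f"missing required column {name!r}")
        known = set(ID_COLS + OUTCOME_COLS + self.schema.names + ["subgroup"])
        extra = [c for c in df.columns if c not in known]
        if extra:
            raise SchemaError(f"columns not in schema: {extra}")

        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValidationError(f"duplicate subject_id {dup!r}")
        bad_arm = ~df["arm"].isin(ARMS)
        if bad_arm.any():
            raise ValidationError(
                f"invalid arm value {df.loc[bad_arm, 'arm'].iloc[0]!r}"
            )

        # Follow-up: longitudinal rows (arm != none) carry time/event once the
        # columns exist; cross-sectional rows never do. A table with arms
        # assigned but no outcome columns yet is a legal intermediate stage.
        has_followup = "time" in df.columns or "event" in df.columns
        longitudinal = df["arm"] != "none"
        if has_followup:
            for col in OUTCOME_COLS:
                if col not in df.columns:
                    raise SchemaError(f"missing required column {col!r}")
            sub = df.loc[longitudinal]
            t = pd.to_numeric(sub["time"], errors="coerce")
            if t.isna().any() or (t <= 0).any():
                row = sub.index[(t.isna() | (t <= 0)).to_numpy()][0]
                raise ValidationError(
                    f"row {df.loc[row, 'subject_id']!r}: time must be > 0"
                )
            e = sub["event"]
            if not e.isin([0, 1]).all():
                row = sub.index[~e.isin([0, 1]).to_numpy()][0]
                raise ValidationError(
                    f"row {df.loc[row, 'subject_id']!r}: event must be 0 or 1"
                )
            cross = df.loc[~longitudinal]
            if not (cross["time"].isna().all() and cross["event"].isna().all()):
                raise ValidationError("arm='none' rows must have empty time/event")

        for spec in self.schema.covariates:
            col = pd.to_numeric(df[spec.name], errors="coerce")
            present = df[spec.name].notna()
            vals = col[present]
            if present.any() and vals.isna().any():
                row = vals.index[vals.isna().to_numpy()][0]
                raise ValidationError(
                    f"row {df.loc[row, 'subject_id']!r}: "
                    f"non-numeric value in {spec.name!r}"
                )
            if spec.kind == "binary":
                ok = vals.isin([0, 1])
                if not ok.all():
                    row = vals.index[~ok.to_numpy()][0]
                    raise ValidationError(
                        f"row {df.loc[row, 'subject_id']!r}: "
                        f"{spec.name!r} must be 0 or 1"
                    )
            else:
                bad = ~np.isfinite(vals) | (vals < spec.lo) | (vals > spec.hi)
                if bad.any():
                    row = vals.index[bad.to_numpy()][0]
                    raise ValidationError(
                        f"row {df.loc[row, 'subject_id']!r}: {spec.name!r} value "
                        f"{vals[row]} outside [{spec.lo}, {spec.hi}]"
                    )

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def sources(self) -> list[str]:
        return sorted(self.df["source"].unique())

    def subset(self, mask) -> "CohortTable":
        return CohortTable(self.df.loc[mask].copy(), self.schema)

    def covariate_matrix(self, names: list[str] | None = None) -> pd.DataFrame:
        names = names if names is not None else self.schema.names
        return self.df[names].astype(float)


# ---------------------------------------------------------------------------
# I/O: comma-delimited UTF-8, header row, missing encoded as empty field
# ---------------------------------------------------------------------------

def read_cohort(path, schema: CovariateSchema) -> CohortTable:
    """Read a delimited cohort table, validating against `schema`.

    The file must be comma-delimited UTF-8 with a header row naming the
    id/arm columns and every schema covariate. Decimal point is always
    ``.``, independent of locale; missing values are empty fields.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "source": str, "arm": str})
    return CohortTable(df, schema)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort table as comma-delimited UTF-8 (missing = empty field)."""
    df = cohort.df.copy()
    for name in cohort.schema.binary:
        present = df[name].notna()
        df[name] = df[name].astype("object")
        df.loc[present, name] = df.loc[present, name].astype(int)
    if "event" in df.columns:
        present = df["event"].notna()
        df["event"] = df["event"].astype("object")
        df.loc[present, "event"] = df.loc[present, "event"].astype(int)
    df.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


# ---------------------------------------------------------------------------


def complete_case_filter(
    cohort: CohortTable, required: list[str]
) -> tuple[CohortTable, int]:
    """Drop every subject missing any of the `required` covariates.

    Returns the filtered cohort and the number of dropped subjects.
    Raises if no complete case remains (an empty analysis set is always an
    error, never a silent empty table).
    """
    unknown = [c for c in required if c not in cohort.schema]
    if unknown:
        raise SchemaError(f"required covariates not in schema: {unknown}")
    if not required:
        return cohort, 0
    keep = cohort.df[list(required)].notna().all(axis=1)
    dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValidationError("no complete cases remain after filtering")
    return cohort.subset(keep), dropped


def describe_and_compare(a: CohortTable, b: CohortTable) -> pd.DataFrame:
    """Baseline table comparing two cohorts covariate by covariate.

    Continuous covariates are summarized as mean (SD) and compared with a
    two-sample t-test; binary covariates as count (%) with a Pearson
    chi-square test (no continuity correction). A covariate constant and
    identical in both groups gets p = 1 with ``degenerate=True``.
    """
    if a.schema.names != b.schema.names:
        raise SchemaError("cohorts must share a covariate schema")
    rows = []
    for spec in a.schema.covariates:
        xa = a.df[spec.name].dropna().astype(float).to_numpy()
        xb = b.df[spec.name].dropna().astype(float).to_numpy()
        degenerate = False
        if spec.kind == "continuous":
            summary_a = f"{xa.mean():.2f} ({xa.std(ddof=1):.2f})"
            summary_b = f"{xb.mean():.2f} ({xb.std(ddof=1):.2f})"
            diff = xa.mean() - xb.mean()
            if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
                degenerate = True
                p = 1.0
            else:
                p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        else:
            ka, kb = int(xa.sum()), int(xb.sum())
            summary_a = f"{ka} ({100 * ka / len(xa):.1f}%)"
            summary_b = f"{kb} ({100 * kb / len(xb):.1f}%)"
            diff = ka / len(xa) - kb / len(xb)
            table = np.array([[ka, len(xa) - ka], [kb, len(xb) - kb]])
            if (table.sum(axis=0) == 0).any():
                degenerate = True
                p = 1.0
            else:
                p = float(stats.chi2_contingency(table, correction=False)[1])
        rows.append(
            {
                "covariate": spec.name,
                "kind": spec.kind,
                "group_a": summary_a,
                "group_b": summary_b,
                "difference": diff,
                "p_value": p,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
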