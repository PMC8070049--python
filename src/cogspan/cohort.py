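"""Cohort tables and the participant exclusion cascade.

The analysis operates on a participant-level table: one row per person
with age, sex, twelve cognitive test scores and questionnaire covariates.
Raw cohorts pass through three filters, in order: completeness (all tests
and all questionnaire items answered), a two-pass standard-deviation
outlier screen on the test scores, and an age window.  Each filter emits a
:class:`FilterReport` so the exclusion cascade can be audited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TEST_COLUMNS",
    "DOMAINS",
    "SEX_LEVELS",
    "DEFAULT_COVARIATE_TYPES",
    "CohortTable",
    "CohortSchemaError",
    "FilterReport",
    "read_cohort",
    "filter_complete",
    "filter_outliers_two_pass",
    "filter_age",
]

#: The twelve tests of the battery, in declared order.
TEST_COLUMNS: tuple[str, ...] = (
    "monkey_ladder",
    "grammatical_reasoning",
    "double_trouble",
    "odd_one_out",
    "spatial_span",
    "rotations",
    "feature_match",
    "digit_span",
    "spatial_planning",
    "paired_associates",
    "interlocking_polygons",
    "token_search",
)

#: The three composite cognitive domains.
DOMAINS: tuple[str, ...] = ("wm", "verbal", "reasoning")

SEX_LEVELS: tuple[str, str] = ("female", "male")

#: Questionnaire covariates shipped by the synthetic generator.
DEFAULT_COVARIATE_TYPES: dict[str, str] = {
    "sleep_hours": "continuous",
    "caffeine_units": "continuous",
    "anxiety": "ordinal",
    "education": "ordinal",
    "exercise": "ordinal",
    "tech_savvy": "categorical",
}

_VAR_TYPES = ("continuous", "ordinal", "categorical")


class CohortSchemaError(ValueError):
    """The input file does not satisfy the cohort schema."""


@dataclass
class CohortTable:
    """Participant-level cohort table.

    Parameters
    ----------
    data : DataFrame
        Must contain ``participant_id`` (unique), ``age``, ``sex``
        (levels within {"female", "male"}), the twelve test columns and
        the declared covariate columns.
    covariate_types : dict
        Maps covariate column name to "continuous" | "ordinal" |
        "categorical".
    """

    data: pd.DataFrame
    covariate_types: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_TYPES)
    )
    test_columns: tuple[str, ...] = TEST_COLUMNS

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        df = self.data
        required = ["participant_id", "age", "sex", *self.test_columns,
                    *self.covariate_types]
        for col in required:
            if col not in df.columns:
                raise CohortSchemaError(f"missing mandatory column: {col!r}")
        if len(self.test_columns) != 12:
            raise CohortSchemaError("exactly 12 test-score columns required")
        if df["participant_id"].duplicated().any():
            dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
            raise CohortSchemaError(f"duplicate participant_id: {dup!r}")
        levels = set(df["sex"].dropna().unique())
        if not levels <= set(SEX_LEVELS):
            bad = sorted(levels - set(SEX_LEVELS))
            raise CohortSchemaError(
                f"sex must take levels {SEX_LEVELS}, found {bad}"
            )
        for name, vt in self.covariate_types.items():
            if vt not in _VAR_TYPES:
                raise CohortSchemaError(
                    f"covariate {name!r} has unknown type {vt!r}"
                )

    # -- convenience --------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def covariate_columns(self) -> list[str]:
        return list(self.covariate_types)

    def scores(self) -> pd.DataFrame:
        """The N x 12 test-score block, in declared column order."""
        return self.data.loc[:, list(self.test_columns)]

    def subset(self, mask) -> "CohortTable":
        return CohortTable(
            self.data.loc[mask].reset_index(drop=True),
            covariate_types=dict(self.covariate_types),
            test_columns=self.test_columns,
        )

    def write_csv(self, path: str | Path, sep: str = ",") -> None:
        self.data.to_csv(path, sep=sep, index=False)


@dataclass
class FilterReport:
    """Bookkeeping for one stage of the exclusion cascade."""

    stage: str
    n_before: int
    n_removed: int
    n_after: int
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_before - self.n_removed != self.n_after:
            raise ValueError("n_before - n_removed must equal n_after")
        if min(self.n_before, self.n_removed, self.n_after) < 0:
            raise ValueError("counts must be non-negative")

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_before": int(self.n_before),
            "n_removed": int(self.n_removed),
            "n_after": int(self.n_after),
            "details": self.details,
        }


def read_cohort(
    path: str | Path,
    covariate_types: dict[str, str] | None = None,
    column_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> CohortTable:
    """Read a delimited cohort file into a validated :class:`CohortTable`.

    Parameters
    ----------
    path : path
        Delimited text with a header row (comma by default, tab accepted;
        the delimiter is sniffed when ``sep`` is None).
    covariate_types : dict, optional
        Covariate name -> variable type; defaults to the generator's
        covariate battery.
    column_map : dict, optional
        Maps canonical column names to the names used in the file, for
        files with non-standard headers.

    Raises
    ------
    CohortSchemaError
        On a missing mandatory column, a duplicate participant id, an
        out-of-contract sex level, or an unparseable age/score (reported
        with its line number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype="object")
    else:
        df = pd.read_csv(path, sep=sep, dtype="object")
    if column_map:
        missing_src = [v for v in column_map.values() if v not in df.columns]
        if missing_src:
            raise CohortSchemaError(
                f"missing mandatory column: {missing_src[0]!r}"
            )
        df = df.rename(columns={v: k for k, v in column_map.items()})

    cov_types = dict(covariate_types or DEFAULT_COVARIATE_TYPES)
    required = ["participant_id", "age", "sex", *TEST_COLUMNS, *cov_types]
    for col in required:
        if col not in df.columns:
            raise CohortSchemaError(f"missing mandatory column: {col!r}")

    numeric_cols = ["age", *TEST_COLUMNS] + [
        c for c, t in cov_types.items() if t in ("continuous", "ordinal")
    ]
    for col in numeric_cols:
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortSchemaError(
                f"unparseable value {raw.iloc[row]!r} in column {col!r} "
                f"at line {row + 2}"  # 1-based, after the header
            )
        df[col] = parsed
    df["sex"] = df["sex"].astype(str)
    return CohortTable(df.reset_index(drop=True), covariate_types=cov_types)


def filter_complete(table: CohortTable) -> tuple[CohortTable, FilterReport]:
    """Keep participants with all 12 tests and all questionnaire items present."""
    cols = [*table.test_columns, *table.covariate_columns]
    block = table.data.loc[:, cols]
    missing_by_col = block.isna().sum()
    keep = ~block.isna().any(axis=1)
    out = table.subset(keep)
    report = FilterReport(
        stage="complete",
        n_before=table.n,
        n_removed=int((~keep).sum()),
        n_after=out.n,
        details={"missing_per_column": {
            c: int(v) for c, v in missing_by_col.items() if v > 0
        }},
    )
    return out, report


def _pass_mask(scores: pd.DataFrame, k: float) -> tuple[pd.Series, dict]:
    """Row mask of survivors for one SD-screen pass; strict ``> k`` removal."""
    remove = pd.Series(False, index=scores.index)
    per_col: dict[str, int] = {}
    for col in scores.columns:
        v = scores[col]
        mu = v.mean()
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(
                f"test column {col!r} has zero variance; outlier screen skipped",
                UserWarning,
                stacklevel=3,
            )
            continue
        flag = (v - mu).abs() / sd > k
        if flag.any():
            per_col[col] = int(flag.sum())
        remove |= flag
    return ~remove, per_col


def filter_outliers_two_pass(
    table: CohortTable, k1: float = 6.0, k2: float = 4.0
) -> tuple[CohortTable, FilterReport]:
    """Two-pass SD screen on the test scores, removing whole participants.

    Pass 1 removes any participant with a test score more than ``k1``
    sample SDs from that column's mean (presumed technical errors).  Pass 2
    recomputes each column's mean and SD on the survivors and removes
    participants beyond ``k2`` SDs of the recalculated mean (performance
    outliers).  Distances use the sample (n-1) SD and strict inequality.

    Re-running the filter after removals may remove more rows (masking):
    the screen is only idempotent when nothing was removed.
    """
    if not k1 > k2 > 0:
        raise ValueError("require k1 > k2 > 0")
    if table.n < 3:
        raise ValueError("need at least 3 rows per test column")
    keep1, cols1 = _pass_mask(table.scores(), k1)
    after1 = table.subset(keep1)
    keep2, cols2 = _pass_mask(after1.scores(), k2)
    out = after1.subset(keep2)
    report = FilterReport(
        stage="outliers_two_pass",
        n_before=table.n,
        n_removed=table.n - out.n,
        n_after=out.n,
        details={
            "pass1": {"k": k1, "n_removed": table.n - after1.n,
                      "per_column": cols1},
            "pass2": {"k": k2, "n_removed": after1.n - out.n,
                      "per_column": cols2},
        },
    )
    return out, report


def filter_age(
    table: CohortTable, min_age: float = 12, max_age: float = 69
) -> tuple[CohortTable, FilterReport]:
    """Keep participants with ``min_age <= age <= max_age`` (closed interval)."""
    if not min_age < max_age:
        raise ValueError("min_age must be below max_age")
    age = table.data["age"]
    keep = (age >= min_age) & (age <= max_age)
    out = table.subset(keep)
    report = FilterReport(
        stage="age_window",
        n_before=table.n,
        n_removed=int((~keep).sum()),
        n_after=out.n,
        details={"min_age": min_age, "max_age": max_age},
    )
    return out, report
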