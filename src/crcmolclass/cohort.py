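"""Cohort data model and TSV interchange format.

A cohort is a flat per-tumour table: ternary molecular calls
(altered / wild-type / missing) for eleven alterations, clinico-pathological
covariates, and a disease-free-survival outcome.  The TSV dialect is the
single interchange object between every analysis stage:

* UTF-8, tab-separated, header row, one row per tumour;
* molecular calls coded ``1`` (altered), ``0`` (wild-type), ``NA`` (missing);
* the missing token is always ``NA``;
* ``age`` and ``dfs_years`` are serialized with 3 decimal places.

No public per-tumour data format exists for this kind of study; the schema
here is the package's own and is documented as such.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path

import numpy as np
import pandas as pd

#: The seven molecular variables used by the network / clustering / classifier
#: stages, in canonical order.
CORE_MARKERS = ("cin", "msi", "kras", "nras", "braf", "pik3ca", "tp53")

#: All eleven molecular call columns.
MARKERS = CORE_MARKERS + ("fbxw7", "loh5q", "loh17p", "loh18q")

#: Closed vocabularies for categorical covariates.
CATEGORICAL_LEVELS = {
    "sex": ("male", "female"),
    "site": ("proximal", "distal"),
    "stage": ("II", "III"),
    "grade": ("well", "moderate", "poor"),
    "arm": ("rofecoxib", "placebo"),
}

FLAG_COLUMNS = ("chemo", "radio")

COLUMNS = (
    ("tumour_id",)
    + MARKERS
    + ("sex", "age", "site", "stage", "grade", "arm", "chemo", "radio",
       "dfs_years", "dfs_event", "group")
)

MISSING_TOKEN = "NA"

#: Grade ordering used when grade enters a model as a continuous covariate.
GRADE_ORDER = {"well": 0, "moderate": 1, "poor": 2}

GROUP_LEVELS = ("1", "2", "3", "4", "5", "6", "7", "unclassifiable")


class SchemaError(ValueError):
    """Raised when a cohort file or frame violates the documented schema."""


@dataclasses.dataclass
class LoadReport:
    """Summary returned alongside a loaded cohort."""

    n_rows: int
    missing_per_column: dict[str, int]


@dataclasses.dataclass
class Cohort:
    """Per-tumour cohort table.

    Wraps a :class:`pandas.DataFrame` whose columns follow the documented
    schema.  Molecular calls are pandas nullable ``Int64`` with values
    {0, 1, <NA>}; survival time and age are floats; categorical covariates
    are plain strings from the closed vocabularies (or ``<NA>``).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        validate_frame(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def markers(self) -> pd.DataFrame:
        return self.df[list(MARKERS)]

    def core_marker_matrix(self, complete_cases: bool = True) -> pd.DataFrame:
        """Binary matrix over the seven core markers, indexed by tumour_id.

        With ``complete_cases`` (the default) rows with any missing core call
        are dropped, mirroring a fully-typed analysis subset.
        """
        m = self.df.set_index("tumour_id")[list(CORE_MARKERS)]
        if complete_cases:
            m = m.dropna()
        return m.astype("Int64")

    def missingness(self) -> dict[str, int]:
        return {c: int(self.df[c].isna().sum()) for c in self.df.columns}

    def copy(self) -> "Cohort":
        return Cohort(self.df.copy())


def empty_frame() -> pd.DataFrame:
    """Header-only frame with the right dtypes."""
    data: dict[str, pd.Series] = {}
    for c in COLUMNS:
        if c in MARKERS:
            data[c] = pd.Series(dtype="Int64")
        elif c in ("age", "dfs_years"):
            data[c] = pd.Series(dtype=float)
        elif c in ("dfs_event",) + FLAG_COLUMNS:
            data[c] = pd.Series(dtype="Int64")
        else:
            data[c] = pd.Series(dtype="string")
    return pd.DataFrame(data)


def validate_frame(df: pd.DataFrame) -> None:
    """Check the schema invariants, raising :class:`SchemaError` on violation."""
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing_cols)}")
    if df["tumour_id"].isna().any():
        raise SchemaError("tumour_id must not be missing")
    if df["tumour_id"].duplicated().any():
        dup = df["tumour_id"][df["tumour_id"].duplicated()].iloc[0]
        raise SchemaError(f"duplicate tumour_id: {dup!r}")
    for c in MARKERS:
        vals = df[c].dropna().unique()
        bad = [v for v in vals if v not in (0, 1)]
        if bad:
            raise SchemaError(f"column {c!r}: molecular calls must be 0/1/NA, got {bad[0]!r}")
    for c, levels in CATEGORICAL_LEVELS.items():
        vals = df[c].dropna().unique()
        bad = [v for v in vals if v not in levels]
        if bad:
            raise SchemaError(f"column {c!r}: value {bad[0]!r} not in {levels}")
    for c in ("age", "dfs_years"):
        v = pd.to_numeric(df[c], errors="coerce")
        if df[c].notna().any() and not np.isfinite(v.dropna()).all():
            raise SchemaError(f"column {c!r} must be finite")
    if (df["age"].dropna() <= 0).any():
        raise SchemaError("age must be positive")
    if (df["dfs_years"].dropna() < 0).any():
        raise SchemaError("dfs_years must be non-negative")
    bad_ev = df["dfs_event"].dropna()
    if not bad_ev.isin([0, 1]).all():
        raise SchemaError("dfs_event must be 0/1")
    g = df["group"].dropna()
    badg = [v for v in g.unique() if v not in GROUP_LEVELS]
    if badg:
        raise SchemaError(f"column 'group': value {badg[0]!r} not in {GROUP_LEVELS}")


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    out["tumour_id"] = df["tumour_id"].astype("string")
    for c in MARKERS:
        try:
            out[c] = df[c].astype("Int64")
        except (ValueError, TypeError) as exc:
            bad = df[c][pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise SchemaError(f"unparseable cell at row {row}, column {c!r}") from exc
    for c in ("sex", "site", "stage", "grade", "arm", "group"):
        out[c] = df[c].astype("string")
    for c in ("age", "dfs_years"):
        v = pd.to_numeric(df[c], errors="coerce")
        unparseable = v.isna() & df[c].notna()
        if unparseable.any():
            raise SchemaError(
                f"unparseable cell at row {unparseable.idxmax()}, column {c!r}"
            )
        out[c] = v
    for c in ("dfs_event",) + FLAG_COLUMNS:
        try:
            out[c] = df[c].astype("Int64")
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"unparseable value in column {c!r}") from exc
    return out[list(COLUMNS)]


def read_cohort(path: str | Path | io.TextIOBase) -> tuple[Cohort, LoadReport]:
    """Read a cohort TSV.

    Returns the cohort together with a load report (row count and per-column
    missingness).  Unknown codes or a missing mandatory column raise
    :class:`SchemaError` with coordinates.
    """
    raw = pd.read_csv(
        path,
        sep="\t",
        dtype="string",
        na_values=[MISSING_TOKEN],
        keep_default_na=False,
        comment="#",
    )
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing_cols)}")
    df = _coerce_types(raw)
    cohort = Cohort(df)
    report = LoadReport(n_rows=len(df), missing_per_column=cohort.missingness())
    return cohort, report


def write_cohort(cohort: Cohort, path: str | Path | io.TextIOBase) -> None:
    """Write a cohort to TSV so that ``read_cohort`` round-trips it exactly.

    Categorical fields round-trip bit-exactly; ``age`` and ``dfs_years`` are
    written with 3 decimals (hence equal after one round trip).
    """
    df = cohort.df.copy()
    for c in ("age", "dfs_years"):
        df[c] = df[c].map(lambda v: f"{v:.3f}" if pd.notna(v) else pd.NA)
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def from_records(records: list[dict]) -> Cohort:
    """Build a cohort from a list of per-tumour dicts, filling absent fields with NA."""
    df = pd.DataFrame(records)
    for c in COLUMNS:
        if c not in df.columns:
            df[c] = pd.NA
    return Cohort(_coerce_types(df))
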