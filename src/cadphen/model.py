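"""Domain model for a linked EHR cohort and delimited-text I/O.

The cohort mirrors the linkage structure of a UK-Biobank-style study: a
baseline participant table plus four event tables (hospital diagnoses,
hospital procedures, death registry, baseline self-report items), joinable
on an opaque participant id.  All tables are held as pandas DataFrames with
canonical column names; readers accept arbitrary column names through a
schema config.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

#: Last date of guaranteed-complete follow-up across all linked sources.
CENSOR_DATE = pd.Timestamp("2016-11-01")


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class CodeSystem(str, enum.Enum):
    ICD10 = "ICD10"
    ICD9 = "ICD9"
    OPCS4 = "OPCS4"
    SELFREPORT = "SELFREPORT"


#: Canonical columns per table. Date columns are parsed to datetime64[ns].
TABLE_COLUMNS: dict[str, list[str]] = {
    "participants": ["pid", "enrol_date", "sex", "age_at_enrol"],
    "diagnoses": ["pid", "code_system", "code", "position", "event_date"],
    "procedures": ["pid", "code_system", "code", "event_date"],
    "deaths": ["pid", "death_date", "code_system", "code", "role"],
    "self_reports": ["pid", "category", "item_code"],
}

DATE_COLUMNS = {"enrol_date", "event_date", "death_date"}

#: Self-report tokens recognised by default. The phenotyping rules only act
#: on the cardiovascular tokens; the rest are legal filler.
DEFAULT_SELFREPORT_VOCAB = frozenset(
    {
        "heart_attack",
        "angina",
        "cabg",
        "ptca",
        "angioplasty",
        "diabetes",
        "asthma",
        "hypertension",
    }
)


class SchemaError(ValueError):
    """A source file does not match the declared schema."""


class ValidationError(ValueError):
    """A structural invariant of the cohort is violated."""


@dataclass
class Cohort:
    """The five linked source tables, keyed on ``pid``.

    Invariants enforced at load time: ``pid`` unique in ``participants``;
    every ``pid`` appearing in an event table exists in ``participants``
    (violating rows go to the rejects report, never silently dropped).
    """

    participants: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame
    deaths: pd.DataFrame
    self_reports: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.participants)

    def death_dates(self) -> pd.Series:
        """One death date per pid that has any death-registry record."""
        if self.deaths.empty:
            return pd.Series(dtype="datetime64[ns]", name="death_date")
        return self.deaths.groupby("pid")["death_date"].first()

    def canonical(self) -> "Cohort":
        """Return a copy with tables in canonical row/column order."""
        sort_keys = {
            "participants": ["pid"],
            "diagnoses": ["pid", "event_date", "code_system", "code", "position"],
            "procedures": ["pid", "event_date", "code"],
            "deaths": ["pid", "role", "code"],
            "self_reports": ["pid", "category", "item_code"],
        }
        out = {}
        for name, cols in TABLE_COLUMNS.items():
            df = getattr(self, name)[cols].sort_values(sort_keys[name])
            out[name] = df.reset_index(drop=True)
        return Cohort(**out)


def _normalize_code_series(s: pd.Series) -> pd.Series:
    return s.astype(str).str.upper().str.replace(r"[.\s]", "", regex=True)


def load_schema_config(path: str | Path) -> dict:
    """YAML schema config: per-table mapping of logical field -> column name,
    plus an optional top-level ``delimiter``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def _read_table(
    path: str | Path,
    table: str,
    schema: Mapping[str, Mapping[str, str]] | None,
    delimiter: str,
) -> pd.DataFrame:
    colmap = dict((schema or {}).get(table, {}))
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in colmap.items()}
    df = df.rename(columns=rename)
    missing = [c for c in TABLE_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"table {table!r}: missing required column(s) {missing}")
    return df[TABLE_COLUMNS[table]].copy()


def read_cohort(
    paths: Mapping[str, str | Path],
    schema_config: Mapping | None = None,
) -> tuple[Cohort, pd.DataFrame]:
    """Read the five delimited tables into a :class:`Cohort`.

    Parameters
    ----------
    paths
        Mapping of table name (``participants``, ``diagnoses``, ``procedures``,
        ``deaths``, ``self_reports``) to file path.
    schema_config
        Optional mapping with a ``delimiter`` key (default ``","``) and
        per-table ``{logical_field: source_column}`` mappings.

    Returns
    -------
    (cohort, rejects)
        ``rejects`` is a DataFrame with columns ``table, row, reason`` listing
        every input row excluded from the cohort; nothing is silently dropped.
    """
    schema_config = schema_config or {}
    delimiter = schema_config.get("delimiter", ",")
    missing_files = [str(p) for p in paths.values() if not Path(p).exists()]
    if missing_files:
        raise FileNotFoundError(f"missing input file(s): {missing_files}")

    tables = {
        t: _read_table(paths[t], t, schema_config, delimiter) for t in TABLE_COLUMNS
    }
    rejects: list[dict] = []

    def reject(table: str, idx, reason: str) -> None:
        rejects.append({"table": table, "row": int(idx), "reason": reason})

    # participants: parse dates, validate uniqueness and enums
    part = tables["participants"]
    dup = part["pid"].duplicated()
    if dup.any():
        raise ValidationError(
            f"duplicate pid(s) in participants: {sorted(part.loc[dup, 'pid'].unique())[:5]}"
        )
    part["enrol_date"] = pd.to_datetime(part["enrol_date"], errors="coerce")
    bad_enrol = part["enrol_date"].isna()
    for i in part.index[bad_enrol]:
        reject("participants", i, "unparseable enrol_date")
    part = part[~bad_enrol]
    bad_sex = ~part["sex"].isin([s.value for s in Sex])
    for i in part.index[bad_sex]:
        reject("participants", i, "unknown sex")
    part = part[~bad_sex].copy()
    part["age_at_enrol"] = pd.to_numeric(part["age_at_enrol"], errors="coerce")
    known = set(part["pid"])

    def keep_known(table: str, df: pd.DataFrame) -> pd.DataFrame:
        orphan = ~df["pid"].isin(known)
        for i in df.index[orphan]:
            reject(table, i, "pid not in participants")
        return df[~orphan]

    def parse_dates(table: str, df: pd.DataFrame, col: str) -> pd.DataFrame:
        parsed = pd.to_datetime(df[col], errors="coerce")
        bad = parsed.isna()
        for i in df.index[bad]:
            reject(table, i, f"missing or unparseable {col}")
        df = df[~bad].copy()
        df[col] = parsed[~bad]
        return df

    def norm_codes(table: str, df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        df["code"] = _normalize_code_series(df["code"])
        empty = df["code"] == ""
        for i in df.index[empty]:
            reject(table, i, "empty code after normalization")
        return df[~empty]

    dx = keep_known("diagnoses", tables["diagnoses"])
    dx = parse_dates("diagnoses", dx, "event_date")
    dx = norm_codes("diagnoses", dx)

    proc = keep_known("procedures", tables["procedures"])
    proc = parse_dates("procedures", proc, "event_date")
    proc = norm_codes("procedures", proc)

    deaths = keep_known("deaths", tables["deaths"])
    deaths = parse_dates("deaths", deaths, "death_date")
    deaths = norm_codes("deaths", deaths)
    # one death date per pid: rows disagreeing with the first-seen date are rejected
    if not deaths.empty:
        first = deaths.groupby("pid")["death_date"].transform("first")
        clash = deaths["death_date"] != first
        for i in deaths.index[clash]:
            reject("deaths", i, "conflicting death_date for pid")
        deaths = deaths[~clash]

    sr = keep_known("self_reports", tables["self_reports"])

    cohort = Cohort(
        participants=part.reset_index(drop=True),
        diagnoses=dx.reset_index(drop=True),
        procedures=proc.reset_index(drop=True),
        deaths=deaths.reset_index(drop=True),
        self_reports=sr.reset_index(drop=True),
    ).canonical()
    rejects_df = pd.DataFrame(rejects, columns=["table", "row", "reason"])
    return cohort, rejects_df


def write_cohort(cohort: Cohort, out_dir: str | Path, delimiter: str = ",") -> dict[str, Path]:
    """Write the five tables as delimited text in canonical order.

    Dates are serialized as ISO ``YYYY-MM-DD``; round-trips through
    :func:`read_cohort` byte-for-byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    canon = cohort.canonical()
    written = {}
    for name in TABLE_COLUMNS:
        df = getattr(canon, name).copy()
        for col in df.columns:
            if col in DATE_COLUMNS:
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = out_dir / f"{name}.csv"
        df.to_csv(path, sep=delimiter, index=False)
        written[name] = path
    return written


def cohort_paths(directory: str | Path) -> dict[str, Path]:
    """Standard per-table file paths inside a cohort directory."""
    d = Path(directory)
    return {name: d / f"{name}.csv" for name in TABLE_COLUMNS}


@dataclass
class ValidationReport:
    """Counts of suspect records; reporting only, data is never mutated."""

    n_death_before_enrol: int = 0
    n_events_after_censor: int = 0
    n_unknown_code_system: int = 0
    n_unknown_selfreport_items: int = 0
    details: dict = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return (
            self.n_death_before_enrol == 0
            and self.n_events_after_censor == 0
            and self.n_unknown_code_system == 0
            and self.n_unknown_selfreport_items == 0
        )


def validate_cohort(
    cohort: Cohort,
    censor_date: pd.Timestamp = CENSOR_DATE,
    selfreport_vocab: frozenset[str] = DEFAULT_SELFREPORT_VOCAB,
) -> ValidationReport:
    """Flag dirty-data patterns: deaths predating enrolment, events after the
    censor date, unknown code systems or self-report tokens."""
    report = ValidationReport()
    dd = cohort.death_dates()
    if not dd.empty:
        enrol = cohort.participants.set_index("pid")["enrol_date"]
        joined = pd.concat([dd, enrol], axis=1, join="inner")
        report.n_death_before_enrol = int(
            (joined["death_date"] < joined["enrol_date"]).sum()
        )
    n_after = 0
    for table, col in (("diagnoses", "event_date"), ("procedures", "event_date"), ("deaths", "death_date")):
        df = getattr(cohort, table)
        if not df.empty:
            n_after += int((df[col] > censor_date).sum())
    report.n_events_after_censor = n_after

    systems = {s.value for s in CodeSystem}
    n_unknown = 0
    for table in ("diagnoses", "procedures", "deaths"):
        df = getattr(cohort, table)
        if not df.empty:
            n_unknown += int((~df["code_system"].isin(systems)).sum())
    report.n_unknown_code_system = n_unknown

    if not cohort.self_reports.empty:
        report.n_unknown_selfreport_items = int(
            (~cohort.self_reports["item_code"].isin(selfreport_vocab)).sum()
        )
    return report
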