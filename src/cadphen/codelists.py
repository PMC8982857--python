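"""Clinical code lists and dated qualifying-event extraction.

A phenotype code list is a set of normalized code *prefixes*, each tagged
with a coding system (ICD-10, ICD-9, OPCS-4) and a disease tag (``MI`` or
``CAD_noMI``).  Matching is longest-prefix-wins within a coding system, so
an exclusion such as "I25 counts as CAD without MI, except I25.2 which is
old MI" is expressed by listing both prefixes: the longer, more specific
entry shadows the shorter one.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .model import CENSOR_DATE, CodeSystem, Cohort


class PhenotypeTag(str, enum.Enum):
    MI = "MI"
    CAD_noMI = "CAD_noMI"


class EventSource(str, enum.Enum):
    hospital_dx = "hospital_dx"
    hospital_proc = "hospital_proc"
    death_registry = "death_registry"
    selfreport_proc = "selfreport_proc"


class InvalidCodeError(ValueError):
    pass


class AmbiguousCodeListError(ValueError):
    """Two entries with the same (code_system, prefix) carry different tags."""


class ConfigError(ValueError):
    pass


def normalize_code(raw: str, code_system: CodeSystem | str | None = None) -> str:
    """Uppercase and strip dots and whitespace from a clinical code.

    >>> normalize_code("I21.4")
    'I214'
    """
    if raw is None:
        raise InvalidCodeError("code is None")
    out = "".join(ch for ch in str(raw).upper() if ch not in ". \t\r\n")
    if not out:
        raise InvalidCodeError(f"code {raw!r} is empty after normalization")
    return out


@dataclass(frozen=True)
class CodeEntry:
    code_system: CodeSystem
    prefix: str
    phenotype_tag: PhenotypeTag
    description: str = ""

    def __post_init__(self):
        norm = normalize_code(self.prefix, self.code_system)
        if norm != self.prefix:
            object.__setattr__(self, "prefix", norm)


@dataclass
class CodeList:
    """Phenotype-tagged prefix set with longest-prefix-wins semantics."""

    entries: frozenset[CodeEntry]
    name: str = "codelist"
    version: str = "0"

    def __post_init__(self):
        self.entries = frozenset(self.entries)
        seen: dict[tuple[CodeSystem, str], PhenotypeTag] = {}
        for e in self.entries:
            key = (e.code_system, e.prefix)
            if key in seen and seen[key] != e.phenotype_tag:
                raise AmbiguousCodeListError(
                    f"prefix {e.prefix!r} in {e.code_system.value} tagged both "
                    f"{seen[key].value} and {e.phenotype_tag.value}"
                )
            seen[key] = e.phenotype_tag
        # index: code_system -> prefix -> entry, for longest-prefix matching
        self._by_system: dict[CodeSystem, dict[str, CodeEntry]] = {}
        for e in self.entries:
            self._by_system.setdefault(e.code_system, {})[e.prefix] = e
        self._max_len = {
            cs: max(len(p) for p in d) for cs, d in self._by_system.items()
        }

    def add(self, entry: CodeEntry) -> "CodeList":
        return CodeList(self.entries | {entry}, self.name, self.version)


def matches(
    code: str, codelist: CodeList, code_system: CodeSystem
) -> Optional[CodeEntry]:
    """Longest CodeList entry whose prefix is a prefix of ``code``.

    An entry never matches a code *shorter* than the entry itself, so the
    list prefix "I214" does not capture the bare three-character code "I21".
    """
    index = codelist._by_system.get(code_system)
    if not index:
        return None
    for ln in range(min(len(code), codelist._max_len[code_system]), 0, -1):
        entry = index.get(code[:ln])
        if entry is not None:
            return entry
    return None


# ---------------------------------------------------------------------------
# Default code lists (replaceable defaults; swap in study-specific lists via
# load_codelist_csv without code changes).

_DEFAULT_ENTRIES = [
    # MI: acute/subsequent MI and complications, old MI
    ("ICD10", "I21", "MI", "acute myocardial infarction"),
    ("ICD10", "I22", "MI", "subsequent myocardial infarction"),
    ("ICD10", "I23", "MI", "complications following acute MI"),
    ("ICD10", "I241", "MI", "Dressler syndrome"),
    ("ICD10", "I252", "MI", "old myocardial infarction"),
    ("ICD9", "410", "MI", "acute myocardial infarction"),
    ("ICD9", "412", "MI", "old myocardial infarction"),
    # CAD without MI: angina, other acute/chronic IHD (I25 minus I25.2 which
    # the MI entry above shadows via longest-prefix-wins)
    ("ICD10", "I20", "CAD_noMI", "angina pectoris"),
    ("ICD10", "I240", "CAD_noMI", "coronary thrombosis without MI"),
    ("ICD10", "I248", "CAD_noMI", "other acute ischaemic heart disease"),
    ("ICD10", "I249", "CAD_noMI", "acute ischaemic heart disease, unspecified"),
    ("ICD10", "I25", "CAD_noMI", "chronic ischaemic heart disease"),
    # OPCS-4 coronary revascularisation and related procedures
    ("OPCS4", "K40", "CAD_noMI", "saphenous vein graft replacement of coronary artery"),
    ("OPCS4", "K41", "CAD_noMI", "other autograft replacement of coronary artery"),
    ("OPCS4", "K42", "CAD_noMI", "allograft replacement of coronary artery"),
    ("OPCS4", "K43", "CAD_noMI", "prosthetic replacement of coronary artery"),
    ("OPCS4", "K44", "CAD_noMI", "other replacement of coronary artery"),
    ("OPCS4", "K45", "CAD_noMI", "connection of thoracic artery to coronary artery"),
    ("OPCS4", "K46", "CAD_noMI", "other bypass of coronary artery"),
    ("OPCS4", "K49", "CAD_noMI", "transluminal balloon angioplasty of coronary artery"),
    ("OPCS4", "K50", "CAD_noMI", "other therapeutic transluminal operations on coronary artery"),
    ("OPCS4", "K75", "CAD_noMI", "percutaneous transluminal balloon angioplasty with stenting"),
]

#: Self-report questionnaire/interview tokens the rules act on.
SELFREPORT_ILLNESS_MI = "heart_attack"
SELFREPORT_ILLNESS_CAD = "angina"
SELFREPORT_PROCEDURES = frozenset({"cabg", "ptca", "angioplasty"})


def default_codelist() -> CodeList:
    """Default MI / CAD-without-MI prefix lists (ICD-10, ICD-9, OPCS-4)."""
    return CodeList(
        frozenset(
            CodeEntry(CodeSystem(cs), p, PhenotypeTag(t), d)
            for cs, p, t, d in _DEFAULT_ENTRIES
        ),
        name="cad-default",
        version="1",
    )


def load_codelist_csv(path: str | Path, name: str | None = None) -> CodeList:
    """Load a code list from CSV with columns
    ``code_system, code, phenotype_tag, description``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"code_system", "code", "phenotype_tag"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"code-list CSV missing column(s) {sorted(missing)}")
    entries = frozenset(
        CodeEntry(
            CodeSystem(row.code_system),
            row.code,
            PhenotypeTag(row.phenotype_tag),
            getattr(row, "description", ""),
        )
        for row in df.itertuples()
    )
    return CodeList(entries, name=name or Path(path).stem)


def write_codelist_csv(codelist: CodeList, path: str | Path) -> None:
    rows = sorted(
        (e.code_system.value, e.prefix, e.phenotype_tag.value, e.description)
        for e in codelist.entries
    )
    pd.DataFrame(
        rows, columns=["code_system", "code", "phenotype_tag", "description"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Event extraction


@dataclass(frozen=True)
class QualifyingEvent:
    pid: str
    phenotype_tag: PhenotypeTag
    event_date: Optional[pd.Timestamp]  # None only for self-reported procedures
    source: EventSource
    code: str


#: Which disease tags each source may contribute, by default all of the
#: combinations the record types admit. Self-reported procedures are
#: revascularisations, hence CAD-without-MI evidence only.
DEFAULT_ELIGIBLE_SOURCES: dict[EventSource, frozenset[PhenotypeTag]] = {
    EventSource.hospital_dx: frozenset({PhenotypeTag.MI, PhenotypeTag.CAD_noMI}),
    EventSource.hospital_proc: frozenset({PhenotypeTag.MI, PhenotypeTag.CAD_noMI}),
    EventSource.death_registry: frozenset({PhenotypeTag.MI, PhenotypeTag.CAD_noMI}),
    EventSource.selfreport_proc: frozenset({PhenotypeTag.CAD_noMI}),
}


@dataclass
class ExtractionConfig:
    """Controls which sources and diagnosis positions yield events."""

    censor_date: pd.Timestamp = CENSOR_DATE
    primary_position_only: bool = False
    eligible_sources: dict = field(
        default_factory=lambda: dict(DEFAULT_ELIGIBLE_SOURCES)
    )

    def __post_init__(self):
        unknown = set(self.eligible_sources) - set(EventSource)
        if unknown:
            raise ConfigError(f"unknown event source(s) in config: {unknown}")


def _match_frame(
    df: pd.DataFrame, codelist: CodeList
) -> pd.DataFrame:
    """Annotate rows with the matched tag; unmatched rows are dropped."""
    if df.empty:
        return df.assign(phenotype_tag=pd.Series(dtype=object))
    systems = {s.value: s for s in CodeSystem}
    tags = []
    for cs_raw, code in zip(df["code_system"], df["code"]):
        cs = systems.get(cs_raw)
        entry = matches(code, codelist, cs) if cs else None
        tags.append(entry.phenotype_tag if entry else None)
    out = df.assign(phenotype_tag=tags)
    return out[out["phenotype_tag"].notna()]


def extract_events(
    cohort: Cohort,
    codelist: CodeList,
    config: ExtractionConfig | None = None,
) -> list[QualifyingEvent]:
    """Scan the cohort's event tables for code-list matches.

    Hospital diagnoses and procedures yield events at their admission date;
    death-registry causes (underlying and contributing) yield events at the
    death date; self-reported revascularisation procedures yield undated
    events.  Events after the censor date are dropped.  Output is sorted by
    (pid, event_date, source, code).
    """
    config = config or ExtractionConfig()
    events: list[QualifyingEvent] = []

    def eligible(source: EventSource, tag: PhenotypeTag) -> bool:
        return tag in config.eligible_sources.get(source, frozenset())

    dx = cohort.diagnoses
    if config.primary_position_only and not dx.empty:
        dx = dx[dx["position"] == "primary"]
    for df, source, date_col in (
        (dx, EventSource.hospital_dx, "event_date"),
        (cohort.procedures, EventSource.hospital_proc, "event_date"),
        (cohort.deaths, EventSource.death_registry, "death_date"),
    ):
        matched = _match_frame(df, codelist)
        if matched.empty:
            continue
        matched = matched[matched[date_col] <= config.censor_date]
        for row in matched.itertuples():
            tag = row.phenotype_tag
            if eligible(source, tag):
                events.append(
                    QualifyingEvent(row.pid, tag, getattr(row, date_col), source, row.code)
                )

    sr = cohort.self_reports
    if not sr.empty:
        proc_rows = sr[
            (sr["category"] == "procedure") & sr["item_code"].isin(SELFREPORT_PROCEDURES)
        ]
        for row in proc_rows.itertuples():
            if eligible(EventSource.selfreport_proc, PhenotypeTag.CAD_noMI):
                events.append(
                    QualifyingEvent(
                        row.pid,
                        PhenotypeTag.CAD_noMI,
                        None,
                        EventSource.selfreport_proc,
                        row.item_code,
                    )
                )

    events.sort(
        key=lambda e: (
            e.pid,
            e.event_date if e.event_date is not None else pd.Timestamp.min,
            e.source.value,
            e.code,
        )
    )
    return events


def events_frame(events: Iterable[QualifyingEvent]) -> pd.DataFrame:
    """Tabular view of qualifying events (one row per event)."""
    return pd.DataFrame(
        [
            {
                "pid": e.pid,
                "phenotype_tag": e.phenotype_tag.value,
                "event_date": e.event_date,
                "source": e.source.value,
                "code": e.code,
            }
            for e in events
        ],
        columns=["pid", "phenotype_tag", "event_date", "source", "code"],
    )
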