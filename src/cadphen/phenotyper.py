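"""Hierarchical assignment of CAD sub-phenotypes and control labels.

Every participant receives exactly one of eight labels.  The hierarchy runs
in fixed order and a participant matched at a step is censored from all
later steps:

1. EHR-coded MI (hospital diagnosis or death-registry cause) →
   ``prevalent_MI`` / ``incident_MI`` by date relative to enrolment.
2. EHR-coded CAD without MI (hospital diagnosis, revascularisation
   procedure, death-registry cause) or self-reported revascularisation →
   ``prevalent_CAD_noMI`` / ``incident_CAD_noMI``.
3. Self-reported heart attack at the baseline interview → ``sr_MI``.
4. Self-reported angina at the baseline interview → ``sr_CAD_noMI``.
5. Otherwise a CAD-free control: ``never_CAD`` if the participant has since
   died, ``no_CAD`` if alive at censoring.

When a participant has qualifying events both before and after enrolment
within one disease tag, a single global switch decides whether they count
as prevalent or incident (default: incident, the more recent event having
greater certainty of date and diagnosis).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import CENSOR_DATE, Cohort
from .codelists import (
    CodeList,
    EventSource,
    ExtractionConfig,
    PhenotypeTag,
    QualifyingEvent,
    SELFREPORT_ILLNESS_CAD,
    SELFREPORT_ILLNESS_MI,
    events_frame,
    extract_events,
)


class PhenotypeLabel(str, enum.Enum):
    prevalent_MI = "prevalent_MI"
    incident_MI = "incident_MI"
    prevalent_CAD_noMI = "prevalent_CAD_noMI"
    incident_CAD_noMI = "incident_CAD_noMI"
    sr_MI = "sr_MI"
    sr_CAD_noMI = "sr_CAD_noMI"
    never_CAD = "never_CAD"
    no_CAD = "no_CAD"


CASE_LABELS: tuple[PhenotypeLabel, ...] = (
    PhenotypeLabel.prevalent_MI,
    PhenotypeLabel.incident_MI,
    PhenotypeLabel.prevalent_CAD_noMI,
    PhenotypeLabel.incident_CAD_noMI,
    PhenotypeLabel.sr_MI,
    PhenotypeLabel.sr_CAD_noMI,
)
CONTROL_LABELS: tuple[PhenotypeLabel, ...] = (
    PhenotypeLabel.never_CAD,
    PhenotypeLabel.no_CAD,
)

#: Hierarchy step at which each label is assigned (1 = earliest). Adding
#: disease evidence can only move a participant to a smaller step.
HIERARCHY_STEP: dict[PhenotypeLabel, int] = {
    PhenotypeLabel.prevalent_MI: 1,
    PhenotypeLabel.incident_MI: 1,
    PhenotypeLabel.prevalent_CAD_noMI: 2,
    PhenotypeLabel.incident_CAD_noMI: 2,
    PhenotypeLabel.sr_MI: 3,
    PhenotypeLabel.sr_CAD_noMI: 4,
    PhenotypeLabel.never_CAD: 5,
    PhenotypeLabel.no_CAD: 5,
}


@dataclass
class AlgorithmConfig:
    """Run-wide knobs of the classification algorithm."""

    censor_date: pd.Timestamp = CENSOR_DATE
    #: Resolution when one disease tag has events on both sides of enrolment.
    both_prevalent_and_incident_resolution: str = "incident"
    #: Side on which an event dated exactly on the enrolment date falls.
    on_enrolment_date_is: str = "prevalent"
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)

    def __post_init__(self):
        if self.both_prevalent_and_incident_resolution not in ("incident", "prevalent"):
            raise ValueError("resolution must be 'incident' or 'prevalent'")
        if self.on_enrolment_date_is not in ("prevalent", "incident"):
            raise ValueError("on_enrolment_date_is must be 'prevalent' or 'incident'")
        self.extraction.censor_date = self.censor_date


# ---------------------------------------------------------------------------
# Feature construction: one row per participant with the earliest qualifying
# event on each (tag, side) plus self-report flags.

_SIDE_COLS = [
    "mi_prev_date", "mi_prev_source", "mi_inc_date", "mi_inc_source",
    "cad_prev_date", "cad_prev_source", "cad_inc_date", "cad_inc_source",
]


def _feature_table(
    events: pd.DataFrame,
    participants: pd.DataFrame,
    self_reports: pd.DataFrame,
    death_dates: pd.Series,
    config: AlgorithmConfig,
) -> pd.DataFrame:
    feats = participants[["pid", "enrol_date"]].set_index("pid")
    for col in _SIDE_COLS:
        feats[col] = pd.NaT if col.endswith("date") else None
    feats["has_srproc"] = False

    if not events.empty:
        ev = events.merge(
            participants[["pid", "enrol_date"]], on="pid", how="left"
        )
        srproc = ev["source"] == EventSource.selfreport_proc.value
        feats.loc[ev.loc[srproc, "pid"].unique(), "has_srproc"] = True
        dated = ev[~srproc]
        if not dated.empty:
            if config.on_enrolment_date_is == "prevalent":
                prev_mask = dated["event_date"] <= dated["enrol_date"]
            else:
                prev_mask = dated["event_date"] < dated["enrol_date"]
            dated = dated.assign(side=np.where(prev_mask, "prev", "inc"))
            # earliest event per (pid, tag, side); sort gives deterministic
            # source/code tie-break at equal dates
            dated = dated.sort_values(["pid", "event_date", "source", "code"])
            first = dated.groupby(["pid", "phenotype_tag", "side"], sort=False).first()
            for (tag, short) in ((PhenotypeTag.MI.value, "mi"), (PhenotypeTag.CAD_noMI.value, "cad")):
                for side in ("prev", "inc"):
                    try:
                        sub = first.xs((tag, side), level=("phenotype_tag", "side"))
                    except KeyError:
                        continue
                    feats.loc[sub.index, f"{short}_{side}_date"] = sub["event_date"]
                    feats.loc[sub.index, f"{short}_{side}_source"] = sub["source"]

    feats["has_sr_mi"] = False
    feats["has_sr_cad"] = False
    if not self_reports.empty:
        ill = self_reports[self_reports["category"] == "illness"]
        mi_pids = ill.loc[ill["item_code"] == SELFREPORT_ILLNESS_MI, "pid"].unique()
        cad_pids = ill.loc[ill["item_code"] == SELFREPORT_ILLNESS_CAD, "pid"].unique()
        feats.loc[feats.index.intersection(mi_pids), "has_sr_mi"] = True
        feats.loc[feats.index.intersection(cad_pids), "has_sr_cad"] = True

    feats["death_date"] = death_dates.reindex(feats.index)
    # deaths after the censor date do not count as deaths for control labels
    feats.loc[feats["death_date"] > config.censor_date, "death_date"] = pd.NaT
    return feats


def _classify_table(feats: pd.DataFrame, config: AlgorithmConfig) -> pd.DataFrame:
    """Vectorized hierarchy over the per-participant feature table."""
    n = len(feats)
    label = pd.Series(pd.NA, index=feats.index, dtype=object)
    qdate = pd.Series(pd.NaT, index=feats.index, dtype="datetime64[ns]")
    source = pd.Series(pd.NA, index=feats.index, dtype=object)
    prefer_inc = config.both_prevalent_and_incident_resolution == "incident"

    def assign_tagged(
        mask: pd.Series,
        prev_date, prev_source, inc_date, inc_source,
        prev_label: PhenotypeLabel, inc_label: PhenotypeLabel,
        fallback_prev_source: Optional[str] = None,
        has_dateless_prev: Optional[pd.Series] = None,
    ) -> None:
        has_prev = prev_date.notna()
        if has_dateless_prev is not None:
            has_prev = has_prev | has_dateless_prev
        has_inc = inc_date.notna()
        hit = mask & (has_prev | has_inc)
        both = has_prev & has_inc
        inc_sel = hit & (has_inc & (~has_prev | (both & prefer_inc)))
        prev_sel = hit & ~inc_sel
        label[inc_sel] = inc_label
        qdate[inc_sel] = inc_date[inc_sel]
        source[inc_sel] = inc_source[inc_sel]
        label[prev_sel] = prev_label
        dated_prev = prev_sel & prev_date.notna()
        qdate[dated_prev] = prev_date[dated_prev]
        source[dated_prev] = prev_source[dated_prev]
        if has_dateless_prev is not None:
            # self-report-procedure-only prevalence: no reliable event date,
            # anchored at enrolment
            undated = prev_sel & prev_date.isna()
            qdate[undated] = feats.loc[undated, "enrol_date"]
            source[undated] = fallback_prev_source

    unassigned = label.isna()
    assign_tagged(
        unassigned,
        feats["mi_prev_date"], feats["mi_prev_source"],
        feats["mi_inc_date"], feats["mi_inc_source"],
        PhenotypeLabel.prevalent_MI, PhenotypeLabel.incident_MI,
    )
    unassigned = label.isna()
    assign_tagged(
        unassigned,
        feats["cad_prev_date"], feats["cad_prev_source"],
        feats["cad_inc_date"], feats["cad_inc_source"],
        PhenotypeLabel.prevalent_CAD_noMI, PhenotypeLabel.incident_CAD_noMI,
        fallback_prev_source=EventSource.selfreport_proc.value,
        has_dateless_prev=feats["has_srproc"],
    )

    unassigned = label.isna()
    sel = unassigned & feats["has_sr_mi"]
    label[sel] = PhenotypeLabel.sr_MI
    source[sel] = "selfreport"

    unassigned = label.isna()
    sel = unassigned & feats["has_sr_cad"]
    label[sel] = PhenotypeLabel.sr_CAD_noMI
    source[sel] = "selfreport"

    unassigned = label.isna()
    died = unassigned & feats["death_date"].notna()
    label[died] = PhenotypeLabel.never_CAD
    label[unassigned & ~died] = PhenotypeLabel.no_CAD

    out = pd.DataFrame(
        {
            "pid": feats.index,
            "label": [l.value for l in label],
            "qualifying_date": qdate.values,
            "source": source.values,
        }
    )
    assert len(out) == n
    return out


def classify_participant(
    events: Sequence[QualifyingEvent],
    participant: Mapping,
    self_reports: Iterable[Mapping] | pd.DataFrame = (),
    config: AlgorithmConfig | None = None,
) -> dict:
    """Classify a single participant; same rules as :func:`run_algorithm`.

    ``participant`` needs keys ``pid``, ``enrol_date`` and optionally
    ``death_date``; ``events`` must already be filtered to the censor date.
    """
    config = config or AlgorithmConfig()
    part = pd.DataFrame(
        [{"pid": participant["pid"], "enrol_date": pd.Timestamp(participant["enrol_date"])}]
    )
    sr = (
        self_reports
        if isinstance(self_reports, pd.DataFrame)
        else pd.DataFrame(list(self_reports), columns=["pid", "category", "item_code"])
    )
    dd = participant.get("death_date")
    deaths = pd.Series(
        [pd.Timestamp(dd)] if dd is not None and not pd.isna(dd) else [],
        index=[participant["pid"]] if dd is not None and not pd.isna(dd) else [],
        dtype="datetime64[ns]",
    )
    feats = _feature_table(events_frame(events), part, sr, deaths, config)
    row = _classify_table(feats, config).iloc[0]
    qd = row["qualifying_date"]
    return {
        "pid": row["pid"],
        "label": PhenotypeLabel(row["label"]),
        "qualifying_date": None if pd.isna(qd) else pd.Timestamp(qd),
        "source": None if pd.isna(row["source"]) else row["source"],
    }


def run_algorithm(
    cohort: Cohort,
    codelist: CodeList,
    config: AlgorithmConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full hierarchy over a cohort.

    Returns
    -------
    (assignments, log)
        ``assignments`` has one row per participant with columns
        ``pid, label, qualifying_date, source``; ``log`` records the count
        classified at each hierarchy step, in execution order.
    """
    config = config or AlgorithmConfig()
    events = extract_events(cohort, codelist, config.extraction)
    feats = _feature_table(
        events_frame(events),
        cohort.participants,
        cohort.self_reports,
        cohort.death_dates(),
        config,
    )
    assignments = _classify_table(feats, config)
    counts = assignments["label"].value_counts()
    log = {
        "step1_ehr_mi": {
            "prevalent_MI": int(counts.get("prevalent_MI", 0)),
            "incident_MI": int(counts.get("incident_MI", 0)),
        },
        "step2_ehr_cad_no_mi": {
            "prevalent_CAD_noMI": int(counts.get("prevalent_CAD_noMI", 0)),
            "incident_CAD_noMI": int(counts.get("incident_CAD_noMI", 0)),
        },
        "step3_selfreport_mi": {"sr_MI": int(counts.get("sr_MI", 0))},
        "step4_selfreport_cad": {"sr_CAD_noMI": int(counts.get("sr_CAD_noMI", 0))},
        "step5_controls": {
            "never_CAD": int(counts.get("never_CAD", 0)),
            "no_CAD": int(counts.get("no_CAD", 0)),
        },
        "n": int(len(assignments)),
    }
    return assignments, log


def aggregate_all_cad(assignments: pd.DataFrame | Mapping[str, int]) -> dict:
    """Per-label counts plus the aggregated all-CAD and control totals.

    Accepts either an assignments table or a ready mapping of label → count
    (e.g. published counts), so the count algebra is checkable on both.
    """
    if isinstance(assignments, pd.DataFrame):
        counts = assignments["label"].value_counts().to_dict()
    else:
        counts = dict(assignments)
    per_label = {lab.value: int(counts.get(lab.value, 0)) for lab in PhenotypeLabel}
    all_cad = sum(per_label[lab.value] for lab in CASE_LABELS)
    controls = sum(per_label[lab.value] for lab in CONTROL_LABELS)
    return {**per_label, "all_CAD": all_cad, "controls": controls, "n": all_cad + controls}


def summarize_baseline(
    assignments: pd.DataFrame,
    cohort: Cohort,
    continuous: Sequence[str] = ("age_at_enrol",),
    categorical: Mapping[str, str] = {"sex": "male"},
) -> pd.DataFrame:
    """Per-label baseline characteristics: mean/SD for continuous covariates
    and proportions for categorical ones, plus all-CAD and control rows.

    Empty groups appear with ``n = 0`` and absent (NaN) statistics; a
    single-member group has an absent SD.
    """
    df = assignments.merge(cohort.participants, on="pid", how="left")
    groups: list[tuple[str, pd.DataFrame]] = [
        (lab.value, df[df["label"] == lab.value]) for lab in PhenotypeLabel
    ]
    case_vals = [l.value for l in CASE_LABELS]
    ctrl_vals = [l.value for l in CONTROL_LABELS]
    groups.append(("all_CAD", df[df["label"].isin(case_vals)]))
    groups.append(("controls", df[df["label"].isin(ctrl_vals)]))

    rows = []
    for name, g in groups:
        row: dict = {"group": name, "n": len(g)}
        for col in continuous:
            vals = pd.to_numeric(g[col], errors="coerce")
            row[f"{col}_mean"] = float(vals.mean()) if len(g) else np.nan
            row[f"{col}_sd"] = float(vals.std(ddof=1)) if len(g) > 1 else np.nan
        for col, level in categorical.items():
            row[f"{col}_{level}_frac"] = (
                float((g[col] == level).mean()) if len(g) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)
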