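"""All-cause mortality evaluation of the phenotype labels.

Follow-up conventions follow the study design: prevalent, self-report and
control groups are followed from the enrolment date, incident groups from
the date of their qualifying hospital admission; everyone is censored
administratively at the common censor date.  Each phenotype is compared
with the pooled CAD-free controls in its own Cox model adjusted for age at
enrolment (linear, years) and sex, with Efron tie handling and a Schoenfeld
residual check of the proportional-hazards assumption.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

from .model import CENSOR_DATE, Cohort
from .phenotyper import CASE_LABELS, CONTROL_LABELS, PhenotypeLabel

INCIDENT_LABELS = {PhenotypeLabel.incident_MI.value, PhenotypeLabel.incident_CAD_noMI.value}
CONTROL_VALUES = tuple(l.value for l in CONTROL_LABELS)


@dataclass
class HazardEstimate:
    group: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    #: (max |corr| of scaled Schoenfeld residuals with time, p-value)
    ph_check: tuple[float, float]
    ci_unreliable: bool = False


class EstimationError(RuntimeError):
    pass


def build_survival_records(
    assignments: pd.DataFrame,
    cohort: Cohort,
    censor_date: pd.Timestamp = CENSOR_DATE,
) -> tuple[pd.DataFrame, dict]:
    """Per-participant time-to-death records.

    t0 is the enrolment date except for incident labels, which start at
    their qualifying event date; follow-up ends at death or the censor
    date, whichever is first.  Records whose death precedes t0 (dirty
    linkage) are excluded and counted in the log.

    Returns a DataFrame with columns ``pid, group, t0, time`` (days),
    ``event`` (1=died), ``age_at_enrol, sex`` and a log dict.
    """
    df = assignments.merge(cohort.participants, on="pid", how="left")
    dd = cohort.death_dates()
    df["death_date"] = df["pid"].map(dd)
    df.loc[df["death_date"] > censor_date, "death_date"] = pd.NaT

    t0 = df["enrol_date"].copy()
    inc = df["label"].isin(INCIDENT_LABELS)
    t0[inc] = df.loc[inc, "qualifying_date"]
    end = df["death_date"].fillna(censor_date)
    time = (end - t0).dt.days
    event = df["death_date"].notna()

    bad = time < 0
    log = {"n_excluded_death_before_t0": int(bad.sum())}
    out = pd.DataFrame(
        {
            "pid": df["pid"],
            "group": df["label"],
            "t0": t0,
            "time": time.astype(float),
            "event": event.astype(int),
            "age_at_enrol": df["age_at_enrol"].astype(float),
            "sex": df["sex"],
        }
    )[~bad].reset_index(drop=True)
    return out, log


def km_curve(records: pd.DataFrame, group: str, alpha: float = 0.05) -> pd.DataFrame:
    """Kaplan–Meier product-limit survival estimate for one group.

    Returns a step function as a DataFrame with columns
    ``time, survival, ci_low, ci_high``.
    """
    sub = records[records["group"] == group]
    if sub.empty:
        raise EstimationError(f"no survival records for group {group!r}")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(sub["time"], sub["event"], label=group)
    ci = kmf.confidence_interval_survival_function_
    out = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.values,
            "survival": kmf.survival_function_[group].values,
            "ci_low": ci.iloc[:, 0].values,
            "ci_high": ci.iloc[:, 1].values,
        }
    )
    return out


def _schoenfeld_check(cph: CoxPHFitter, df: pd.DataFrame) -> tuple[float, float]:
    """Correlation of the case indicator's scaled Schoenfeld residuals with
    rank event time (the classic cox.zph-style check): returns
    (|Pearson r|, two-sided p)."""
    try:
        resid = cph.compute_residuals(df, "scaled_schoenfeld")
        times = df.loc[resid.index, "time"].to_numpy()
        res = stats.pearsonr(stats.rankdata(times), resid["case"].to_numpy())
        return float(abs(res.statistic)), float(res.pvalue)
    except Exception:  # PH diagnostics must never sink the fit itself
        return float("nan"), float("nan")


def cox_fit(
    records: pd.DataFrame,
    group: str,
    controls: Sequence[str] = CONTROL_VALUES,
    ph_check: bool = True,
) -> HazardEstimate:
    """Age/sex-adjusted Cox hazard ratio of ``group`` versus the pooled
    CAD-free controls.

    The model regresses time-to-death on a case indicator, age at enrolment
    and sex (Efron ties).  Raises :class:`EstimationError` when no deaths
    are observed; flags the CI as unreliable on convergence failure
    (e.g. complete separation).
    """
    cases = records[records["group"] == group]
    ctrl = records[records["group"].isin(controls)]
    if cases.empty or ctrl.empty:
        raise EstimationError(f"empty case or control set for group {group!r}")
    df = pd.concat([cases.assign(case=1), ctrl.assign(case=0)], ignore_index=True)
    if df["event"].sum() == 0:
        raise EstimationError("no deaths observed; hazard ratio is not estimable")
    df["sex_male"] = (df["sex"] == "male").astype(float)
    fit_df = df[["time", "event", "case", "age_at_enrol", "sex_male"]]
    unreliable = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph = CoxPHFitter()
            cph.fit(fit_df, duration_col="time", event_col="event", batch_mode=True)
        except Exception:
            # sparse groups / separation: retry with a light ridge penalty
            # and mark the interval as unreliable
            try:
                cph = CoxPHFitter(penalizer=0.1)
                cph.fit(fit_df, duration_col="time", event_col="event", batch_mode=True)
                unreliable = True
            except Exception as exc:
                raise EstimationError(f"Cox fit failed for {group!r}: {exc}") from exc
    if not np.isfinite(cph.standard_errors_["case"]) or cph.standard_errors_["case"] > 10:
        unreliable = True
    hr = float(np.exp(cph.params_["case"]))
    ci = cph.confidence_intervals_
    lo = float(np.exp(ci.loc["case"].iloc[0]))
    hi = float(np.exp(ci.loc["case"].iloc[1]))
    ph = _schoenfeld_check(cph, fit_df) if ph_check else (float("nan"), float("nan"))
    return HazardEstimate(
        group=group,
        hazard_ratio=hr,
        ci_low=lo,
        ci_high=hi,
        n_cases=int(len(cases)),
        n_controls=int(len(ctrl)),
        ph_check=ph,
        ci_unreliable=unreliable,
    )


def hazard_table(
    records: pd.DataFrame,
    groups: Optional[Sequence[str]] = None,
    include_all_cad: bool = True,
    ph_check: bool = True,
) -> pd.DataFrame:
    """One Cox model per phenotype versus the shared control pool.

    With ``include_all_cad``, an extra row pools all six case labels into
    the aggregated all-CAD group against the same controls.
    """
    groups = list(groups or [l.value for l in CASE_LABELS])
    nan = float("nan")

    def fit_or_nan(rec, g):
        try:
            return cox_fit(rec, g, ph_check=ph_check)
        except EstimationError:
            n_cases = int((rec["group"] == g).sum())
            n_ctrl = int(rec["group"].isin(CONTROL_VALUES).sum())
            return HazardEstimate(g, nan, nan, nan, n_cases, n_ctrl, (nan, nan), True)

    rows = [fit_or_nan(records, g) for g in groups]
    if include_all_cad:
        pooled = records.copy()
        case_vals = [l.value for l in CASE_LABELS]
        pooled.loc[pooled["group"].isin(case_vals), "group"] = "all_CAD"
        rows.append(fit_or_nan(pooled, "all_CAD"))
    return pd.DataFrame(
        {
            "group": [r.group for r in rows],
            "n_cases": [r.n_cases for r in rows],
            "n_controls": [r.n_controls for r in rows],
            "hr": [r.hazard_ratio for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "ph_corr": [r.ph_check[0] for r in rows],
            "ph_p": [r.ph_check[1] for r in rows],
            "unreliable": [r.ci_unreliable for r in rows],
        }
    )


def mortality_summary(
    deaths_by_group: Mapping[str, int], n_by_group: Mapping[str, int]
) -> dict:
    """Death counts and one-decimal percentages for cases and controls.

    ``deaths_by_group`` / ``n_by_group`` map ``all_CAD`` and ``controls``
    (or any label set) to counts; percentages are rounded to one decimal as
    conventionally reported.
    """
    total = sum(deaths_by_group.values())
    out = {"total_deaths": int(total)}
    for g, d in deaths_by_group.items():
        n = n_by_group[g]
        out[f"{g}_deaths"] = int(d)
        out[f"{g}_death_pct"] = round(100.0 * d / n, 1) if n else float("nan")
    return out
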