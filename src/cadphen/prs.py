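"""Polygenic risk score: greedy LD clumping, scoring, and per-SD
case-control association.

The score is a weighted sum of effect-allele dosages, with weights taken
from external GWAS summary statistics.  Variants are first restricted to
those below the association p-value threshold and then greedily clumped:
the best remaining variant (smallest p) is kept and every other variant on
the same chromosome within the window whose in-sample dosage r² with it
exceeds the threshold is removed.  Scores are standardized to zero mean and
unit SD over the scored sample, and each phenotype's odds ratio per SD is
estimated against the CAD-free controls by logistic regression adjusted
for age and sex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .model import Cohort
from .phenotyper import CONTROL_LABELS

#: Clumping defaults: association threshold, r² and window.
DEFAULT_P_THRESHOLD = 5e-6
DEFAULT_R2_THRESHOLD = 0.2
DEFAULT_WINDOW_KB = 250.0

VARIANT_COLUMNS = ["vid", "chrom", "pos", "effect_allele", "beta", "pvalue"]


class StandardizationError(ValueError):
    pass


@dataclass
class AssociationEstimate:
    group: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    flagged: bool = False
    note: str = ""


def load_variants(path) -> pd.DataFrame:
    """Read a GWAS summary-statistics CSV (vid,chrom,pos,effect_allele,beta,pvalue)."""
    df = pd.read_csv(path, dtype={"vid": str, "chrom": str, "effect_allele": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weights file missing column(s) {sorted(missing)}")
    return df[VARIANT_COLUMNS].copy()


def load_dosages(path) -> pd.DataFrame:
    """Read a delimited dosage matrix: first column ``pid``, one column per
    variant id; values in [0,2] or empty for missing."""
    df = pd.read_csv(path)
    return df.set_index("pid")


def harmonize(variants: pd.DataFrame, dosage_meta: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep weight rows whose (vid, effect_allele) exactly match the dosage
    metadata; return (matched variants, dropped count)."""
    merged = variants.merge(
        dosage_meta[["vid", "effect_allele"]], on="vid", suffixes=("", "_dosage")
    )
    keep = merged["effect_allele"] == merged["effect_allele_dosage"]
    n_dropped = len(variants) - int(keep.sum())
    return merged.loc[keep, VARIANT_COLUMNS].reset_index(drop=True), n_dropped


def ld_clump(
    variants: pd.DataFrame,
    dosages: pd.DataFrame,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_kb: float = DEFAULT_WINDOW_KB,
) -> pd.DataFrame:
    """Greedy p-value-ordered LD clumping on in-sample dosage correlations.

    Variants at or above ``p_threshold`` are discarded first.  Ties on
    p-value break by (chrom, pos, vid).  A zero-variance dosage column has
    undefined correlation, treated as 0 (it can never be clumped away).

    Returns the retained rows of ``variants`` in selection order.
    """
    sig = variants[variants["pvalue"] < p_threshold].copy()
    if sig.empty:
        return sig
    sig = sig.sort_values(["pvalue", "chrom", "pos", "vid"]).reset_index(drop=True)
    X = dosages[sig["vid"]].to_numpy(dtype=float)
    # centre, fill missing with column mean (zero after centring)
    mu = np.nanmean(X, axis=0)
    Xc = X - mu
    Xc[np.isnan(Xc)] = 0.0
    norms = np.sqrt((Xc**2).sum(axis=0))

    chrom = sig["chrom"].to_numpy()
    pos = sig["pos"].to_numpy(dtype=float)
    window = window_kb * 1000.0
    alive = np.ones(len(sig), dtype=bool)
    kept: list[int] = []
    for i in range(len(sig)):
        if not alive[i]:
            continue
        kept.append(i)
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        if not near.any():
            continue
        idx = np.flatnonzero(near)
        if norms[i] == 0:
            continue  # zero-variance index variant: r² defined as 0
        denom = norms[idx] * norms[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc[:, idx].T @ Xc[:, i]) / denom
        r = np.where(denom == 0, 0.0, r)
        alive[idx[r**2 > r2_threshold]] = False
    return sig.iloc[kept].reset_index(drop=True)


def check_clump_independence(
    selected: pd.DataFrame,
    dosages: pd.DataFrame,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    window_kb: float = DEFAULT_WINDOW_KB,
) -> bool:
    """Post-hoc invariant: no retained pair on one chromosome within the
    window has r² above the threshold."""
    X = dosages[selected["vid"]].to_numpy(dtype=float)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
    for i in range(len(selected)):
        for j in range(i + 1, len(selected)):
            if selected["chrom"].iat[i] != selected["chrom"].iat[j]:
                continue
            if abs(selected["pos"].iat[i] - selected["pos"].iat[j]) > window_kb * 1000:
                continue
            sd_i, sd_j = X[:, i].std(), X[:, j].std()
            if sd_i == 0 or sd_j == 0:
                continue
            r = np.corrcoef(X[:, i], X[:, j])[0, 1]
            if r**2 > r2_threshold:
                return False
    return True


def compute_prs(dosages: pd.DataFrame, selected: pd.DataFrame) -> pd.DataFrame:
    """Raw and standardized polygenic scores.

    raw = Σ beta·dosage over the selected variants, with missing dosages
    imputed as twice the column's effect-allele frequency (the column mean
    dosage); z standardizes raw to mean 0, SD 1 over the scored sample.
    """
    missing_cols = set(selected["vid"]) - set(dosages.columns)
    if missing_cols:
        raise KeyError(f"selected variants absent from dosage matrix: {sorted(missing_cols)[:5]}")
    X = dosages[selected["vid"]].to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)  # = 2 x effect-allele frequency
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    raw = X @ selected["beta"].to_numpy(dtype=float)
    sd = raw.std(ddof=0)
    if sd == 0:
        raise StandardizationError("polygenic score is constant; cannot standardize")
    z = (raw - raw.mean()) / sd
    return pd.DataFrame({"pid": dosages.index, "raw": raw, "z": z}).set_index("pid")


def logistic_association(
    scores: pd.DataFrame,
    assignments: pd.DataFrame,
    group: str,
    cohort: Cohort,
    controls: Optional[Sequence[str]] = None,
) -> AssociationEstimate:
    """Odds ratio per SD of the score for one phenotype versus controls,
    adjusted for age at enrolment and sex (Wald 95% CI).

    Participants with labels other than ``group`` or a control label are
    excluded.  Fewer than 2 cases, or non-finite standard errors (complete
    separation), yield a flagged estimate.
    """
    controls = list(controls or (l.value for l in CONTROL_LABELS))
    df = assignments.merge(cohort.participants, on="pid", how="left")
    df = df[df["label"].isin([group] + controls)].copy()
    df = df.join(scores["z"], on="pid", how="inner")
    df["y"] = (df["label"] == group).astype(int)
    n_cases = int(df["y"].sum())
    n_controls = int(len(df) - n_cases)
    if n_cases < 2 or n_controls < 2:
        return AssociationEstimate(
            group, float("nan"), float("nan"), float("nan"),
            n_cases, n_controls, flagged=True, note="too few cases or controls",
        )
    X = sm.add_constant(
        pd.DataFrame(
            {
                "z": df["z"].astype(float),
                "age": df["age_at_enrol"].astype(float),
                "sex_male": (df["sex"] == "male").astype(float),
            }
        )
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(df["y"].to_numpy(), X).fit(disp=0, maxiter=200)
        except Exception:
            return AssociationEstimate(
                group, float("nan"), float("nan"), float("nan"),
                n_cases, n_controls, flagged=True, note="fit failed (separation?)",
            )
    beta = float(res.params["z"])
    se = float(res.bse["z"])
    flagged = not np.isfinite(se) or se > 10
    return AssociationEstimate(
        group=group,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        n_cases=n_cases,
        n_controls=n_controls,
        flagged=flagged,
        note="" if not flagged else "unstable standard error",
    )


def association_table(
    scores: pd.DataFrame,
    assignments: pd.DataFrame,
    cohort: Cohort,
    groups: Optional[Sequence[str]] = None,
    include_all_cad: bool = True,
) -> pd.DataFrame:
    """Per-SD odds ratios for every phenotype (plus aggregated all-CAD)."""
    from .phenotyper import CASE_LABELS

    groups = list(groups or [l.value for l in CASE_LABELS])
    rows = [logistic_association(scores, assignments, g, cohort) for g in groups]
    if include_all_cad:
        pooled = assignments.copy()
        case_vals = [l.value for l in CASE_LABELS]
        pooled.loc[pooled["label"].isin(case_vals), "label"] = "all_CAD"
        rows.append(logistic_association(scores, pooled, "all_CAD", cohort))
    return pd.DataFrame(
        {
            "group": [r.group for r in rows],
            "n_cases": [r.n_cases for r in rows],
            "n_controls": [r.n_controls for r in rows],
            "or_per_sd": [r.odds_ratio for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "flagged": [r.flagged for r in rows],
        }
    )
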