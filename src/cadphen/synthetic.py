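"""Synthetic linked-biobank generator with planted ground truth.

Emits a fully linked cohort — baseline, hospital diagnoses/procedures,
death registry, self-report items — together with a genotype dosage matrix
and GWAS-style weights file, such that:

* each participant carries records that the phenotyping hierarchy must map
  back to a known true label (minimal one-pattern-per-label mode, or an
  adversarial mode that adds distractor records whose correct resolution is
  still uniquely determined by the hierarchy);
* time-to-death follows an exponential proportional-hazards model with a
  configurable hazard ratio per label and a log-linear age effect, so the
  survival evaluation has a known truth to recover;
* the polygenic score's per-SD log-odds against controls is planted per
  label by drawing labels from an exponentially tilted multinomial given
  the genotype-derived score (the log-odds of each case label versus
  controls is exactly linear in the score), so the association evaluation
  has a known truth to recover.

Survival and genotype effects are planted independently (no confounding),
which keeps parameter-recovery tests clean.  Everything is deterministic
under the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model import CENSOR_DATE, Cohort, write_cohort
from .phenotyper import PhenotypeLabel

DAY = pd.Timedelta(days=1)

#: Label mix of the eight-way partition (fractions of the whole cohort).
#: The six case fractions and the died-control (never_CAD) fraction mirror
#: the published cohort counts over n = 502,631.
DEFAULT_LABEL_FRACTIONS: dict[str, float] = {
    "prevalent_MI": 4_900 / 502_631,
    "incident_MI": 4_621 / 502_631,
    "prevalent_CAD_noMI": 10_910 / 502_631,
    "incident_CAD_noMI": 8_668 / 502_631,
    "sr_MI": 2_754 / 502_631,
    "sr_CAD_noMI": 5_623 / 502_631,
    "never_CAD": 10_649 / 502_631,
    "no_CAD": 454_506 / 502_631,
}

#: All-cause mortality hazard ratios versus controls (Fig-4-style gradient).
DEFAULT_HAZARD_RATIOS: dict[str, float] = {
    "prevalent_MI": 2.52,
    "incident_MI": 6.66,
    "prevalent_CAD_noMI": 1.75,
    "incident_CAD_noMI": 5.65,
    "sr_MI": 1.77,
    "sr_CAD_noMI": 1.31,
}

#: Per-SD polygenic-score log odds versus controls. The published per-SD ORs
#: exist for the prevalent EHR groups (1.50, 1.44) and the weakest group
#: (1.08); the remaining groups interpolate the reported prevalent > incident
#: > self-report gradient.
DEFAULT_PRS_LOG_ODDS: dict[str, float] = {
    "prevalent_MI": float(np.log(1.50)),
    "incident_MI": float(np.log(1.35)),
    "prevalent_CAD_noMI": float(np.log(1.44)),
    "incident_CAD_noMI": float(np.log(1.30)),
    "sr_MI": float(np.log(1.20)),
    "sr_CAD_noMI": float(np.log(1.08)),
}

#: Male fraction per label. The reported figures are 46.7% male in
#: self-reported CAD without MI versus 70.1% in the aggregated all-CAD
#: group; with sr_CAD_noMI carrying 15.0% of the case mass under the default
#: label fractions, the remaining case groups need (0.701 - 0.150*0.467) /
#: 0.850 = 0.742 for the aggregate to equal 70.1%. Controls sit near the
#: population male fraction.
DEFAULT_MALE_FRACTION: dict[str, float] = {
    "prevalent_MI": 0.742,
    "incident_MI": 0.742,
    "prevalent_CAD_noMI": 0.742,
    "incident_CAD_noMI": 0.742,
    "sr_MI": 0.742,
    "sr_CAD_noMI": 0.467,
    "control": 0.45,
}

# Fully specified codes used to instantiate qualifying events.
MI_ICD10_CODES = ["I210", "I211", "I214", "I219", "I220", "I229", "I236", "I241", "I252"]
MI_ICD9_CODES = ["4109", "412"]
CAD_ICD10_CODES = ["I200", "I201", "I209", "I240", "I248", "I249", "I250", "I251", "I259"]
CAD_OPCS4_CODES = ["K401", "K411", "K451", "K491", "K492", "K502", "K751"]
NONCAD_ICD10_CODES = ["C349", "J449", "G309", "A419", "I639", "N179"]
NONCAD_OPCS4_CODES = ["W401", "H011", "T202"]
SR_PROC_TOKENS = ["cabg", "ptca", "angioplasty"]

CASE_LABEL_VALUES = [
    "prevalent_MI", "incident_MI", "prevalent_CAD_noMI",
    "incident_CAD_noMI", "sr_MI", "sr_CAD_noMI",
]


class SimulationConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults emulate the published cohort: label mix from the printed
    counts, 2006–2010 enrolment, censoring on 2016-11-01, ages 40–69, a
    baseline mortality rate giving ~2.3% control mortality over follow-up,
    and the published hazard-ratio / odds-ratio gradients.
    """

    n: int = 10_000
    seed: int = 0  # mandatory; every generator stream derives from it
    label_fractions: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_FRACTIONS))
    enrol_start: pd.Timestamp = pd.Timestamp("2006-01-01")
    enrol_end: pd.Timestamp = pd.Timestamp("2010-12-31")
    censor_date: pd.Timestamp = CENSOR_DATE
    age_min: int = 40
    age_max: int = 69
    male_fraction: dict = field(default_factory=lambda: dict(DEFAULT_MALE_FRACTION))
    #: baseline all-cause mortality rate per person-year at the centring age
    baseline_rate: float = 0.002
    #: log-hazard slope per year of age at enrolment
    beta_age: float = 0.09
    hazard_ratios: dict = field(default_factory=lambda: dict(DEFAULT_HAZARD_RATIOS))
    prs_log_odds: dict = field(default_factory=lambda: dict(DEFAULT_PRS_LOG_ODDS))
    #: genotype architecture: m variants in LD blocks; the first variant of
    #: each block is causal, the rest are correlated tags
    m_variants: int = 60
    block_size: int = 3
    block_r2: float = 0.5
    af_min: float = 0.1
    af_max: float = 0.9
    missing_rate: float = 0.0
    #: adversarial mode plants distractor records whose resolution is still
    #: uniquely determined by the hierarchy
    adversarial: bool = False

    def __post_init__(self):
        if self.seed is None:
            raise SimulationConfigError("seed is mandatory")
        total = sum(self.label_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise SimulationConfigError(f"label_fractions sum to {total}, not 1")
        if any(v < 0 for v in self.label_fractions.values()):
            raise SimulationConfigError("label_fractions must be non-negative")
        if self.block_size > self.m_variants:
            raise SimulationConfigError("block_size exceeds m_variants")
        if self.baseline_rate < 0:
            raise SimulationConfigError("baseline_rate must be >= 0")


@dataclass
class SimulatedData:
    cohort: Cohort
    ground_truth: pd.DataFrame  # pid, true_label, true_event_date, true_score
    dosages: pd.DataFrame  # pid-indexed dosage matrix
    variants: pd.DataFrame  # weights file contents


def _rand_dates(rng, start: pd.Timestamp, end: pd.Timestamp, size: int) -> pd.Series:
    span = (end - start).days
    return pd.Series(start + pd.to_timedelta(rng.integers(0, span + 1, size=size), unit="D"))


def simulate_survival(
    frame: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.Series:
    """Exponential proportional-hazards death dates; NaT = alive at censor.

    ``frame`` needs columns ``label`` (control labels count as baseline
    hazard), ``age_at_enrol`` and ``t0`` (follow-up start).  The hazard is
    baseline_rate x HR(label) x exp(beta_age (age - mean age)) per year.
    """
    age_center = (config.age_min + config.age_max) / 2.0
    hr = frame["label"].map(lambda l: config.hazard_ratios.get(l, 1.0)).to_numpy(float)
    rate = (
        config.baseline_rate
        * hr
        * np.exp(config.beta_age * (frame["age_at_enrol"].to_numpy(float) - age_center))
    )
    draws = rng.exponential(1.0, size=len(frame))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_years = np.where(rate > 0, draws / np.where(rate > 0, rate, 1.0), np.inf)
    t_years = np.minimum(t_years, 200.0)  # cap keeps date arithmetic in range
    death = frame["t0"] + pd.to_timedelta(np.ceil(t_years * 365.25), unit="D")
    death = pd.Series(death.values, index=frame.index)
    death[death > config.censor_date] = pd.NaT
    return death


def simulate_cohort(
    config: SimulationConfig, labels: Optional[np.ndarray] = None
) -> tuple[Cohort, pd.DataFrame]:
    """Generate the five linked tables plus a ground-truth table.

    ``labels`` optionally supplies a pre-drawn label per participant (the
    six case labels or ``"control"``), e.g. score-coupled labels from
    :func:`assign_labels_given_score`; otherwise labels are drawn from the
    configured fractions.  Control participants are split into
    ``never_CAD`` / ``no_CAD`` by their simulated survival (a CAD-free
    control is never_CAD exactly when it dies before the censor date), so
    the emitted tables and the true labels are consistent by construction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    pids = np.array([f"P{i:07d}" for i in range(n)])

    if labels is None:
        frac = config.label_fractions
        pool_labels = CASE_LABEL_VALUES + ["control"]
        probs = [frac[l] for l in CASE_LABEL_VALUES]
        probs.append(frac["never_CAD"] + frac["no_CAD"])
        drawn = rng.choice(pool_labels, size=n, p=np.asarray(probs) / sum(probs))
    else:
        if len(labels) != n:
            raise SimulationConfigError("labels length must equal n")
        drawn = np.asarray(labels, dtype="U18").copy()

    ages = rng.integers(config.age_min, config.age_max + 1, size=n)
    enrol = _rand_dates(rng, config.enrol_start, config.enrol_end, n)
    male_p = np.array([config.male_fraction.get(l, config.male_fraction["control"]) for l in drawn])
    sex = np.where(rng.random(n) < male_p, "male", "female")

    # qualifying event dates for the EHR-defined labels
    event_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    prev_mask = np.isin(drawn, ["prevalent_MI", "prevalent_CAD_noMI"])
    if prev_mask.any():
        back = rng.integers(30, 15 * 365, size=int(prev_mask.sum()))
        event_date[prev_mask] = enrol[prev_mask] - pd.to_timedelta(back, unit="D")
    inc_mask = np.isin(drawn, ["incident_MI", "incident_CAD_noMI"])
    if inc_mask.any():
        gap = (config.censor_date - enrol[inc_mask]).dt.days.to_numpy()
        fwd = (rng.random(int(inc_mask.sum())) * (gap - 1)).astype(int) + 1
        event_date[inc_mask] = enrol[inc_mask] + pd.to_timedelta(fwd, unit="D")

    # survival: follow-up starts at the event for incident labels, else enrolment
    t0 = enrol.copy()
    t0[inc_mask] = event_date[inc_mask]
    surv_frame = pd.DataFrame(
        {"label": drawn, "age_at_enrol": ages, "t0": t0.values}
    )
    death_date = simulate_survival(surv_frame, config, rng)

    true_label = drawn.copy()
    is_control = drawn == "control"
    true_label[is_control & death_date.notna().to_numpy()] = "never_CAD"
    true_label[is_control & death_date.isna().to_numpy()] = "no_CAD"

    participants = pd.DataFrame(
        {
            "pid": pids,
            "enrol_date": enrol.values,
            "sex": sex,
            "age_at_enrol": ages,
        }
    )

    dx_rows, proc_rows, sr_rows, death_rows = [], [], [], []

    def add_dx(pid, code, date, system="ICD10", position=None):
        dx_rows.append(
            {
                "pid": pid,
                "code_system": system,
                "code": code,
                "position": position or ("primary" if rng.random() < 0.7 else "secondary"),
                "event_date": date,
            }
        )

    def add_proc(pid, code, date):
        proc_rows.append(
            {"pid": pid, "code_system": "OPCS4", "code": code, "event_date": date}
        )

    def add_sr(pid, category, item):
        sr_rows.append({"pid": pid, "category": category, "item_code": item})

    adversarial = config.adversarial
    # controls carry no records in minimal mode; skip them for speed
    loop_idx = range(n) if adversarial else np.flatnonzero(drawn != "control")
    for i in loop_idx:
        lab, pid, ed = drawn[i], pids[i], event_date.iloc[i]
        en = enrol.iloc[i]
        if lab in ("prevalent_MI", "incident_MI"):
            use_icd9 = lab == "prevalent_MI" and rng.random() < 0.1
            if use_icd9:
                add_dx(pid, str(rng.choice(MI_ICD9_CODES)), ed, system="ICD9")
            else:
                add_dx(pid, str(rng.choice(MI_ICD10_CODES)), ed)
            if adversarial and lab == "incident_MI":
                # CAD code before enrolment: the MI step still wins
                add_dx(pid, str(rng.choice(CAD_ICD10_CODES)), en - 400 * DAY)
                add_sr(pid, "illness", "heart_attack")
            if adversarial and lab == "prevalent_MI":
                # CAD code after enrolment: censored from the CAD step
                cad_d = en + 200 * DAY
                if cad_d <= config.censor_date:
                    add_dx(pid, str(rng.choice(CAD_ICD10_CODES)), cad_d)
        elif lab in ("prevalent_CAD_noMI", "incident_CAD_noMI"):
            u = rng.random()
            if lab == "prevalent_CAD_noMI" and u < 0.15:
                # identified by self-reported revascularisation only
                add_sr(pid, "procedure", str(rng.choice(SR_PROC_TOKENS)))
                event_date.iloc[i] = pd.NaT
            elif u < 0.55:
                add_dx(pid, str(rng.choice(CAD_ICD10_CODES)), ed)
            else:
                add_proc(pid, str(rng.choice(CAD_OPCS4_CODES)), ed)
            if adversarial:
                add_sr(pid, "illness", "angina")
                if lab == "incident_CAD_noMI":
                    add_sr(pid, "illness", "heart_attack")
        elif lab == "sr_MI":
            add_sr(pid, "illness", "heart_attack")
            if adversarial:
                add_sr(pid, "illness", "angina")
        elif lab == "sr_CAD_noMI":
            add_sr(pid, "illness", "angina")
        if adversarial and rng.random() < 0.2:
            # unrelated hospital contact; must never affect classification
            d = min(en + int(rng.integers(0, 1000)) * DAY, config.censor_date)
            add_dx(pid, str(rng.choice(NONCAD_ICD10_CODES)), d)
            if rng.random() < 0.5:
                add_proc(pid, str(rng.choice(NONCAD_OPCS4_CODES)), d)

    died = death_date.notna()
    for i in np.flatnonzero(died.to_numpy()):
        lab = drawn[i]
        if adversarial and lab == "incident_MI":
            # cardiovascular death cause: an extra post-enrolment MI event
            # from the death registry, resolution unchanged
            cause = str(rng.choice(MI_ICD10_CODES))
        else:
            cause = str(rng.choice(NONCAD_ICD10_CODES))
        death_rows.append(
            {
                "pid": pids[i],
                "death_date": death_date.iloc[i],
                "code_system": "ICD10",
                "code": cause,
                "role": "underlying",
            }
        )

    cohort = Cohort(
        participants=participants,
        diagnoses=pd.DataFrame(dx_rows, columns=["pid", "code_system", "code", "position", "event_date"]),
        procedures=pd.DataFrame(proc_rows, columns=["pid", "code_system", "code", "event_date"]),
        deaths=pd.DataFrame(death_rows, columns=["pid", "death_date", "code_system", "code", "role"]),
        self_reports=pd.DataFrame(sr_rows, columns=["pid", "category", "item_code"]),
    ).canonical()

    ground_truth = pd.DataFrame(
        {
            "pid": pids,
            "true_label": true_label,
            "true_event_date": event_date.values,
            "death_date": death_date.values,
        }
    )
    return cohort, ground_truth


def simulate_genotypes(
    pids, config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Blockwise-LD dosages, a weights file, and the true standardized score.

    Haplotypes within a block share an allele frequency; a tag variant is
    copied with probability sqrt(block_r2) so adjacent dosage r² equals
    block_r2 in expectation.  The first variant of each block is causal and
    carries the smallest p-value; one tag is significant-but-correlated
    (removed by clumping) and the rest sit above the p threshold, so the
    clumped selection is exactly the causal set.

    ``pids`` is a sequence of participant ids (or a frame with a ``pid``
    column).  Returns (dosage matrix, weights-file frame, true score).
    """
    if isinstance(pids, pd.DataFrame):
        pids = pids["pid"].to_numpy()
    pids = np.asarray(pids)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1_000_003)
    n = len(pids)
    m, bs = config.m_variants, config.block_size
    n_blocks = int(np.ceil(m / bs))
    copy_p = float(np.sqrt(config.block_r2))

    dosage = np.empty((n, m), dtype=np.int8)
    meta_rows = []
    causal_idx = []
    for b in range(n_blocks):
        lo, hi = b * bs, min((b + 1) * bs, m)
        af = rng.uniform(config.af_min, config.af_max)
        tag = (rng.random((n, 2)) < af).astype(np.int8)  # two haplotypes
        chrom = str((b % 22) + 1)
        base_pos = 10_000_000 + (b // 22) * 5_000_000
        beta_causal = rng.normal(0.0, 0.15)
        if abs(beta_causal) < 0.02:
            beta_causal = 0.02 * np.sign(beta_causal or 1.0)
        for j in range(lo, hi):
            k = j - lo
            if k == 0:
                hap = tag
                beta = beta_causal
                pval = 10 ** rng.uniform(-12, -8)
                causal_idx.append(j)
            else:
                copy = rng.random((n, 2)) < copy_p
                fresh = (rng.random((n, 2)) < af).astype(np.int8)
                hap = np.where(copy, tag, fresh)
                beta = copy_p * beta_causal + rng.normal(0.0, 0.02)
                if k == 1:
                    pval = 10 ** rng.uniform(-7.5, -5.5)  # clumped away
                else:
                    pval = 10 ** rng.uniform(-4, -0.3)  # above threshold
            dosage[:, j] = hap.sum(axis=1)
            meta_rows.append(
                {
                    "vid": f"rs{b:03d}{k:02d}",
                    "chrom": chrom,
                    "pos": int(base_pos + k * 10_000),
                    "effect_allele": str(rng.choice(["A", "C", "G", "T"])),
                    "beta": float(beta),
                    "pvalue": float(pval),
                }
            )
    variants = pd.DataFrame(meta_rows)

    causal = variants.iloc[causal_idx]
    raw = dosage[:, causal_idx].astype(float) @ causal["beta"].to_numpy()
    sd = raw.std(ddof=0) if n else 0.0
    z = (raw - raw.mean()) / sd if sd > 0 else np.zeros(n)
    dosage = dosage.astype(float)

    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    dosages = pd.DataFrame(dosage, columns=variants["vid"], index=pids)
    dosages.index.name = "pid"
    true_score = pd.Series(z, index=pids, name="true_score")
    return dosages, variants, true_score


def assign_labels_given_score(
    scores: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw case/control labels with exact per-SD log-odds in the score.

    Labels follow an exponentially tilted multinomial:
    P(label g | z) ∝ f_g exp(β_g z) / mean(exp(β_g z)), with β = 0 for the
    pooled control mass, so the log-odds of each case label versus controls
    is *exactly* linear in z with slope β_g, and the marginal label
    fractions stay (to first order) at their configured values.
    """
    z = np.asarray(scores, dtype=float)
    frac = config.label_fractions
    pool = CASE_LABEL_VALUES + ["control"]
    f = np.array(
        [frac[l] for l in CASE_LABEL_VALUES] + [frac["never_CAD"] + frac["no_CAD"]]
    )
    betas = np.array([config.prs_log_odds.get(l, 0.0) for l in CASE_LABEL_VALUES] + [0.0])
    w = f[None, :] * np.exp(z[:, None] * betas[None, :])
    if len(z):
        w /= np.exp(z[:, None] * betas[None, :]).mean(axis=0, keepdims=True)
    p = w / w.sum(axis=1, keepdims=True)
    cum = np.cumsum(p, axis=1)
    u = rng.random(len(z))
    idx = (u[:, None] > cum).sum(axis=1)
    return np.array(pool, dtype="U18")[idx]


def simulate_all(config: SimulationConfig) -> SimulatedData:
    """Cohort tables + genotypes in one call, deterministic under the seed.

    Genotypes are drawn first; labels are then assigned conditionally on
    the true score (planting the per-SD odds-ratio gradient exactly) and
    the cohort records are emitted to match those labels.
    """
    pids = np.array([f"P{i:07d}" for i in range(config.n)])
    geno_rng = np.random.default_rng(config.seed + 1_000_003)
    dosages, variants, true_score = simulate_genotypes(pids, config, geno_rng)
    labels = assign_labels_given_score(true_score.to_numpy(), config, geno_rng)
    cohort, gt = simulate_cohort(config, labels=labels)
    gt = gt.merge(true_score.rename("true_score"), left_on="pid", right_index=True)
    return SimulatedData(cohort=cohort, ground_truth=gt, dosages=dosages, variants=variants)


def write_simulation(sim: SimulatedData, out_dir: str | Path) -> None:
    """Write cohort tables, dosage matrix, weights CSV and ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_cohort(sim.cohort, out_dir)
    sim.dosages.to_csv(out_dir / "dosages.csv")
    sim.variants.to_csv(out_dir / "weights.csv", index=False)
    gt = sim.ground_truth.copy()
    for col in ("true_event_date", "death_date"):
        gt[col] = pd.to_datetime(gt[col]).dt.strftime("%Y-%m-%d")
    gt.to_csv(out_dir / "ground_truth.csv", index=False)
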