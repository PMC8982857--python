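import numpy as np
import pandas as pd
import pytest

from cadphen import (
    SimulationConfig,
    compute_prs,
    default_codelist,
    harmonize,
    ld_clump,
    logistic_association,
    run_algorithm,
    simulate_all,
)
from cadphen.prs import StandardizationError, check_clump_independence

from conftest import make_cohort


def vdf(rows):
    """rows: (vid, chrom, pos, beta, pvalue)"""
    return pd.DataFrame(
        [
            {"vid": v, "chrom": str(c), "pos": p, "effect_allele": "A",
             "beta": b, "pvalue": pv}
            for v, c, p, b, pv in rows
        ]
    )


def brute_force_clump(variants, dosages, p_thr, r2_thr, window_kb):
    """Plain re-derivation of greedy clumping used as the oracle."""
    sig = variants[variants["pvalue"] < p_thr]
    sig = sig.sort_values(["pvalue", "chrom", "pos", "vid"]).reset_index(drop=True)
    removed, kept = set(), []
    X = {v: dosages[v].to_numpy(float) for v in sig["vid"]}
    for v in X:
        col = X[v]
        if np.isnan(col).any():
            col = np.where(np.isnan(col), np.nanmean(col), col)
            X[v] = col
    for i in range(len(sig)):
        if i in removed:
            continue
        kept.append(sig["vid"].iloc[i])
        for j in range(len(sig)):
            if j == i or j in removed:
                continue
            if sig["chrom"].iloc[j] != sig["chrom"].iloc[i]:
                continue
            if abs(sig["pos"].iloc[j] - sig["pos"].iloc[i]) > window_kb * 1000:
                continue
            xi, xj = X[sig["vid"].iloc[i]], X[sig["vid"].iloc[j]]
            if xi.std() == 0 or xj.std() == 0:
                r = 0.0
            else:
                r = np.corrcoef(xi, xj)[0, 1]
            if r**2 > r2_thr:
                removed.add(j)
        removed.add(i)
    return kept


class TestLdClump:
    def test_colocated_correlated_variants_keep_smallest_p(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, 500).astype(float)
        dosages = pd.DataFrame(
            {
                "v1": base,
                "v2": np.where(rng.random(500) < 0.95, base, rng.integers(0, 3, 500)),
                "v3": np.where(rng.random(500) < 0.95, base, rng.integers(0, 3, 500)),
            },
            index=[f"P{i}" for i in range(500)],
        )
        variants = vdf(
            [("v1", 1, 1000, 0.1, 1e-8), ("v2", 1, 2000, 0.1, 1e-7), ("v3", 1, 3000, 0.1, 1e-6)]
        )
        sel = ld_clump(variants, dosages)
        assert list(sel["vid"]) == ["v1"]

    def test_variants_outside_window_both_kept(self):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, 200).astype(float)
        dosages = pd.DataFrame({"v1": base, "v2": base}, index=range(200))
        variants = vdf([("v1", 1, 1_000_000, 0.1, 1e-8), ("v2", 1, 1_300_001, 0.1, 1e-7)])
        sel = ld_clump(variants, dosages, window_kb=250)
        assert sorted(sel["vid"]) == ["v1", "v2"]

    def test_p_threshold_filter_applies_before_clumping(self):
        dosages = pd.DataFrame({"v1": [0.0, 1, 2, 1], "v2": [0.0, 1, 2, 1]})
        variants = vdf([("v1", 1, 1000, 0.1, 1e-8), ("v2", 2, 1000, 0.1, 5e-6)])
        sel = ld_clump(variants, dosages, p_threshold=5e-6)
        assert list(sel["vid"]) == ["v1"]  # 5e-6 is not < 5e-6

    def test_zero_variance_column_is_unclumpable(self):
        rng = np.random.default_rng(2)
        dosages = pd.DataFrame(
            {"v1": np.full(100, 2.0), "v2": rng.integers(0, 3, 100).astype(float)}
        )
        variants = vdf([("v1", 1, 1000, 0.1, 1e-9), ("v2", 1, 2000, 0.1, 1e-8)])
        sel = ld_clump(variants, dosages)
        assert sorted(sel["vid"]) == ["v1", "v2"]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            m = int(rng.integers(4, 16))
            n = 120
            base = rng.integers(0, 3, (n, 3)).astype(float)
            cols = {}
            meta = []
            for j in range(m):
                src = base[:, rng.integers(0, 3)]
                noise_p = rng.random() * 0.6
                col = np.where(rng.random(n) < noise_p, rng.integers(0, 3, n), src)
                if rng.random() < 0.05:
                    col = np.full(n, 1.0)
                cols[f"v{j}"] = col
                meta.append(
                    (f"v{j}", int(rng.integers(1, 3)), int(rng.integers(0, 600_000)),
                     0.1, float(10 ** rng.uniform(-9, -3)))
                )
            dosages = pd.DataFrame(cols)
            variants = vdf(meta)
            got = list(ld_clump(variants, dosages, 1e-4, 0.2, 250)["vid"])
            want = brute_force_clump(variants, dosages, 1e-4, 0.2, 250)
            assert got == want


class TestComputePrs:
    def test_weighted_sum_arithmetic(self):
        dosages = pd.DataFrame(
            {"v1": [2.0, 0], "v2": [1.0, 1], "v3": [0.0, 2]}, index=["A", "B"]
        )
        sel = vdf([("v1", 1, 1, 0.1, 1e-8), ("v2", 1, 2, 0.2, 1e-8), ("v3", 1, 3, 0.3, 1e-8)])
        scores = compute_prs(dosages, sel)
        assert scores.loc["A", "raw"] == pytest.approx(0.4)
        assert scores.loc["B", "raw"] == pytest.approx(0.8)

    def test_all_zero_betas_raise_standardization_error(self):
        dosages = pd.DataFrame({"v1": [0.0, 1, 2]})
        sel = vdf([("v1", 1, 1, 0.0, 1e-8)])
        sel["beta"] = 0.0
        with pytest.raises(StandardizationError):
            compute_prs(dosages, sel)

    def test_missing_dosage_imputed_at_twice_allele_frequency(self):
        # column mean over observed = 1.0 -> allele frequency 0.5 -> impute 1.0
        dosages = pd.DataFrame({"v1": [0.0, 2.0, np.nan], "v2": [1.0, 1.0, 1.0]})
        sel = vdf([("v1", 1, 1, 1.0, 1e-8), ("v2", 1, 2, 0.0, 1e-8)])
        scores = compute_prs(dosages, sel)
        assert scores["raw"].iloc[2] == pytest.approx(1.0)

    def test_invariant_to_variant_column_order(self):
        rng = np.random.default_rng(3)
        dosages = pd.DataFrame(rng.integers(0, 3, (50, 4)).astype(float),
                               columns=["a", "b", "c", "d"])
        sel = vdf([("a", 1, 1, 0.1, 1e-8), ("b", 1, 2, -0.2, 1e-8),
                   ("c", 1, 3, 0.3, 1e-8), ("d", 1, 4, 0.05, 1e-8)])
        s1 = compute_prs(dosages, sel)
        s2 = compute_prs(dosages[["d", "b", "a", "c"]], sel)
        pd.testing.assert_frame_equal(s1, s2)

    def test_standardized_scores_zero_mean_unit_sd(self, small_sim):
        sel = ld_clump(small_sim.variants, small_sim.dosages)
        scores = compute_prs(small_sim.dosages, sel)
        assert abs(scores["z"].mean()) < 1e-8
        assert abs(scores["z"].std(ddof=0) - 1) < 1e-8


def test_harmonize_drops_allele_mismatches():
    weights = vdf([("v1", 1, 1, 0.1, 1e-8), ("v2", 1, 2, 0.2, 1e-8)])
    meta = vdf([("v1", 1, 1, 0.0, 1.0), ("v2", 1, 2, 0.0, 1.0)])
    meta.loc[meta["vid"] == "v2", "effect_allele"] = "G"
    matched, dropped = harmonize(weights, meta)
    assert list(matched["vid"]) == ["v1"]
    assert dropped == 1


def test_clump_output_satisfies_independence_invariant(small_sim):
    sel = ld_clump(small_sim.variants, small_sim.dosages)
    assert check_clump_independence(sel, small_sim.dosages)


class TestLogisticAssociation:
    def test_null_score_ci_covers_one(self, codelist):
        sim = simulate_all(
            SimulationConfig(n=20_000, seed=13, prs_log_odds={})
        )
        assignments, _ = run_algorithm(sim.cohort, codelist)
        sel = ld_clump(sim.variants, sim.dosages)
        scores = compute_prs(sim.dosages, sel)
        est = logistic_association(scores, assignments, "prevalent_CAD_noMI", sim.cohort)
        assert est.ci_low < 1.0 < est.ci_high

    def test_too_few_cases_is_flagged(self, codelist):
        cohort = make_cohort(
            participants=[("P1", "2007-01-01", "male", 55), ("P2", "2007-01-01", "female", 60)],
            diagnoses=[("P1", "ICD10", "I214", "primary", "2004-01-01")],
        )
        assignments, _ = run_algorithm(cohort, codelist)
        scores = pd.DataFrame({"pid": ["P1", "P2"], "raw": [0.1, 0.2], "z": [-1.0, 1.0]}).set_index("pid")
        est = logistic_association(scores, assignments, "prevalent_MI", cohort)
        assert est.flagged
        assert np.isnan(est.odds_ratio)
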