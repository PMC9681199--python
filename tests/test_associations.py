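"""Tests for the association and survival analyses: examples computed by
hand, independent oracles (enumeration, brute-force product-limit,
hand-coded partial likelihood, scipy, R lme4), and calibration properties."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from xciskew.associations import (
    age_group_prevalence,
    bonferroni_family,
    cancer_eligibility_filter,
    derive_ratios,
    discordant_pairs,
    fit_cox,
    fit_family_mixed_model,
    kaplan_meier,
    longitudinal_transitions,
    mortality_records,
    paired_wilcoxon_one_sided,
)
from xciskew.simulate import SimConfig, simulate_phenotypes, simulate_truth


# ---------------------------------------------------------------------------
# ratios and multiple testing


class TestDeriveRatios:
    def test_direct_division(self):
        df = pd.DataFrame({"monocytes": [0.5], "neutrophils": [4.0], "lymphocytes": [2.0]})
        out = derive_ratios(df)
        assert out.loc[0, "mlr"] == 0.25
        assert out.loc[0, "nlr"] == 2.0

    def test_zero_lymphocytes_guarded(self, caplog):
        df = pd.DataFrame({"monocytes": [0.5, 0.4], "neutrophils": [4.0, 3.0],
                           "lymphocytes": [2.0, 0.0]})
        with caplog.at_level("WARNING"):
            out = derive_ratios(df)
        assert np.isnan(out.loc[1, "mlr"]) and np.isnan(out.loc[1, "nlr"])
        assert len(out) == 2  # row retained
        assert "lymphocyte" in caplog.text


@pytest.mark.parametrize("m, thr", [(7, 0.007), (10, 0.005), (2, 0.025),
                                    (5, 0.01), (1, 0.05), (4, 0.0125)])
def test_bonferroni_printed_thresholds(m, thr):
    got, flags = bonferroni_family([0.001, 0.04], m)
    assert got == thr
    assert flags[0] == (0.001 < thr)


def test_bonferroni_invalid_family():
    with pytest.raises(ValueError):
        bonferroni_family([0.1], 0)


# ---------------------------------------------------------------------------
# twin discordance


class TestDiscordantPairs:
    def _cohort(self, cats_by_pair, zygosity="MZ", start=0):
        rows = []
        for i, (a, b) in enumerate(cats_by_pair):
            fam = f"F{start + i:03d}"
            rows.append((f"{fam}a", fam, zygosity, a))
            rows.append((f"{fam}b", fam, zygosity, b))
        return pd.DataFrame(rows, columns=["individual_id", "family_id",
                                           "zygosity", "skew_category"])

    def test_counting_fixture(self):
        pairs = [(0, 0)] * 6 + [(0, 1), (1, 2), (0, 2), (1, 0)]  # 4 discordant of 10
        _, summary = discordant_pairs(self._cohort(pairs))
        mz = summary.set_index("zygosity").loc["MZ"]
        assert mz["n_pairs"] == 10 and mz["n_discordant"] == 4
        assert mz["pct_discordant"] == pytest.approx(40.0)

    def test_all_concordant(self):
        _, summary = discordant_pairs(self._cohort([(1, 1)] * 5))
        assert summary.set_index("zygosity").loc["MZ", "pct_discordant"] == 0.0

    def test_incomplete_pair_skipped(self, caplog):
        df = self._cohort([(0, 1)])
        df = pd.concat([df, pd.DataFrame([("solo", "F999", "DZ", 1)], columns=df.columns)])
        with caplog.at_level("INFO"):
            pairs, _ = discordant_pairs(df)
        assert "F999" not in set(pairs["family_id"])


# ---------------------------------------------------------------------------
# signed-rank test


def enumeration_pvalue(d):
    """Independent oracle: exhaustive sign-flip null for P(W+ >= w_obs)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=len(d)):
        if np.dot(signs, ranks) >= w_obs - 1e-12:
            count += 1
    return count / 2 ** len(d)


class TestPairedWilcoxon:
    def test_three_pairs_all_positive(self):
        w, p = paired_wilcoxon_one_sided([(3, 1), (5, 2), (4, 1)])
        assert w == 6.0
        assert p == pytest.approx(1 / 8)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 13))
        d = np.round(r.normal(0.3, 1.0, n), 1)  # rounding induces ties
        d = d[d != 0]
        if d.size == 0:
            return
        _, p = paired_wilcoxon_one_sided(d)
        assert p == pytest.approx(enumeration_pvalue(d), abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_exact_without_ties(self, seed):
        r = np.random.default_rng(100 + seed)
        d = r.normal(0.2, 1.0, 10)  # continuous: no ties, no zeros
        _, p = paired_wilcoxon_one_sided(d)
        sp = stats.wilcoxon(d, alternative="greater", mode="exact").pvalue
        assert p == pytest.approx(sp, abs=1e-12)

    def test_mirror_complement(self):
        d = np.array([1.5, -0.7, 2.2, 0.4, -1.1])
        s = stats.rankdata(np.abs(d)).sum()
        w_pos, p_pos = paired_wilcoxon_one_sided(d)
        w_neg, p_neg = paired_wilcoxon_one_sided(-d)
        assert w_pos + w_neg == pytest.approx(s)
        # discrete complement: P(W>=w) + P(W>=S-w) = 1 + P(W=w)
        assert p_pos + p_neg >= 1.0

    def test_all_zero_differences_undefined(self):
        with pytest.raises(ValueError, match="zero"):
            paired_wilcoxon_one_sided([(1.0, 1.0), (2.0, 2.0)])

    def test_normal_approximation_tail(self):
        r = np.random.default_rng(77)
        d = r.normal(0.8, 1.0, 40)
        _, p = paired_wilcoxon_one_sided(d)
        sp = stats.wilcoxon(d, alternative="greater", mode="approx",
                            correction=True).pvalue
        assert p == pytest.approx(sp, rel=1e-6)

    def test_planted_shift_detected_at_study_n(self):
        """34 discordant pairs (the intra-twin ASCVD design) with a modest
        positive shift rejects at 0.05 in most replicates."""
        r = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            d = r.normal(0.5, 1.0, 34)
            _, p = paired_wilcoxon_one_sided(d)
            hits += p < 0.05
        assert hits > 70

    def test_type_one_error_nominal(self):
        r = np.random.default_rng(13)
        rejects = 0
        reps = 400
        for _ in range(reps):
            d = r.normal(0.0, 1.0, 20)
            _, p = paired_wilcoxon_one_sided(d)
            rejects += p < 0.05
        rate = rejects / reps
        assert abs(rate - 0.05) < 2.5 * np.sqrt(0.05 * 0.95 / reps)


# ---------------------------------------------------------------------------
# mixed models


class TestMixedModel:
    def test_degenerate_family_variance_matches_ols(self):
        r = np.random.default_rng(21)
        n = 300
        df = pd.DataFrame({
            "y": r.normal(size=n), "x": r.normal(size=n), "age": r.uniform(30, 80, n),
            "family_id": [f"F{i}" for i in range(n)],  # all singletons
        })
        df["y"] = df["y"] + 0.3 * df["x"]
        res = fit_family_mixed_model(df, "y", "x", ["age"], standardize_outcome=False)
        import statsmodels.formula.api as smf
        ols = smf.ols("y ~ x + age", df).fit()
        assert res.estimate == pytest.approx(ols.params["x"], abs=1e-6)

    def test_recovers_planted_effect_sign(self):
        cfg = SimConfig(seed=31, n_mz_pairs=180, n_dz_pairs=110, n_singletons=91)  # 671
        coh = simulate_phenotypes(simulate_truth(cfg), cfg)
        res = fit_family_mixed_model(coh, "monocytes", "skew_binary_true",
                                     ["age", "bmi", "season", "smoking_ever"])
        assert res.estimate > 0
        assert res.n == 671

    def test_missing_covariate_named(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "x": [0, 1], "family_id": ["a", "b"]})
        with pytest.raises(KeyError, match="bmi"):
            fit_family_mixed_model(df, "y", "x", ["bmi"])

    def test_against_r_lme4(self, tmp_path):
        """Independent oracle: REML fixed-effect estimate from lme4."""
        cfg = SimConfig(seed=41, n_mz_pairs=60, n_dz_pairs=40, n_singletons=40)
        coh = simulate_phenotypes(simulate_truth(cfg), cfg)
        res = fit_family_mixed_model(coh, "il10", "skew_binary_true", ["age"],
                                     standardize_outcome=False)
        csv = tmp_path / "d.csv"
        coh[["il10", "skew_binary_true", "age", "family_id"]].to_csv(csv, index=False)
        rscript = (
            f"suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            f"m <- lmer(il10 ~ skew_binary_true + age + (1|family_id), data=d, REML=TRUE);"
            f"cat(fixef(m)['skew_binary_true'], sqrt(diag(vcov(m)))[2])"
        )
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, check=True)
        est_r, se_r = map(float, out.stdout.split())
        assert res.estimate == pytest.approx(est_r, abs=1e-4)
        assert res.se == pytest.approx(se_r, abs=1e-3)

    def test_apply_family_flags(self):
        from xciskew.associations import AssocResult
        res = AssocResult("y", "x", 0.2, 0.05, 0.004, 100).apply_family("bloodcounts")
        assert res.bonferroni_threshold == 0.005
        assert res.significant is True


# ---------------------------------------------------------------------------
# eligibility filter


def _toy_registry():
    entry = pd.Timestamp("2010-01-01")
    cohort = pd.DataFrame({
        "individual_id": [f"I{i}" for i in range(1, 11)],
        "entry_date": [entry] * 10,
        "death_date": [pd.NaT] * 10,
    })
    dx = pd.DataFrame([
        ("I1", "2008-05-01", "Breast"),            # prior cancer
        ("I2", "2009-12-31", "Lung"),              # prior cancer
        ("I3", "2010-04-01", "Other"),             # within 6 months
        ("I4", "2012-01-01", "Non-melanoma skin cancer"),  # filtered report
        ("I5", "2013-06-15", "Colorectal"),        # genuine event
    ], columns=["individual_id", "diagnosis_date", "site_group"])
    return cohort, dx


class TestEligibilityFilter:
    def test_toy_registry_hand_counts(self):
        cohort, dx = _toy_registry()
        rec = cancer_eligibility_filter(cohort, dx, study_end="2018-01-01")
        assert len(rec) == 10
        assert int(rec["eligible"].sum()) == 7
        assert int(rec["event"].sum()) == 1
        by_id = rec.set_index("individual_id")
        assert by_id.loc["I1", "exclusion_reason"] == "prior_cancer"
        assert by_id.loc["I3", "exclusion_reason"] == "within_6_months"
        # skin-cancer-only individual: at risk, no event
        assert by_id.loc["I4", "eligible"] and by_id.loc["I4", "event"] == 0
        assert by_id.loc["I5", "event"] == 1

    def test_six_month_boundary_inclusive(self):
        cohort, _ = _toy_registry()
        dx = pd.DataFrame([("I1", "2010-07-01", "Breast")],
                          columns=["individual_id", "diagnosis_date", "site_group"])
        rec = cancer_eligibility_filter(cohort, dx, study_end="2018-01-01")
        assert not rec.set_index("individual_id").loc["I1", "eligible"]

    def test_censoring_at_study_end(self):
        cohort, _ = _toy_registry()
        dx = pd.DataFrame(columns=["individual_id", "diagnosis_date", "site_group"])
        rec = cancer_eligibility_filter(cohort, dx, study_end="2018-01-01")
        assert rec["event"].sum() == 0
        assert rec["time_years"].iloc[0] == pytest.approx(8.0, abs=0.01)

    def test_ten_year_cap(self):
        cohort, _ = _toy_registry()
        dx = pd.DataFrame(columns=["individual_id", "diagnosis_date", "site_group"])
        rec = cancer_eligibility_filter(cohort, dx, study_end="2030-01-01")
        assert rec["time_years"].iloc[0] == pytest.approx(10.0, abs=0.01)

    def test_death_censors_first(self):
        cohort, dx = _toy_registry()
        cohort.loc[cohort["individual_id"] == "I6", "death_date"] = pd.Timestamp("2012-01-01")
        rec = cancer_eligibility_filter(cohort, dx, study_end="2018-01-01")
        assert rec.set_index("individual_id").loc["I6", "time_years"] == pytest.approx(2.0, abs=0.01)

    def test_conservation_and_idempotence(self):
        cohort, dx = _toy_registry()
        rec = cancer_eligibility_filter(cohort, dx, study_end="2018-01-01")
        assert int(rec["eligible"].sum()) + int((~rec["eligible"]).sum()) == len(cohort)
        elig_ids = rec.loc[rec["eligible"], "individual_id"]
        rec2 = cancer_eligibility_filter(
            cohort[cohort["individual_id"].isin(elig_ids)], dx[dx["individual_id"].isin(elig_ids)],
            study_end="2018-01-01")
        pd.testing.assert_frame_equal(
            rec[rec["eligible"]].reset_index(drop=True), rec2)

    def test_inconsistent_dates_rejected(self):
        cohort, dx = _toy_registry()
        cohort.loc[0, "death_date"] = pd.Timestamp("2005-01-01")
        with pytest.raises(ValueError, match="I1"):
            cancer_eligibility_filter(cohort, dx, study_end="2018-01-01")


# ---------------------------------------------------------------------------
# Cox and Kaplan-Meier


def _survival_fixture():
    rec = pd.DataFrame({
        "individual_id": list("abcde"),
        "time_years": [1.0, 2.0, 3.0, 4.0, 5.0],
        "event": [1, 1, 0, 1, 0],
        "eligible": True,
        "exclusion_reason": "none",
    })
    cohort = pd.DataFrame({
        "individual_id": list("abcde"),
        "skew_binary": [1, 0, 1, 0, 0],
        "age": [61.0, 55.0, 70.0, 65.0, 50.0],
        "zygosity": ["MZ"] * 5,
        "family_id": list("ABCDE"),
    })
    return rec, cohort


class TestCox:
    def test_matches_hand_coded_partial_likelihood(self):
        """Estimates agree with direct numerical maximisation of the
        hand-written Breslow partial likelihood."""
        rec, cohort = _survival_fixture()
        res = fit_cox(rec, cohort, adjust_zygosity=False)

        t = rec["time_years"].to_numpy()
        e = rec["event"].to_numpy()
        X = cohort[["skew_binary", "age"]].to_numpy(dtype=float)

        def negloglik(beta):
            eta = X @ beta
            ll = 0.0
            for i in np.where(e == 1)[0]:
                risk = t >= t[i]
                ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
            return -ll

        opt = optimize.minimize(negloglik, np.zeros(2), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert res.log_hr == pytest.approx(opt.x[0], abs=1e-4)

    def test_zero_events_refused(self):
        rec, cohort = _survival_fixture()
        rec["event"] = 0
        with pytest.raises(ValueError, match="no events"):
            fit_cox(rec, cohort)

    def test_null_coverage(self):
        """With no planted effect, the robust 95% CI covers HR=1 at close
        to the nominal rate."""
        rng = np.random.default_rng(3)
        cover = 0
        reps = 150
        for _ in range(reps):
            n = 400
            skew = rng.integers(0, 2, n)
            tdat = rng.exponential(10.0, n)
            cens = rng.uniform(2, 12, n)
            time = np.minimum(tdat, cens)
            rec = pd.DataFrame({
                "individual_id": np.arange(n).astype(str),
                "time_years": time, "event": (tdat <= cens).astype(int),
                "eligible": True, "exclusion_reason": "none",
            })
            cohort = pd.DataFrame({
                "individual_id": np.arange(n).astype(str),
                "skew_binary": skew, "age": rng.uniform(20, 90, n),
                "zygosity": "singleton",
                "family_id": np.arange(n).astype(str),
            })
            res = fit_cox(rec, cohort)
            cover += res.ci_low <= 1.0 <= res.ci_high
        rate = cover / reps
        assert abs(rate - 0.95) < 3 * np.sqrt(0.95 * 0.05 / reps) + 0.01


class TestKaplanMeier:
    def test_single_step_closed_form(self):
        rec = pd.DataFrame({
            "individual_id": ["a", "b"], "time_years": [1.0, 3.0],
            "event": [1, 0], "eligible": True, "exclusion_reason": "none",
            "skew_binary": [0, 0],
        })
        km = kaplan_meier(rec)
        s = km[0]["survival"]
        assert s.loc[1.0].iloc[0] == pytest.approx(0.5)

    def test_no_events_flat_survival(self):
        rec = pd.DataFrame({
            "individual_id": list("abc"), "time_years": [1.0, 2.0, 3.0],
            "event": 0, "eligible": True, "exclusion_reason": "none",
            "skew_binary": [0, 0, 0],
        })
        km = kaplan_meier(rec)
        assert (km[0]["survival"].to_numpy() == 1.0).all()

    def test_matches_brute_force_product(self):
        rec = pd.DataFrame({
            "individual_id": list("abcde"),
            "time_years": [1.0, 2.0, 2.5, 4.0, 5.0],
            "event": [1, 0, 1, 1, 0],
            "eligible": True, "exclusion_reason": "none",
            "skew_binary": 0,
        })
        km = kaplan_meier(rec)
        s = km[0]["survival"]["0"]
        # independent product-limit oracle over risk sets
        t = rec["time_years"].to_numpy()
        e = rec["event"].to_numpy()
        surv = 1.0
        expected = {}
        for ti in sorted(t[e == 1]):
            d = np.sum((t == ti) & (e == 1))
            n_risk = np.sum(t >= ti)
            surv *= 1 - d / n_risk
            expected[ti] = surv
        for ti, val in expected.items():
            assert s.loc[ti] == pytest.approx(val, abs=1e-12)
        arr = s.to_numpy()
        assert (np.diff(arr) <= 1e-12).all()  # non-increasing
        assert s.loc[0.0] == 1.0

    def test_cumulative_event_percentages(self):
        rec = pd.DataFrame({
            "individual_id": [str(i) for i in range(10)],
            "time_years": np.linspace(1, 5, 10),
            "event": [1, 0, 0, 0, 0, 1, 1, 0, 0, 0],
            "eligible": True, "exclusion_reason": "none",
            "skew_binary": [0] * 5 + [1] * 5,
        })
        km = kaplan_meier(rec)
        assert km[0]["pct_events"] == pytest.approx(20.0)
        assert km[1]["pct_events"] == pytest.approx(40.0)


def test_mortality_records_no_diagnosis_exclusions():
    cohort = pd.DataFrame({
        "individual_id": ["a", "b"],
        "entry_date": [pd.Timestamp("2010-01-01")] * 2,
        "death_date": [pd.Timestamp("2015-01-01"), pd.NaT],
    })
    rec = mortality_records(cohort, study_end="2018-01-01")
    assert rec["eligible"].all()
    by = rec.set_index("individual_id")
    assert by.loc["a", "event"] == 1
    assert by.loc["a", "time_years"] == pytest.approx(5.0, abs=0.01)
    assert by.loc["b", "event"] == 0
    assert by.loc["b", "time_years"] == pytest.approx(8.0, abs=0.01)


# ---------------------------------------------------------------------------
# descriptive summaries


class TestAgeGroupPrevalence:
    def _table(self, band_specs):
        """band_specs: list of (age, n_total, n_skewed, n_extreme)."""
        rows = []
        for age, n, n_sk, n_ex in band_specs:
            cats = [2] * n_ex + [1] * (n_sk - n_ex) + [0] * (n - n_sk)
            rows += [(age, c) for c in cats]
        return pd.DataFrame(rows, columns=["age", "skew_category"])

    def test_printed_percentages(self):
        df = self._table([(30, 75, 9, 2), (50, 652, 183, 20),
                          (65, 498, 185, 35), (80, 303, 132, 27)])
        out = age_group_prevalence(df).set_index("age_band")
        assert list(out["pct_skewed"]) == [12, 28, 37, 44]
        assert out.loc["<40", "n"] == 75
        assert out.loc[">=70", "n_skewed"] + out.loc[">=70", "n_extreme"] == 132

    def test_zero_and_empty_bands(self):
        df = self._table([(30, 10, 0, 0)])
        out = age_group_prevalence(df).set_index("age_band")
        assert out.loc["<40", "pct_skewed"] == 0
        assert np.isnan(out.loc[">=70", "pct_skewed"])


class TestLongitudinalTransitions:
    def test_printed_progression(self):
        ids = [f"p{i}" for i in range(21)]
        v1 = pd.Series([0] * 21, index=ids)
        v2 = pd.Series([0] * 15 + [1] * 6, index=ids)
        counts, pct = longitudinal_transitions(v1, v2)
        assert counts.loc[0, 0] == 15 and counts.loc[0, 1] == 6
        assert pct.loc[0, 0] == 71.4
        assert pct.loc[0, 1] == 28.6

    def test_identity_is_diagonal(self):
        ids = list("abcdef")
        v = pd.Series([0, 0, 1, 1, 2, 2], index=ids)
        counts, _ = longitudinal_transitions(v, v)
        assert (counts.to_numpy() == np.diag([2, 2, 2])).all()

    def test_hand_counted_fixture(self):
        ids = [f"q{i}" for i in range(8)]
        v1 = pd.Series([0, 0, 0, 1, 1, 1, 2, 2], index=ids)
        v2 = pd.Series([0, 1, 1, 1, 2, 1, 2, 2], index=ids)
        counts, _ = longitudinal_transitions(v1, v2)
        expected = np.array([[1, 2, 0], [0, 2, 1], [0, 0, 2]])
        assert (counts.to_numpy() == expected).all()

    def test_unmatched_ids_dropped(self, caplog):
        v1 = pd.Series([0, 1], index=["a", "b"])
        v2 = pd.Series([0, 2], index=["a", "c"])
        with caplog.at_level("INFO"):
            counts, _ = longitudinal_transitions(v1, v2)
        assert counts.to_numpy().sum() == 1
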