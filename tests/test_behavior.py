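"""SDT indices, paired tests, RT screening, and the probit mixed model."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
import statsmodels.api as sm

import pupilforget as pf
from pupilforget import glmm


class TestLoglinearRates:
    def test_symmetric_half(self):
        hr, far = pf.loglinear_rates(10, 20, 10, 20)
        assert hr == far == pytest.approx(0.5)

    def test_perfect_and_empty_rates_stay_inside_unit_interval(self):
        hr, far = pf.loglinear_rates(20, 20, 0, 20)
        assert hr == pytest.approx(20.5 / 21)
        assert far == pytest.approx(0.5 / 21)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            pf.loglinear_rates(0, 0, 0, 10)

    @given(st.integers(1, 200), st.integers(1, 200), st.data())
    @settings(max_examples=50, deadline=None)
    def test_rates_strictly_inside_unit_interval(self, n_old, n_lure, data):
        hits = data.draw(st.integers(0, n_old))
        fas = data.draw(st.integers(0, n_lure))
        hr, far = pf.loglinear_rates(hits, n_old, fas, n_lure)
        assert 0 < hr < 1 and 0 < far < 1


class TestDprimeCriterion:
    def test_equal_rates_give_zero_dprime(self):
        d, _ = pf.dprime_criterion(0.3, 0.3)
        assert d == pytest.approx(0.0)

    def test_symmetric_rates_give_zero_criterion(self):
        _, c = pf.dprime_criterion(0.8, 0.2)
        assert c == pytest.approx(0.0, abs=1e-12)

    def test_closed_form(self):
        hr = 20.5 / 21
        d, _ = pf.dprime_criterion(hr, 1 - hr)
        assert d == pytest.approx(2 * stats.norm.ppf(hr), rel=1e-12)

    def test_boundary_rates_rejected(self):
        with pytest.raises(ValueError, match="loglinear"):
            pf.dprime_criterion(1.0, 0.2)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(max_examples=100, deadline=None)
    def test_swap_antisymmetry(self, hr, far):
        d1, c1 = pf.dprime_criterion(hr, far)
        d2, c2 = pf.dprime_criterion(far, hr)
        assert d1 == pytest.approx(-d2, abs=1e-10)
        assert c1 == pytest.approx(c2, abs=1e-10)


class TestPairedTest:
    def test_identical_vectors(self):
        res = pf.paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.dz == 0.0 and res.p == 1.0

    def test_constant_nonzero_difference_overflows(self):
        with pytest.raises(OverflowError):
            pf.paired_test([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])

    def test_hand_computed_example(self):
        # diffs [2, 0, 1, 1]: mean 1, sd 0.8165 -> t = 1 / (0.8165/2)
        res = pf.paired_test([3.0, 1.0, 2.0, 2.0], [1.0, 1.0, 1.0, 1.0])
        assert res.t == pytest.approx(2.4494897, rel=1e-6)
        assert res.df == 3
        assert res.dz == pytest.approx(1.0 / 0.81649658, rel=1e-6)

    def test_matches_scipy_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b = rng.normal(size=(2, 15))
            ours = pf.paired_test(a, b)
            ref = stats.ttest_rel(a, b)
            assert ours.t == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_compare_conditions_pairs_by_subject(self):
        config = pf.SimulationConfig(n_subjects=30, n_items=40, seed=17)
        trials, _ = pf.simulate_behavior(config)
        summary = pf.sdt_summary(trials)
        res = pf.compare_conditions(summary, "dprime", ("R", "F"))
        # generative d' is larger for R than F
        assert res.mean_a > res.mean_b
        assert res.df == 29


class TestRtPrepare:
    def test_equal_rts_keep_everything(self):
        trials = pd.DataFrame({"rt_ms": np.full(50, 1000.0)})
        out, removed = pf.rt_prepare(trials)
        assert len(out) == 50 and removed == 0.0
        assert np.allclose(out["log_rt"], np.log(1000.0))

    def test_single_far_outlier_removed(self):
        rng = np.random.default_rng(6)
        rt = rng.uniform(900, 1100, 1000)  # bounded: no natural 3-SD outliers
        rt[123] = rt.mean() + 10 * rt.std()
        out, removed = pf.rt_prepare(pd.DataFrame({"rt_ms": rt, "i": np.arange(1000)}))
        assert removed == pytest.approx(1 / 1000)
        assert 123 not in out["i"].to_numpy()

    def test_removal_matches_reference_scan(self):
        rng = np.random.default_rng(7)
        rt = np.exp(rng.normal(7, 0.5, 2000))  # heavy-tailed raw scale
        out, removed = pf.rt_prepare(pd.DataFrame({"rt_ms": rt}))
        ref_keep = np.abs(rt - rt.mean()) <= 3 * rt.std(ddof=1)
        assert removed == pytest.approx(1 - ref_keep.mean())
        assert len(out) == ref_keep.sum()

    def test_nonpositive_rt_rejected(self):
        with pytest.raises(ValueError):
            pf.rt_prepare(pd.DataFrame({"rt_ms": [100.0, 0.0]}))


class TestAccuracyGlmm:
    def test_degenerate_input_matches_plain_probit(self):
        # one subject: the ladder bottoms out in an ordinary probit GLM
        config = pf.SimulationConfig(n_subjects=1, n_items=40, seed=19,
                                     subject_sd_dprime=0.0, item_sd_dprime=0.0)
        trials, _ = pf.simulate_behavior(config)
        res = pf.fit_accuracy_glmm(trials, ladder=[""])
        data = trials.copy()
        y = (data["response"] == "old").astype(float)
        X, _ = glmm.fixed_design(data, {"condition": ("R", "F"),
                                        "image_type": ("Lure", "Old")})
        ref = sm.GLM(y, X, family=sm.families.Binomial(
            sm.families.links.Probit())).fit()
        np.testing.assert_allclose(res.coef["estimate"], ref.params, rtol=1e-5)
        np.testing.assert_allclose(res.coef["se"], ref.bse, rtol=1e-4)
        assert res.random_structure == "none (GLM)"

    def test_type_coefficient_recovers_generative_dprime(self):
        # homogeneous world: type beta should estimate the common d'
        # (n = 4000 trials puts the Monte-Carlo SE of d' near 0.045)
        config = pf.SimulationConfig(
            n_subjects=100, n_items=40, seed=23,
            sdt={"R": (1.5, 0.0), "F": (1.5, 0.0)},
            subject_sd_dprime=0.0, item_sd_dprime=0.0)
        trials, _ = pf.simulate_behavior(config)
        res = pf.fit_accuracy_glmm(trials, ladder=["subject, item"])
        assert res["image_type"]["estimate"] == pytest.approx(1.5, abs=0.15)
        assert res["condition:image_type"]["estimate"] == pytest.approx(0.0, abs=0.2)

    def test_permuted_labels_null_out_condition_effects(self):
        # shuffling condition labels within subject breaks every cue link;
        # the refit cue terms should then be null-calibrated
        config = pf.SimulationConfig(n_subjects=24, n_items=24, seed=100)
        trials, _ = pf.simulate_behavior(config)
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 6
        for _ in range(n_rep):
            shuffled = trials.copy()
            shuffled["condition"] = (
                shuffled.groupby("subject")["condition"]
                .transform(lambda s: s.to_numpy()[rng.permutation(len(s))]))
            res = pf.fit_accuracy_glmm(shuffled, ladder=["subject, item"])
            if abs(res["condition:image_type"]["stat"]) < 2 and \
                    abs(res["condition"]["stat"]) < 2:
                hits += 1
        assert hits >= n_rep - 1

    def test_unknown_condition_levels_rejected(self):
        trials = pd.DataFrame({
            "subject": [0, 0], "item": [0, 1], "condition": ["X", "Y"],
            "image_type": ["Old", "Lure"], "response": ["old", "lure"],
            "accuracy": [True, True], "rt_ms": [900.0, 1000.0]})
        with pytest.raises(ValueError, match="condition"):
            pf.fit_accuracy_glmm(trials)


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_probit_glmm_matches_lme4_oracle(tmp_path):
    """Independent cross-check of the Laplace fit against glmer (lme4)."""
    config = pf.SimulationConfig(n_subjects=25, n_items=20, seed=11)
    trials, _ = pf.simulate_behavior(config)
    df = trials[["subject", "item", "condition", "image_type"]].copy()
    df["y"] = (trials["response"] == "old").astype(int)
    csv = tmp_path / "d.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(textwrap.dedent(f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$cond <- ifelse(d$condition == "F", 0.5, -0.5)
        d$type <- ifelse(d$image_type == "Old", 0.5, -0.5)
        m <- glmer(y ~ cond * type + (1 | subject) + (1 | item),
                   data = d, family = binomial(link = "probit"))
        write.csv(data.frame(est = fixef(m), se = sqrt(diag(vcov(m)))),
                  "{tmp_path}/ref.csv")
    """))
    subprocess.run(["Rscript", str(script)], check=True, capture_output=True,
                   timeout=300)
    ref = pd.read_csv(tmp_path / "ref.csv")

    data = trials.copy()
    data["_y"] = (data["response"] == "old").astype(float)
    res = glmm.fit_probit_mixed(data, {"condition": ("R", "F"),
                                       "image_type": ("Lure", "Old")},
                                "subject, item")
    np.testing.assert_allclose(res.coef["estimate"], ref["est"], atol=0.02)
    np.testing.assert_allclose(res.coef["se"], ref["se"], atol=0.02)


class TestRtModel:
    def test_single_subject_intercept_only_equals_ols(self):
        config = pf.SimulationConfig(n_subjects=1, n_items=40, seed=29)
        trials, _ = pf.simulate_behavior(config)
        prepared, _ = pf.rt_prepare(trials)
        res = pf.fit_rt_model(prepared, ladder=[""])
        X, _ = glmm.fixed_design(
            prepared.assign(accuracy_label=np.where(prepared["accuracy"],
                                                    "Correct", "Incorrect")),
            {"condition": ("R", "F"),
             "accuracy_label": ("Incorrect", "Correct"),
             "image_type": ("Lure", "Old")})
        ref = sm.OLS(prepared["log_rt"].to_numpy(), X).fit()
        np.testing.assert_allclose(res.coef["estimate"], ref.params, rtol=1e-8)

    def test_injected_lure_shift_recovered(self):
        config = pf.SimulationConfig(
            n_subjects=40, n_items=40, seed=31, rt_lure_shift=0.1,
            rt_condition_shift={"R": 0.0, "F": 0.0}, rt_outlier_prob=0.0)
        trials, _ = pf.simulate_behavior(config)
        prepared, _ = pf.rt_prepare(trials)
        res = pf.fit_rt_model(prepared, ladder=["subject, item", "subject"])
        # Old is coded +0.5, so a lure slowdown appears as a negative effect
        assert res["image_type"]["estimate"] == pytest.approx(-0.1, abs=0.03)
        assert res["condition"]["estimate"] == pytest.approx(0.0, abs=0.03)

    def test_requires_prepared_trials(self):
        config = pf.SimulationConfig(n_subjects=2, n_items=8, seed=1)
        trials, _ = pf.simulate_behavior(config)
        with pytest.raises(ValueError, match="rt_prepare"):
            pf.fit_rt_model(trials)
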