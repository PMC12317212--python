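"""Per-bin statistics, cluster formation, and the permutation machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pupilforget as pf
from pupilforget.cluster import condition_bin_means, find_clusters, per_bin_stats


def make_series(values, condition, subject=None, accuracy=None):
    n = len(values)
    labels = pd.DataFrame({
        "subject": subject if subject is not None else np.zeros(n, int),
        "item": np.arange(n),
        "condition": condition,
        "accuracy": accuracy if accuracy is not None else np.ones(n, bool),
    })
    return pf.BinSeries(np.asarray(values, dtype=float), labels)


def reference_find_clusters(p, t, alpha=0.05, min_len=10):
    """Independent exhaustive scan: walk every index, close runs on any
    insignificance or sign change, keep runs meeting the length rule."""
    out = []
    current = []
    prev_sign = 0

    def close():
        if len(current) >= min_len:
            out.append((current[0], current[-1],
                        float(np.sum([t[k] for k in current]))))

    for i in range(len(p)):
        sig = p[i] < alpha and t[i] != 0
        sign = 0 if t[i] == 0 else (1 if t[i] > 0 else -1)
        if sig and (not current or sign == prev_sign):
            current.append(i)
            prev_sign = sign
        else:
            close()
            current = [i] if sig else []
            prev_sign = sign if sig else 0
    close()
    return out


class TestPerBinStats:
    def test_identical_condition_values_give_zero_estimate(self):
        # balanced mirror design: every trace appears under both labels
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 20))
        values = np.vstack([base, base])
        cond = ["R"] * 6 + ["F"] * 6
        res = per_bin_stats(make_series(values, cond), spec="ols")
        np.testing.assert_allclose(res["estimate"], 0.0, atol=1e-12)

    def test_ols_spec_equals_two_sample_t(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(16, 10))
        cond = np.array(["R"] * 8 + ["F"] * 8)
        res = per_bin_stats(make_series(values, cond), spec="ols")
        for b in range(10):
            ref = stats.ttest_ind(values[cond == "F", b], values[cond == "R", b])
            assert res.loc[b, "stat"] == pytest.approx(ref.statistic, rel=1e-10)
            assert res.loc[b, "p"] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_subject_spec_equals_fixed_effects_regression(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        n = 40
        subject = np.repeat(np.arange(4), 10)
        cond = np.tile(np.array(["R"] * 5 + ["F"] * 5), 4)
        values = rng.normal(size=(n, 3)) + subject[:, None] * 2.0
        res = per_bin_stats(make_series(values, cond, subject), spec="subject")
        x = (cond == "R").astype(float) * -1 + 0.5  # F=+0.5, R=-0.5
        dummies = np.eye(4)[subject]
        for b in range(3):
            ref = sm.OLS(values[:, b], np.column_stack([x, dummies])).fit()
            assert res.loc[b, "stat"] == pytest.approx(ref.tvalues[0], rel=1e-8)
            assert res.loc[b, "p"] == pytest.approx(ref.pvalues[0], rel=1e-8)

    def test_constant_bin_gives_zero_stat(self):
        values = np.ones((8, 5))
        res = per_bin_stats(make_series(values, ["R", "F"] * 4), spec="ols")
        assert (res["stat"] == 0).all() and (res["p"] == 1).all()

    def test_injected_window_elevates_t(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(60, 150))
        cond = np.array(["R", "F"] * 30)
        values[cond == "F", 94:141] += 1.5
        res = per_bin_stats(make_series(values, cond), spec="ols")
        inside = res["stat"].to_numpy()[94:141]
        outside = np.abs(np.concatenate([res["stat"][:94], res["stat"][141:]]))
        assert np.median(np.abs(inside)) > 4.0
        assert (inside > 0).all()  # injection direction is F > R
        assert np.median(outside) < 1.5

    def test_mixed_spec_reports_structure(self, clean_experiment):
        _, _, clean, _ = clean_experiment
        series = pf.bin_series_from_clean(clean)
        small = pf.BinSeries(series.values[:, :3], series.labels)
        res = per_bin_stats(small, spec="mixed")
        assert len(res) == 3
        assert set(res.columns) >= {"estimate", "se", "stat", "p", "structure"}
        assert (res["p"].between(0, 1)).all()


class TestFindClusters:
    def _stats(self, p, t):
        return pd.DataFrame({"bin": np.arange(len(p)), "p": p, "stat": t})

    def test_exact_min_length_run(self):
        p = np.full(30, 0.5)
        t = np.zeros(30)
        p[5:15] = 0.01
        t[5:15] = 2.0
        (c,) = find_clusters(self._stats(p, t))
        assert (c.start_bin, c.end_bin, c.sign) == (5, 14, 1)
        assert c.mass == pytest.approx(20.0)
        assert c.time_window_ms() == (100, 300)

    def test_below_min_length_ignored(self):
        p = np.full(30, 0.5)
        t = np.ones(30)
        p[5:14] = 0.01  # only 9 bins
        assert find_clusters(self._stats(p, t)) == []

    def test_sign_flip_splits_run(self):
        p = np.full(40, 0.01)
        t = np.ones(40)
        t[20:] = -1.0
        clusters = find_clusters(self._stats(p, t), min_len=10)
        assert [(c.start_bin, c.end_bin, c.sign) for c in clusters] == \
            [(0, 19, 1), (20, 39, -1)]

    def test_matches_exhaustive_reference_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = 150
            p = rng.beta(0.35, 1.0, n)  # many small p values -> real runs
            t = rng.normal(size=n) + np.sign(rng.normal()) * 1.0
            got = [(c.start_bin, c.end_bin, c.mass)
                   for c in find_clusters(pd.DataFrame({"p": p, "stat": t}))]
            ref = reference_find_clusters(p, t)
            assert len(got) == len(ref)
            for g, r in zip(got, ref):
                assert g[:2] == r[:2]
                assert g[2] == pytest.approx(r[2], rel=1e-12)

    def test_cluster_mass_is_plain_sum(self):
        assert pf.cluster_mass([2.1] * 10) == pytest.approx(21.0)
        assert pf.cluster_mass([-2.5] * 12) == pytest.approx(-30.0)
        rng = np.random.default_rng(5)
        v = rng.normal(size=17)
        assert pf.cluster_mass(v) == pytest.approx(float(v.sum()))


class TestPermutationTest:
    def _effect_series(self, seed=0, n_subj=4, per_cond=10, amp=1.2):
        rng = np.random.default_rng(seed)
        n = n_subj * per_cond * 2
        subject = np.repeat(np.arange(n_subj), per_cond * 2)
        cond = np.tile(np.array(["R"] * per_cond + ["F"] * per_cond), n_subj)
        values = rng.normal(size=(n, 150))
        values[cond == "F", 60:100] += amp
        return make_series(values, cond, subject)

    def test_p_is_plain_proportion_of_null_maxima(self):
        series = self._effect_series()
        res = pf.permutation_test(series, spec="subject", n_perm=200, seed=7)
        assert len(res.null_max_mass) == 200
        assert res.clusters, "expected at least one observed cluster"
        for c in res.clusters:
            expected = (np.abs(res.null_max_mass) >= abs(c.mass)).mean()
            assert c.p == pytest.approx(expected)

    def test_add_one_estimator_option(self):
        series = self._effect_series()
        res = pf.permutation_test(series, spec="subject", n_perm=99, seed=7,
                                  estimator="add_one")
        for c in res.clusters:
            exceed = (np.abs(res.null_max_mass) >= abs(c.mass)).sum()
            assert c.p == pytest.approx((exceed + 1) / 100)

    def test_overwhelming_effect_gives_p_zero(self):
        series = self._effect_series(amp=5.0)
        res = pf.permutation_test(series, spec="subject", n_perm=100, seed=3)
        assert res.clusters and min(c.p for c in res.clusters) == 0.0

    def test_seeded_determinism(self):
        series = self._effect_series()
        a = pf.permutation_test(series, spec="subject", n_perm=100, seed=11)
        b = pf.permutation_test(series, spec="subject", n_perm=100, seed=11)
        np.testing.assert_array_equal(a.null_max_mass, b.null_max_mass)
        assert [(c.start_bin, c.end_bin, c.p) for c in a.clusters] == \
            [(c.start_bin, c.end_bin, c.p) for c in b.clusters]

    def test_label_swap_symmetry(self):
        series = self._effect_series()
        swapped = make_series(series.values,
                              np.where(series.labels["condition"] == "R",
                                       "F", "R"),
                              series.labels["subject"].to_numpy())
        a = pf.permutation_test(series, spec="subject", n_perm=150, seed=5)
        b = pf.permutation_test(swapped, spec="subject", n_perm=150, seed=5)
        np.testing.assert_allclose(a.bin_stats["estimate"],
                                   -b.bin_stats["estimate"], atol=1e-10)
        assert [(c.start_bin, c.end_bin) for c in a.clusters] == \
            [(c.start_bin, c.end_bin) for c in b.clusters]
        for ca, cb in zip(a.clusters, b.clusters):
            assert ca.mass == pytest.approx(-cb.mass, rel=1e-10)
            assert ca.p == cb.p

    def test_large_shift_cannot_reduce_peak_t(self):
        series = self._effect_series(amp=0.4)
        base = per_bin_stats(series, spec="subject")
        shifted = series.values.copy()
        is_f = series.labels["condition"].to_numpy() == "F"
        shifted[is_f, 60:100] += 10.0
        after = per_bin_stats(make_series(shifted,
                                          series.labels["condition"],
                                          series.labels["subject"].to_numpy()),
                              spec="subject")
        assert np.abs(after["stat"][60:100]).max() >= \
            np.abs(base["stat"][60:100]).max()

    def test_invalid_arguments_rejected(self):
        series = self._effect_series()
        with pytest.raises(ValueError):
            pf.permutation_test(series, n_perm=0)
        with pytest.raises(ValueError):
            pf.permutation_test(series, statistic="median")


class TestRunContrast:
    def test_missing_level_is_named(self, clean_experiment):
        _, _, clean, _ = clean_experiment
        only_r = clean.meta["condition"] == "R"
        crippled = pf.CleanTrials(clean.bins.copy(), clean.meta.copy())
        crippled.meta.loc[~only_r, "accuracy"] = True
        crippled.meta.loc[~only_r, "image_type"] = "Lure"
        with pytest.raises(ValueError, match="F"):
            pf.run_contrast(crippled, {"image_type": "Old", "accuracy": False},
                            n_perm=10)

    def test_condition_means_are_plot_ready(self, clean_experiment):
        _, _, clean, _ = clean_experiment
        series = pf.bin_series_from_clean(clean)
        means = condition_bin_means(series)
        assert set(means["condition"]) == {"R", "F"}
        assert len(means) == 2 * series.n_bins
        one = means[(means["condition"] == "R") & (means["bin"] == 0)]
        sel = (series.labels["condition"] == "R").to_numpy()
        assert one["mean"].iloc[0] == pytest.approx(
            series.values[sel, 0].mean())
        assert one["n"].iloc[0] == sel.sum()

    def test_full_contrast_runs_and_reports(self, clean_experiment):
        _, _, clean, _ = clean_experiment
        res = pf.run_contrast(clean, {"image_type": "Old", "accuracy": True},
                              spec="subject", n_perm=50, seed=2)
        assert len(res.bin_stats) == 150
        assert res.levels == ("R", "F")  # effect reads F minus R
        assert len(res.permutation.null_max_mass) == 50
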