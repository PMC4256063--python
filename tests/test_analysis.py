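import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from equinoise.analysis import (
    analyze,
    apply_catch_screen,
    catch_screen,
    correlations,
    fit_trajectory,
    fixation_stability,
    hierarchical_regression,
    screen_and_transform,
)


def _binomial_tail_oracle(n, k_correct, chance):
    """Exact one-sided P(X >= k_correct) by direct enumeration."""
    return sum(
        math.comb(n, j) * chance**j * (1 - chance) ** (n - j) for j in range(k_correct, n + 1)
    )


class TestCatchScreen:
    def test_study_design_criterion(self):
        # 15 catch trials at chance 0.5: 4 or more errors fails the screen
        assert catch_screen(15, 0.5, 0.05) == 4

    def test_exact_tail_probabilities(self):
        assert _binomial_tail_oracle(15, 12, 0.5) == pytest.approx(576 / 32768, rel=1e-12)
        assert _binomial_tail_oracle(15, 11, 0.5) == pytest.approx(1941 / 32768, rel=1e-12)
        assert 576 / 32768 < 0.05 < 1941 / 32768

    @pytest.mark.parametrize("alpha", [0.01, 0.05, 0.10])
    @pytest.mark.parametrize("n_catch", [5, 10, 15, 20, 30])
    def test_matches_enumeration_oracle(self, n_catch, alpha):
        expected = n_catch + 1
        for k in range(n_catch + 1):
            if _binomial_tail_oracle(n_catch, n_catch - k, 0.5) > alpha:
                expected = k
                break
        assert catch_screen(n_catch, 0.5, alpha) == expected

    def test_applied_per_participant(self):
        est = pd.DataFrame(
            dict(
                participant_id=["a", "a", "b", "b"],
                speed=[1.5, 6.0, 1.5, 6.0],
                catch_incorrect_en=[0, 5, 1, 2],
                catch_incorrect_mc=[0, 0, 3, 3],
            )
        )
        excl = apply_catch_screen(est)
        assert excl.tolist() == [True, True, False, False]  # 'a' fails at one speed


class TestScreenAndTransform:
    def _frame(self, values, measure="sigma_int"):
        n = len(values)
        d = dict(
            participant_id=[f"p{i}" for i in range(n)],
            age_group=["g"] * n,
            age_years=[9.0] * n,
            speed=[1.5] * n,
            sigma_int=np.full(n, 8.0),
            n_samp=np.full(n, 1.0),
            coherence_threshold=np.full(n, 0.4),
        )
        d[measure] = np.asarray(values, dtype=float)
        return pd.DataFrame(d)

    def test_spike_beyond_three_z_removed_but_mild_spike_kept(self, rng):
        base = 10 ** rng.normal(np.log10(8.0), 0.1, 50)
        lm, ls = np.log10(base).mean(), np.log10(base).std(ddof=1)
        for mult, kept in ((4.5, False), (2.0, True)):
            vals = np.concatenate([base, [10 ** (lm + mult * ls)]])
            out = screen_and_transform(self._frame(vals))
            assert bool(out.data["included"].iloc[-1]) is kept

    def test_non_positive_values_excluded_with_reason(self):
        out = screen_and_transform(self._frame([8.0] * 9 + [0.0]))
        assert not out.data["included"].iloc[-1]
        assert "non-positive" in out.data["reason"].iloc[-1]

    def test_log_transform_reduces_skew_of_lognormal(self, rng):
        vals = 10 ** rng.normal(0.5, 0.3, 400)
        out = screen_and_transform(self._frame(vals))
        row = out.skew_kurtosis.query("measure == 'sigma_int'").iloc[0]
        assert row["skew_raw"] > 0.5
        assert abs(row["skew_log"]) < abs(row["skew_raw"])

    def test_outliers_are_rare_in_default_cohorts(self, structure_rates):
        # the three-z screen on log measures flags only a small fraction of
        # values (heavy right tail of sampling estimates at high MTN)
        n_values = structure_rates["n_seeds"] * structure_rates["n_participants"] * 2 * 3
        assert structure_rates["total_outliers"] / n_values < 0.01


class TestTrajectories:
    def _make(self, rng, slopes=(-0.2, -0.4), noise=0.1, n=120):
        ages = np.tile(np.repeat([5.0, 7.25, 9.17, 11.25, 26.75], n // 5), 2)
        la = np.log10(ages)
        speed = np.repeat([1.5, 6.0], n)
        pid = np.tile([f"p{i}" for i in range(n)], 2)
        slope = np.where(speed == 1.5, slopes[0], slopes[1])
        y = 1.0 + slope * la + rng.normal(0, noise, 2 * n)
        return y, la, speed, pid

    def test_recovers_generative_slopes(self, rng):
        y, la, speed, pid = self._make(rng)
        fit = fit_trajectory(y, la, speed, pid)
        for _, row in fit.per_speed.iterrows():
            truth = -0.2 if row["speed"] == 1.5 else -0.4
            assert abs(row["slope"] - truth) < 2.5 * row["slope_se"]

    def test_detects_generative_interaction(self, rng):
        y, la, speed, pid = self._make(rng)
        fit = fit_trajectory(y, la, speed, pid)
        assert fit.interaction_slope < 0
        assert fit.interaction_p < 0.05

    def test_null_interaction_calibrated(self):
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(400):
            y, la, speed, pid = self._make(rng, slopes=(-0.3, -0.3), n=60)
            if fit_trajectory(y, la, speed, pid).interaction_p < 0.05:
                rejections += 1
        assert 0.01 < rejections / 400 < 0.10

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError):
            fit_trajectory([1.0, 2.0], [0.7, 0.7], ["a", "b"])


class TestHierarchicalRegression:
    def _cohortlike(self, rng, n=120, noise_drives=False):
        la = np.log10(np.repeat([5.0, 7.25, 9.17, 11.25, 26.75], n // 5))
        ln = 0.3 * (la - la.mean()) + rng.normal(0, 0.12, n)
        ls = -0.2 * (la - la.mean()) + rng.normal(0, 0.12, n)
        driver = ls if noise_drives else ln
        y = -0.3 - 0.25 * la - 0.5 * driver + rng.normal(0, 0.08, n)
        return y, la, ln, ls

    def test_sampling_enters_noise_excluded_when_sampling_drives(self, rng):
        y, la, ln, ls = self._cohortlike(rng)
        rep = hierarchical_regression(y, la, ln, ls)
        assert "log_sampling" in rep.entered
        assert "log_internal_noise" not in rep.entered
        assert rep.excluded["log_internal_noise"] > 0.05

    def test_symmetric_case_detects_noise(self, rng):
        y, la, ln, ls = self._cohortlike(rng, noise_drives=True)
        rep = hierarchical_regression(y, la, ln, ls)
        assert "log_internal_noise" in rep.entered

    def test_delta_r2_identity(self, rng):
        y, la, ln, ls = self._cohortlike(rng)
        rep = hierarchical_regression(y, la, ln, ls)
        assert rep.steps[1].delta_r2 == pytest.approx(rep.steps[1].r2 - rep.steps[0].r2, abs=1e-12)
        assert rep.steps[1].delta_r2 >= 0

    def test_age_null_is_calibrated(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(300):
            n = 100
            la = np.log10(np.repeat([5.0, 7.25, 9.17, 11.25, 26.75], n // 5))
            y = rng.normal(0, 0.1, n)
            ln = rng.normal(0, 0.12, n)
            ls = rng.normal(0, 0.12, n)
            rep = hierarchical_regression(y, la, ln, ls)
            if rep.steps[0].table.query("term == 'log_age'")["p"].iloc[0] < 0.05:
                hits += 1
        assert 0.01 < hits / 300 < 0.11

    def test_step2_r2_independent_of_entry_order(self, rng):
        # when both covariates belong in the model, the final step equals
        # the full OLS fit regardless of which entered first
        import statsmodels.api as sm

        n = 150
        la = np.log10(np.repeat([5.0, 7.25, 9.17, 11.25, 26.75], n // 5))
        ln = 0.3 * (la - la.mean()) + rng.normal(0, 0.12, n)
        ls = -0.2 * (la - la.mean()) + rng.normal(0, 0.12, n)
        y = -0.3 - 0.25 * la - 0.4 * ln + 0.4 * ls + rng.normal(0, 0.03, n)
        rep = hierarchical_regression(y, la, ln, ls)
        assert set(rep.entered) == {"log_sampling", "log_internal_noise"}
        X = np.column_stack([la, ln, ls])
        full = sm.OLS(y, sm.add_constant(X)).fit()
        assert rep.steps[1].r2 == pytest.approx(full.rsquared, abs=1e-12)


class TestCorrelations:
    def _screened(self, x, y):
        n = len(x)
        return pd.DataFrame(
            dict(
                speed=[1.5] * n,
                log10_sigma_int=x,
                log10_n_samp=x,
                log10_coherence_threshold=y,
            )
        )

    def test_perfect_negative_line(self):
        x = np.linspace(0, 1, 10)
        out = correlations(self._screened(x, -2 * x + 1))
        assert np.allclose(out["r"], -1.0)
        assert (out["df"] == 8).all()

    def test_permuted_labels_kill_correlation(self, rng):
        x = np.linspace(0, 1, 60)
        y = -2 * x + rng.normal(0, 0.1, 60)
        hits, rs = 0, []
        for _ in range(200):
            yp = rng.permutation(y)
            out = correlations(self._screened(x, yp))
            rs.append(abs(out["r"].iloc[0]))
            hits += out["p"].iloc[0] < 0.05
        assert np.mean(rs) < 0.15
        assert hits / 200 < 0.12

    def test_zero_variance_reported_not_crashed(self):
        out = correlations(self._screened(np.ones(10), np.linspace(0, 1, 10)))
        assert out["note"].str.contains("zero variance").all()
        assert out["r"].isna().all()


class TestFixationStability:
    def _traces(self, xy, val=0):
        n = len(xy)
        return pd.DataFrame(
            dict(
                participant_id=["p"] * n,
                task=["t"] * n,
                speed=[1.5] * n,
                x_l=xy[:, 0],
                y_l=xy[:, 1],
                x_r=xy[:, 0],
                y_r=xy[:, 1],
                val_l=[val] * n,
                val_r=[val] * n,
            )
        )

    def test_degenerate_zero_spread_flagged(self):
        out = fixation_stability(self._traces(np.full((50, 2), 0.5)))
        assert out.loc[0, "flag"] == "zero spread"
        assert np.isnan(out.loc[0, "log10_pooled_sd"])

    def test_all_invalid_flagged_missing(self):
        out = fixation_stability(self._traces(np.random.default_rng(0).normal(size=(50, 2)), val=3))
        assert out.loc[0, "flag"] == "too few valid samples"

    def test_isotropic_scatter_recovers_sd(self, rng):
        xy = rng.normal(0.5, 0.08, size=(20_000, 2))
        out = fixation_stability(self._traces(xy))
        assert out.loc[0, "pooled_sd"] == pytest.approx(0.08, rel=0.03)
        assert out.loc[0, "log10_pooled_sd"] == pytest.approx(math.log10(0.08), abs=0.02)

    def test_rms_vs_mean_pooling(self, rng):
        xy = rng.normal(0.5, 0.05, size=(5000, 2))
        xy[:, 1] *= 3  # anisotropic spread
        rms = fixation_stability(self._traces(xy), method="rms").loc[0, "pooled_sd"]
        amean = fixation_stability(self._traces(xy), method="mean").loc[0, "pooled_sd"]
        assert rms > amean  # RMS dominates the arithmetic mean
        with pytest.raises(ValueError):
            fixation_stability(self._traces(xy), method="median")


class TestFullPipeline:
    def test_analysis_is_deterministic(self, default_dataset, lapse_table):
        a = analyze(default_dataset, lapse_table=lapse_table)
        b = analyze(default_dataset, lapse_table=lapse_table)
        pd.testing.assert_frame_equal(a.screened.data, b.screened.data)
        assert a.regressions.keys() == b.regressions.keys()
        for sp in a.regressions:
            pd.testing.assert_frame_equal(a.regressions[sp].steps[1].table, b.regressions[sp].steps[1].table)

    def test_report_written_to_disk(self, default_report, tmp_path):
        default_report.write(tmp_path)
        for name in ("screened_estimates.csv", "skew_kurtosis.csv", "trajectories.csv",
                     "correlations.csv", "regression.csv"):
            assert (tmp_path / name).exists()

    def test_sampling_anticorrelates_with_coherence_thresholds(self, default_report):
        tab = default_report.correlation_table
        ns = tab[tab["measure"] == "n_samp"]
        assert (ns["r"] < 0).all()
        assert (ns["p"] < 0.01).all()

    def test_en_measures_positively_skewed_before_log(self, default_report):
        # the motivation for the log transform: raw noise and sampling
        # estimates have heavy right tails (coherence is ceiling-compressed)
        sk = default_report.screened.skew_kurtosis
        en = sk[sk["measure"].isin(["sigma_int", "n_samp"])]
        assert (en["skew_raw"] > 0).all()
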