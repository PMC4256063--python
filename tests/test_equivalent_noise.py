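import math

import numpy as np
import pytest
from scipy.stats import norm, pearsonr

from equinoise.equivalent_noise import (
    EQ2_COEFFS,
    LapseCorrectionTable,
    MtnSimulationConfig,
    en_curve,
    estimates_from_thresholds,
    fit_en_full,
    lapse_correct,
    lapse_correction_build,
    mtn_from_nsamp,
    nsamp_from_mtn,
    rederive_mtn_mapping,
    sigma_int_from,
)
from equinoise.observer import ObserverParams, en_decision_batch
from equinoise.staircase import run_en_task


class TestPrintedMapping:
    def test_anchor_values(self):
        # direct evaluation of the printed coefficients
        assert nsamp_from_mtn(0.0) == pytest.approx(math.exp(-1.8093), rel=1e-9)
        assert nsamp_from_mtn(0.0) == pytest.approx(0.1637, abs=5e-4)
        expected_45 = math.exp(0.000121 * 2025 + 0.0357 * 45 - 1.8093)
        assert nsamp_from_mtn(45.0) == pytest.approx(expected_45, rel=1e-12)
        assert nsamp_from_mtn(45.0) == pytest.approx(1.043, abs=1e-3)

    def test_strictly_increasing(self):
        assert nsamp_from_mtn(60) > nsamp_from_mtn(45) > nsamp_from_mtn(30)

    def test_negative_mtn_rejected(self):
        with pytest.raises(ValueError):
            nsamp_from_mtn(-1.0)

    def test_inverse_round_trip(self):
        for n in (0.3, 1.0, 2.0):
            assert nsamp_from_mtn(mtn_from_nsamp(n)) == pytest.approx(n, rel=1e-10)
        # unit sampling sits near 44 deg on the printed quadratic
        assert mtn_from_nsamp(1.0) == pytest.approx(44.09, abs=0.05)


class TestDecomposition:
    def test_unit_sampling_identity(self):
        assert sigma_int_from(7.3, 1.0) == pytest.approx(7.3)

    def test_staircase_example(self):
        # inverse of the staircase closed-form example: 4.41 deg at n=1.85
        assert sigma_int_from(6.0 / math.sqrt(1.85), 1.85) == pytest.approx(6.0, rel=1e-12)

    def test_en_curve_zero_noise_limit(self):
        assert en_curve(6.0, 2.0, 0.0) == pytest.approx(6.0 / math.sqrt(2.0))
        # algebraic inverse: sigma_int_from(en_curve(s, n, 0), n) == s
        for s, n in ((4, 0.5), (6, 1.0), (10, 2.0)):
            assert sigma_int_from(en_curve(s, n, 0.0), n) == pytest.approx(s, rel=1e-12)

    def test_en_curve_high_noise_asymptote(self):
        # slope 1 on log-log axes once external noise dominates
        t1 = en_curve(6.0, 2.0, 600.0)
        t2 = en_curve(6.0, 2.0, 6000.0)
        assert math.log10(t2 / t1) == pytest.approx(1.0, abs=1e-4)

    def test_en_curve_monotone_in_external_noise(self):
        xs = np.linspace(0, 100, 50)
        t = en_curve(6.0, 1.3, xs)
        assert np.all(np.diff(t) >= 0)

    def test_estimates_bundle_consistent(self):
        est = estimates_from_thresholds(4.41, 61.0)
        assert est.sigma_int == pytest.approx(est.no_noise_threshold * math.sqrt(est.n_samp), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sigma_int_from(-1.0, 1.0)
        with pytest.raises(ValueError):
            en_curve(6.0, 0.0, 1.0)


class TestFullCurveFit:
    def test_recovers_exact_parameters_from_noiseless_curve(self):
        xs = [0, 5, 10, 20, 40, 80]
        pts = [(x, en_curve(6.0, 2.0, x)) for x in xs]
        sig, n = fit_en_full(pts)
        assert sig == pytest.approx(6.0, abs=1e-4)
        assert n == pytest.approx(2.0, abs=1e-4)

    def test_robust_to_multiplicative_threshold_noise(self):
        rng = np.random.default_rng(11)
        xs = np.array([0, 5, 10, 20, 40, 80], dtype=float)
        sigs, ns = [], []
        for _ in range(500):
            noisy = en_curve(6.0, 2.0, xs) * np.exp(rng.normal(0, 0.2, xs.size))
            s, n = fit_en_full(list(zip(xs, noisy)))
            sigs.append(s)
            ns.append(n)
        assert abs(np.median(sigs) / 6.0 - 1) < 0.10
        assert abs(np.median(ns) / 2.0 - 1) < 0.10

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_en_full([(0.0, 5.0), (0.0, 5.1), (0.0, 4.9)])

    def test_rapid_estimates_track_full_fit(self):
        """Two-point and full-curve n_samp agree (r > 0.8) across observers."""
        rng = np.random.default_rng(21)
        xs = np.array([0, 5, 10, 20, 40, 80], dtype=float)
        z84 = norm.ppf(0.84)
        rapid, full = [], []
        observers = [
            ObserverParams(s, n, 0.0)
            for s in (4.0, 5.5, 7.0, 8.5, 10.0)
            for n in (0.5, 0.9, 1.5, 2.2)
        ]
        for obs in observers:
            res = run_en_task(obs, 1.5, rng)
            rapid.append(math.log10(estimates_from_thresholds(
                res.thresholds["no_noise"], res.thresholds["high_noise"]).n_samp))
            # slow-paradigm oracle: constant-stimuli thresholds at 6 levels
            pts = []
            for x in xs:
                pred = en_curve(obs.sigma_int, obs.n_samp, x)
                right, _ = en_decision_batch(obs, np.full(4000, z84 * pred), x, rng)
                p = np.clip(np.mean(right), 0.55, 0.999)
                pts.append((x, z84 * pred / norm.ppf(p) * z84))
            full.append(math.log10(fit_en_full(pts)[1]))
        r, _ = pearsonr(rapid, full)
        assert r > 0.8


@pytest.fixture(scope="module")
def mapping():
    return rederive_mtn_mapping(MtnSimulationConfig(), np.random.default_rng(5))


class TestMappingRederivation:
    def test_mapping_is_monotone_over_simulated_range(self, mapping):
        mtns = np.linspace(mapping.mtn_grid.min(), mapping.mtn_grid.max(), 50)
        assert np.all(np.diff(mapping.predict(mtns)) > 0)
        assert np.all(np.diff(mapping.mtn_grid) > 0)

    def test_fit_quality(self, mapping):
        assert mapping.r_squared > 0.99

    def test_unit_sampling_falls_near_printed_crossing(self, mapping):
        # where the printed quadratic equals 1 (~44 deg), the simulated
        # observer's MTN at n_samp = 1 lands within a few degrees
        mtn_at_1 = float(np.interp(0.0, np.log(mapping.n_samp_grid), mapping.mtn_grid))
        assert abs(mtn_at_1 - mtn_from_nsamp(1.0)) < 3.0

    def test_agreement_with_printed_coefficients_near_unit_sampling(self, mapping):
        # the printed coefficients and the ideal-observer re-derivation
        # agree in the mid range; the acceptance suite probes the full band
        for mtn in (40.0, 45.0, 50.0, 55.0):
            assert mapping.predict(mtn) / nsamp_from_mtn(mtn) == pytest.approx(1.0, abs=0.15)

    def test_tiny_simulation_warns(self):
        with pytest.warns(UserWarning, match="noisy"):
            MtnSimulationConfig(trials_per_level=100)


class TestLapseCorrection:
    def test_identity_at_zero_lapse(self, lapse_table):
        for task in ("no_noise", "high_noise", "coherence"):
            assert lapse_table.factor(task, 0.0) == 1.0
        assert lapse_correct(5.0, 0.0, lapse_table, "no_noise") == 5.0

    def test_factors_monotone_in_lapse(self, lapse_table):
        g = lapse_table.observed_lapse_grid
        for task in ("no_noise", "coherence"):
            f = np.array([lapse_table.factor(task, x) for x in g])
            assert np.all(np.diff(f) >= 0) and f[-1] > 1.0
        f = np.array([lapse_table.factor("high_noise", x) for x in g])
        assert np.all(np.diff(f) <= 0) and f[-1] < 1.0

    def test_out_of_grid_lapse_clamped_with_warning(self, lapse_table):
        with pytest.warns(UserWarning, match="clamped"):
            hi = lapse_table.factor("no_noise", 0.4)
        assert hi == lapse_table.factor("no_noise", lapse_table.observed_lapse_grid[-1])

    def test_json_round_trip(self, lapse_table):
        back = LapseCorrectionTable.from_json(lapse_table.to_json())
        assert np.allclose(back.observed_lapse_grid, lapse_table.observed_lapse_grid)
        for k in lapse_table.factors:
            assert np.allclose(back.factors[k], lapse_table.factors[k])

    def test_correction_restores_lapse_free_internal_noise(self, lapse_table):
        """Correcting a lapsing observer's thresholds recovers the lapse-free sigma_int.

        Paired common-seed runs; the correction is applied at the
        observer's expected catch-trial error rate (half the true lapse
        probability), which isolates the accuracy of the correction table
        from the binomial noise of a single 15-trial lapse estimate.
        """
        lam_observed = 0.04 / 2
        sig_free, sig_corr = [], []
        for i in range(200):
            r0 = run_en_task(ObserverParams(6.0, 1.0, 0.0), 1.5, np.random.default_rng(300_000 + i))
            sig_free.append(estimates_from_thresholds(
                r0.thresholds["no_noise"], r0.thresholds["high_noise"]).sigma_int)
            r4 = run_en_task(ObserverParams(6.0, 1.0, 0.04), 1.5, np.random.default_rng(300_000 + i))
            nn = lapse_correct(r4.thresholds["no_noise"], lam_observed, lapse_table, "no_noise")
            mtn = lapse_correct(r4.thresholds["high_noise"], lam_observed, lapse_table, "high_noise")
            sig_corr.append(estimates_from_thresholds(nn, mtn).sigma_int)
        assert abs(np.median(sig_corr) / np.median(sig_free) - 1) < 0.05

    def test_unknown_task_rejected(self, lapse_table):
        with pytest.raises(KeyError):
            lapse_table.factor("detection", 0.0)
        with pytest.raises(ValueError):
            lapse_correction_build(task_types=("detection",), n_replicates=2)
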