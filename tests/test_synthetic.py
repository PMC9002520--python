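"""The cohort generator: determinism, calibration, and injected-parameter
recovery."""

import numpy as np
import pytest

from sleepvalid.epochs import EpochSeries
from sleepvalid.hypnogram import STAGES, Hypnogram, summary_vars
from sleepvalid.synthetic import (
    CohortConfig,
    DeviceConfig,
    HypnogramConfig,
    VitalsConfig,
    gen_cohort,
    gen_device_observation,
    gen_hypnogram,
    gen_reference_vitals,
    gen_scorer_panel,
)


class TestGenHypnogram:
    def test_absorbing_wake_gives_all_wake_night(self):
        P = np.eye(5)
        cfg = HypnogramConfig(time_in_bed=100, transition=P)
        hyp = gen_hypnogram(cfg, seed=0)
        assert (hyp.stages == "W").all()
        assert summary_vars(hyp).tst == 0.0

    def test_invalid_transition_matrix_rejected(self):
        P = np.full((5, 5), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            gen_hypnogram(HypnogramConfig(transition=P), seed=0)

    def test_reproducible_under_fixed_seed(self):
        cfg = HypnogramConfig(time_in_bed=500)
        a = gen_hypnogram(cfg, seed=42)
        b = gen_hypnogram(cfg, seed=42)
        assert np.array_equal(a.stages, b.stages)

    def test_night_begins_in_wake(self):
        for seed in range(20):
            assert gen_hypnogram(HypnogramConfig(), seed=seed).stages[0] == "W"

    def test_two_state_chain_matches_stationary_fraction(self):
        """p(W->S) = p(S->W) = 0.1: stationary sleep fraction is 1/2."""
        P = np.zeros((5, 5))
        P[0, 0], P[0, 2] = 0.9, 0.1   # W <-> N2
        P[2, 2], P[2, 0] = 0.9, 0.1
        P[1, 1] = P[3, 3] = P[4, 4] = 1.0
        cfg = HypnogramConfig(
            time_in_bed=20_000, transition=P,
            initial_sleep=np.array([0, 0, 1.0, 0, 0]),
            sol_mean_min=0.5, sol_sd_min=0.1,
        )
        hyp = gen_hypnogram(cfg, seed=3)
        frac = (hyp.stages != "W").mean()
        # MC SE of the mean of a two-state chain with switching prob 0.1:
        # var = pi(1-pi) * (1+rho)/(1-rho), rho = 1 - 0.2 = 0.8 -> 3 SE
        se = np.sqrt(0.25 * (1.8 / 0.2) / 20_000)
        assert abs(frac - 0.5) <= 3 * se

    def test_default_chain_reproduces_cohort_tst(self):
        """Mean TST across many nights lands within ±15 min of 388.7."""
        rng = np.random.default_rng(21)
        tsts = []
        for _ in range(400):
            tib = int(np.clip(round(rng.normal(918, 55)), 686, 1036))
            hyp = gen_hypnogram(HypnogramConfig(time_in_bed=tib), rng)
            tsts.append(summary_vars(hyp).tst)
        assert abs(np.mean(tsts) - 388.7) <= 15.0


class TestScorerPanel:
    def test_zero_error_rate_reproduces_truth(self):
        truth = gen_hypnogram(HypnogramConfig(time_in_bed=300), seed=1)
        scorers, expert = gen_scorer_panel(truth, error_rate=0.0, seed=2)
        for s in scorers:
            assert np.array_equal(s.stages, truth.stages)
        assert np.array_equal(expert.stages, truth.stages)

    def test_disagreement_fraction_matches_error_rate(self):
        truth = Hypnogram(np.array(["N2"] * 10_000))
        scorers, _ = gen_scorer_panel(truth, error_rate=0.10, seed=4)
        se = np.sqrt(0.1 * 0.9 / 10_000)
        for s in scorers:
            frac = (s.stages != truth.stages).mean()
            assert abs(frac - 0.10) <= 3 * se

    def test_errors_uniform_over_wrong_stages(self):
        truth = Hypnogram(np.array(["W"] * 40_000))
        scorers, _ = gen_scorer_panel(truth, error_rate=0.5, seed=5)
        wrong = scorers[0].stages[scorers[0].stages != "W"]
        _, counts = np.unique(wrong, return_counts=True)
        assert counts.min() / counts.max() > 0.9

    def test_expert_always_equals_truth(self):
        truth = gen_hypnogram(HypnogramConfig(time_in_bed=200), seed=6)
        _, expert = gen_scorer_panel(truth, error_rate=0.3, seed=7)
        assert np.array_equal(expert.stages, truth.stages)


class TestReferenceVitals:
    def test_noiseless_single_stage_equals_baseline(self):
        hyp = Hypnogram(np.array(["N2"] * 50))
        cfg = VitalsConfig(hr_ar_sd=0.0, br_ar_sd=0.0,
                           hr_trend_amp=0.0, br_trend_amp=0.0)
        _, _, hr, br = gen_reference_vitals(hyp, cfg, seed=0)
        assert np.allclose(hr.values, cfg.hr_baseline[2])
        assert np.allclose(br.values, cfg.br_baseline[2])

    def test_stage_means_ordered_by_baseline(self):
        stages = np.array(["W"] * 100 + ["N3"] * 100)
        hyp = Hypnogram(stages)
        cfg = VitalsConfig(
            hr_baseline=np.array([70.0, 65, 63, 58, 66]),
            hr_trend_amp=0.0, hr_ar_sd=0.5 * np.sqrt(1 - 0.97**2),
        )
        for seed in range(10):
            _, _, hr, _ = gen_reference_vitals(hyp, cfg, seed=seed)
            assert hr.values[:100].mean() > hr.values[100:].mean()

    def test_epoch_values_are_instantaneous_means(self):
        hyp = Hypnogram(np.array(["N1"] * 20))
        cfg = VitalsConfig()
        inst_hr, _, hr, _ = gen_reference_vitals(hyp, cfg, seed=8)
        spe = cfg.samples_per_epoch
        assert hr.values[3] == pytest.approx(inst_hr[3 * spe:4 * spe].mean())

    def test_pooled_cohort_mean_hr_br_calibration(self):
        """Pooled over 300 nights: HR within ±2 of 66.4, BR within ±0.5 of 14.9."""
        recs = []
        for block in range(3):
            recs += gen_cohort(CohortConfig(seed=7000 + block, n_subjects=100,
                                            psg_artifact_prob=0.0))
        hr = np.mean([r.ref_hr.values.mean() for r in recs])
        br = np.mean([r.ref_br.values.mean() for r in recs])
        assert abs(hr - 66.4) <= 2.0
        assert abs(br - 14.9) <= 0.5

    def test_nonpositive_baseline_rejected(self):
        cfg = VitalsConfig(hr_baseline=np.array([0.0, 60, 60, 60, 60]))
        with pytest.raises(ValueError, match="positive"):
            gen_reference_vitals(Hypnogram(np.array(["W"] * 5)), cfg, seed=0)


class TestDeviceObservation:
    def _refs(self, seed=0, n=400):
        hyp = gen_hypnogram(HypnogramConfig(time_in_bed=n), seed=seed)
        _, _, hr, br = gen_reference_vitals(hyp, VitalsConfig(), seed=seed)
        return hyp, hr, br

    def test_error_free_device_equals_reference(self):
        hyp, hr, br = self._refs()
        cfg = DeviceConfig(hr_bias=0, br_bias=0, hr_noise_c0=0, br_noise_c0=0,
                           hr_coverage=1, br_coverage=1, clock_offset_s=0)
        obs = gen_device_observation(hr, br, hyp, cfg, seed=1)
        assert np.allclose(obs.dev_hr.values, hr.values)
        assert np.allclose(obs.dev_br.values, br.values)
        assert obs.lag_epochs == 0

    def test_coverage_fraction_binomial(self):
        hyp = Hypnogram(np.array(["N2"] * 100_000))
        hr = EpochSeries(np.full(100_000, 60.0))
        br = EpochSeries(np.full(100_000, 15.0))
        cfg = DeviceConfig(hr_coverage=0.936, clock_offset_s=0)
        obs = gen_device_observation(hr, br, hyp, cfg, seed=2)
        se = np.sqrt(0.936 * 0.064 / 100_000)
        assert abs(obs.dev_hr.covered.mean() - 0.936) <= 3 * se

    def test_constant_bias_recovered_by_direct_arithmetic(self):
        hyp = Hypnogram(np.array(["N2"] * 10_000))
        hr = EpochSeries(np.full(10_000, 60.0))
        br = EpochSeries(np.full(10_000, 15.0))
        cfg = DeviceConfig(hr_bias=0.5, hr_noise_c0=1.0, br_noise_c0=0,
                           clock_offset_s=0, hr_coverage=1, br_coverage=1)
        obs = gen_device_observation(hr, br, hyp, cfg, seed=3)
        d = hr.values - obs.dev_hr.values
        se = 1.0 / np.sqrt(10_000)
        assert abs(d.mean() - 0.5) <= 3 * se

    def test_clock_offset_shifts_device_grid(self):
        hyp, hr, br = self._refs(n=300)
        cfg = DeviceConfig(clock_offset_s=90.0, hr_noise_c0=0, br_noise_c0=0,
                           hr_bias=0, br_bias=0, hr_coverage=1, br_coverage=1)
        obs = gen_device_observation(hr, br, hyp, cfg, seed=4)
        assert obs.lag_epochs == 3
        assert not obs.dev_hr.covered[:3].any()
        assert np.allclose(obs.dev_hr.values[3:], hr.values[:-3])

    def test_negative_noise_sd_rejected(self):
        hyp, hr, br = self._refs(n=100)
        cfg = DeviceConfig(hr_noise_c1=-1.0)
        with pytest.raises(ValueError, match="negative noise SD"):
            gen_device_observation(hr, br, hyp, cfg, seed=0)

    def test_movement_bursts_present_in_both_systems(self):
        hyp, hr, br = self._refs(seed=9)
        obs = gen_device_observation(hr, br, hyp, DeviceConfig(), seed=5)
        assert obs.ref_move.values.max() > 3.0
        assert obs.dev_move.values.max() > 3.0


class TestGenCohort:
    def test_same_seed_bit_identical(self):
        a = gen_cohort(CohortConfig(seed=9, n_subjects=1))[0]
        b = gen_cohort(CohortConfig(seed=9, n_subjects=1))[0]
        assert np.array_equal(a.hyp_truth.stages, b.hyp_truth.stages)
        assert np.array_equal(a.ref_hr.values, b.ref_hr.values)
        assert np.array_equal(a.dev_hr.values, b.dev_hr.values,
                              equal_nan=True)
        assert np.array_equal(a.score, b.score)
        assert a.truth == b.truth

    def test_default_cohort_size_and_grid_range(self):
        recs = gen_cohort(CohortConfig(seed=1))
        assert len(recs) == 45
        for r in recs:
            assert 686 <= r.n_epochs <= 1036

    def test_all_series_share_the_epoch_grid(self):
        for r in gen_cohort(CohortConfig(seed=2, n_subjects=3)):
            n = r.n_epochs
            for s in (r.ref_hr, r.dev_hr, r.ref_br, r.dev_br,
                      r.ref_move, r.dev_move):
                assert len(s) == n
            assert len(r.score) == n and len(r.pred_sleep) == n
            assert r.lights_on > r.lights_off

    def test_negative_bmi_coupling_gives_negative_correlation(self):
        """Noise SD is a deterministic linear function of BMI, so the
        sample correlation across subjects must be negative whenever the
        coupling coefficient is."""
        for seed in range(5):
            recs = gen_cohort(CohortConfig(
                seed=100 + seed, n_subjects=40,
                bmi_noise_coef=-0.2, sex_noise_coef=0.0,
            ))
            bmi = np.array([r.bmi for r in recs])
            sd = np.array([r.truth["hr_noise_c0"] for r in recs])
            assert np.corrcoef(bmi, sd)[0, 1] < 0

    def test_injected_parameters_stored(self):
        rec = gen_cohort(CohortConfig(seed=3, n_subjects=1))[0]
        for key in ("hr_bias", "br_bias", "hr_noise_c0", "lag_epochs",
                    "time_in_bed"):
            assert key in rec.truth
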