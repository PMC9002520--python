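"""Synthetic subject-night generator for the validation pipeline.

The study data behind contactless-sleep-tracker validations are rarely
shareable, so this module fabricates whole cohorts with the statistical
structure the downstream analysis assumes, calibrated by default to a
typical adult laboratory cohort (mean TST ≈ 389 min, WASO ≈ 54 min,
SOL ≈ 16 min, SE ≈ 0.87, overnight HR ≈ 66 bpm, BR ≈ 15 breaths/min):

* hypnograms from a first-order 5-stage Markov chain at 30 s resolution,
  with sleep-onset latency drawn from a lognormal so the empirical SOL
  distribution is right-skewed as in real cohorts;
* stage-dependent instantaneous heart and breathing rates (baseline per
  stage + slow overnight dip + AR(1) fluctuation), averaged into epoch
  means;
* a device observation model with constant and proportional bias,
  heteroscedastic Gaussian noise, Bernoulli coverage gaps, an integer
  clock offset/drift, a logistic-noise sleep score thresholded into a
  sleep/wake prediction, and movement bursts at wake-bout onsets visible
  in both systems;
* a three-technician scorer panel with symmetric stage-confusion errors
  plus an error-free expert for tie-breaking;
* subject covariates (age, sex, BMI, AHI) that can couple into the
  device HR noise so concordance degrades with BMI and differs by sex.

Every injected parameter is retained in ``SubjectRecord.truth`` so tests
can check end-to-end recovery.  Reproducibility: subject ``i`` of a
cohort uses ``default_rng(master_seed + i)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit, logit

from .epochs import EpochSeries
from .hypnogram import EPOCH_SECONDS, STAGES, Hypnogram

__all__ = [
    "HypnogramConfig",
    "VitalsConfig",
    "DeviceConfig",
    "CohortConfig",
    "SubjectRecord",
    "DeviceObservation",
    "gen_hypnogram",
    "gen_scorer_panel",
    "gen_reference_vitals",
    "gen_device_observation",
    "gen_cohort",
    "default_transition_matrix",
]

_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def default_transition_matrix() -> np.ndarray:
    """Per-epoch stage transition probabilities (rows: W, N1, N2, N3, REM).

    Tuned so that, after sleep onset, the chain's long-run stage mix is
    ≈ (0.12 W, 0.05 N1, 0.50 N2, 0.20 N3, 0.13 REM) with plausible bout
    lengths (wake bouts ≈ 2.5 min, N3 bouts ≈ 8 min), which reproduces
    the target cohort's WASO and TST on the default time-in-bed grid.
    """
    return np.array([
        # W      N1     N2     N3     REM
        [0.800, 0.150, 0.050, 0.000, 0.000],   # W
        [0.090, 0.455, 0.430, 0.000, 0.025],   # N1
        [0.027, 0.010, 0.924, 0.024, 0.015],   # N2
        [0.012, 0.000, 0.048, 0.940, 0.000],   # N3
        [0.034, 0.013, 0.020, 0.000, 0.933],   # REM
    ])


@dataclass
class HypnogramConfig:
    """Markov-chain hypnogram model on the 30 s epoch grid.

    ``sol_mean_min`` / ``sol_sd_min`` parameterize the lognormal
    sleep-onset latency in minutes (distribution mean and SD, not
    log-scale parameters).
    """

    time_in_bed: int = 918                 # epochs (≈ 7 h 39 min)
    transition: np.ndarray = field(default_factory=default_transition_matrix)
    initial_sleep: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.70, 0.28, 0.00, 0.02])
    )
    sol_mean_min: float = 16.4
    sol_sd_min: float = 13.6
    epoch_seconds: float = EPOCH_SECONDS

    def validate(self) -> None:
        P = np.asarray(self.transition, dtype=float)
        if P.shape != (5, 5):
            raise ValueError("transition matrix must be 5x5")
        if (P < 0).any() or (P > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.abs(P.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("transition matrix rows must sum to 1")
        if self.time_in_bed < 1:
            raise ValueError("time_in_bed must be >= 1 epoch")
        if self.sol_mean_min <= 0 or self.sol_sd_min <= 0:
            raise ValueError("SOL distribution parameters must be positive")


@dataclass
class VitalsConfig:
    """Stage-dependent instantaneous HR/BR model.

    Baselines are in beats (breaths) per minute per stage in the order
    W, N1, N2, N3, REM.  The overnight trend is a mid-night dip of
    ``trend_amp`` units (zero at lights-off and lights-on).  Fluctuation
    is AR(1) on the instantaneous samples.
    """

    hr_baseline: np.ndarray = field(
        default_factory=lambda: np.array([72.9, 69.4, 67.4, 64.4, 70.4])
    )
    br_baseline: np.ndarray = field(
        default_factory=lambda: np.array([16.2, 15.6, 15.2, 14.7, 15.7])
    )
    hr_trend_amp: float = 2.0
    br_trend_amp: float = 0.3
    ar_coef: float = 0.97
    hr_ar_sd: float = 0.4               # innovation SD, bpm
    br_ar_sd: float = 0.12
    samples_per_epoch: int = 60         # one instantaneous value per 0.5 s

    def validate(self) -> None:
        if (np.asarray(self.hr_baseline) <= 0).any() or (
            np.asarray(self.br_baseline) <= 0
        ).any():
            raise ValueError("stage baselines must be strictly positive")
        if not -1.0 < self.ar_coef < 1.0:
            raise ValueError("AR(1) coefficient must be in (-1, 1)")
        if self.samples_per_epoch < 1:
            raise ValueError("samples_per_epoch must be >= 1")


@dataclass
class DeviceConfig:
    """Device error structure.

    All biases are defined as reference − device, so a positive constant
    bias makes the device underestimate.  Noise SD at reference value x
    is ``noise_c0 + noise_c1·x`` (heteroscedastic when the slope is
    nonzero).  The sleep score is logistic(logit(p_state) + noise) with
    ``p_state`` high during sleep epochs; the binary prediction is
    score ≥ threshold.
    """

    hr_bias: float = 0.23               # ref − dev, bpm (device overreads HR slightly)
    br_bias: float = 0.08
    hr_prop_bias: float = 0.0
    br_prop_bias: float = 0.0
    hr_noise_c0: float = 3.2            # bpm
    hr_noise_c1: float = 0.0
    br_noise_c0: float = 1.05
    br_noise_c1: float = 0.0
    hr_coverage: float = 0.936
    br_coverage: float = 0.994
    clock_offset_s: float = 60.0
    clock_drift_s_per_h: float = 0.0
    score_sleep_p: float = 0.90
    score_wake_p: float = 0.52
    score_noise_sd: float = 1.41
    score_noise_ar: float = 0.75        # epoch-to-epoch correlation of the logit noise
    score_threshold: float = 0.5
    move_burst_amp: float = 5.0
    move_noise_sd: float = 0.2

    def validate(self) -> None:
        for name, p in (("hr_coverage", self.hr_coverage),
                        ("br_coverage", self.br_coverage)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.hr_noise_c0 < 0 or self.br_noise_c0 < 0:
            raise ValueError("noise SD intercepts must be >= 0")
        if not 0.0 < self.score_threshold < 1.0:
            raise ValueError("score_threshold must lie in (0, 1)")
        if not -1.0 < self.score_noise_ar < 1.0:
            raise ValueError("score_noise_ar must lie in (-1, 1)")
        for name, p in (("score_sleep_p", self.score_sleep_p),
                        ("score_wake_p", self.score_wake_p)):
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class CohortConfig:
    """Cohort-level distributions and covariate-noise coupling."""

    n_subjects: int = 45
    seed: int = 0
    age_mean: float = 41.2
    age_sd: float = 10.5
    age_min: float = 22.0
    age_max: float = 64.0
    female_prop: float = 0.556
    bmi_mean: float = 25.9
    bmi_sd: float = 4.4
    ahi_log_mean: float = 0.75          # lognormal; mean ≈ 6.5 events/h
    ahi_log_sd: float = 1.5
    tib_mean_epochs: float = 918.0
    tib_sd_epochs: float = 55.0
    tib_min_epochs: int = 686
    tib_max_epochs: int = 1036
    hr_between_sd: float = 9.0          # between-subject HR level SD, bpm
    br_between_sd: float = 2.0
    bmi_noise_coef: float = 0.15        # added HR noise SD per kg/m² above the mean
    sex_noise_coef: float = 0.8         # added HR noise SD for female subjects
    psg_artifact_prob: float = 0.01
    scorer_error_rate: float = 0.10

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.female_prop <= 1.0:
            raise ValueError("female_prop must lie in [0, 1]")
        if not 0.0 <= self.psg_artifact_prob <= 1.0:
            raise ValueError("psg_artifact_prob must lie in [0, 1]")
        if not 0.0 <= self.scorer_error_rate < 1.0:
            raise ValueError("scorer_error_rate must lie in [0, 1)")


@dataclass
class DeviceObservation:
    """Everything the device reports for one night."""

    dev_hr: EpochSeries
    dev_br: EpochSeries
    score: np.ndarray
    pred_sleep: np.ndarray
    ref_move: EpochSeries
    dev_move: EpochSeries
    lag_epochs: int


@dataclass
class SubjectRecord:
    """One synthetic participant-night with its ground truth."""

    subject_id: str
    age: float
    sex_female: int
    bmi: float
    ahi: float
    hyp_truth: Hypnogram
    scorers: tuple[Hypnogram, Hypnogram, Hypnogram]
    expert: Hypnogram
    ref_hr: EpochSeries
    dev_hr: EpochSeries
    ref_br: EpochSeries
    dev_br: EpochSeries
    score: np.ndarray
    pred_sleep: np.ndarray
    ref_move: EpochSeries
    dev_move: EpochSeries
    lights_off: int
    lights_on: int
    truth: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return len(self.hyp_truth)


def _sol_lognormal_params(mean_min: float, sd_min: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd_min / mean_min) ** 2)
    mu = np.log(mean_min) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def gen_hypnogram(config: HypnogramConfig, seed=0) -> Hypnogram:
    """Simulate one night of stage labels.

    The night starts in W; the sleep-onset epoch is drawn from the
    lognormal latency distribution, the onset stage from the
    ``initial_sleep`` distribution, and the chain then evolves under the
    transition matrix (which may revisit W, producing WASO).  If the W
    row has no mass on sleep stages (absorbing wake) the whole night is
    wake.
    """
    config.validate()
    rng = _rng(seed)
    tib = config.time_in_bed
    P = np.asarray(config.transition, dtype=float)
    stages = np.zeros(tib, dtype=int)  # W

    mu, sigma = _sol_lognormal_params(config.sol_mean_min, config.sol_sd_min)
    sol_min = rng.lognormal(mu, sigma)
    onset = int(round(sol_min * 60.0 / config.epoch_seconds))
    onset = max(1, onset)

    w_to_sleep = P[0, 1:].sum()
    if onset >= tib or w_to_sleep == 0.0:
        return Hypnogram(np.array(STAGES)[stages])

    init = np.asarray(config.initial_sleep, dtype=float).copy()
    init[0] = 0.0
    if init.sum() == 0:
        init[1:] = P[0, 1:]
    init = init / init.sum()
    stages[onset] = rng.choice(5, p=init)

    # per-epoch chain; uses one uniform per epoch against the cumulative rows
    cum = np.cumsum(P, axis=1)
    u = rng.random(tib)
    for t in range(onset + 1, tib):
        stages[t] = np.searchsorted(cum[stages[t - 1]], u[t])
    return Hypnogram(np.array(STAGES)[stages])


def gen_scorer_panel(
    truth: Hypnogram, error_rate: float = 0.10, seed=0
) -> tuple[tuple[Hypnogram, Hypnogram, Hypnogram], Hypnogram]:
    """Three independent technicians plus an error-free expert.

    Each scorer reproduces the true stage with probability
    1 − error_rate and otherwise picks uniformly among the four other
    stages.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must lie in [0, 1)")
    rng = _rng(seed)
    n = len(truth)
    truth_idx = np.array([_STAGE_INDEX[s] for s in truth.stages])
    scorers = []
    labels = np.array(STAGES)
    for _ in range(3):
        idx = truth_idx.copy()
        err = rng.random(n) < error_rate
        # uniform over the 4 wrong stages: offset 1..4 modulo 5
        idx[err] = (idx[err] + rng.integers(1, 5, size=int(err.sum()))) % 5
        scorers.append(Hypnogram(labels[idx], truth.lights_off, truth.lights_on))
    expert = Hypnogram(truth.stages.copy(), truth.lights_off, truth.lights_on)
    return tuple(scorers), expert


def gen_reference_vitals(
    hyp: Hypnogram, config: VitalsConfig, seed=0
) -> tuple[np.ndarray, np.ndarray, EpochSeries, EpochSeries]:
    """Instantaneous HR/BR series and their epoch means.

    value = stage baseline + overnight dip + AR(1) noise, floored at 1.
    Returns ``(inst_hr, inst_br, epoch_hr, epoch_br)``; the epoch series
    are exact within-epoch means of the instantaneous samples.
    """
    config.validate()
    rng = _rng(seed)
    n = len(hyp)
    spe = config.samples_per_epoch
    stage_idx = np.array([_STAGE_INDEX[s] for s in hyp.stages])
    stage_samples = np.repeat(stage_idx, spe)
    total = n * spe
    # mid-night dip, zero at both ends
    phase = np.linspace(0.0, np.pi, total)
    dip = -np.sin(phase)

    out = []
    for baseline, amp, innov_sd in (
        (np.asarray(config.hr_baseline, dtype=float), config.hr_trend_amp,
         config.hr_ar_sd),
        (np.asarray(config.br_baseline, dtype=float), config.br_trend_amp,
         config.br_ar_sd),
    ):
        noise = lfilter([1.0], [1.0, -config.ar_coef],
                        rng.normal(0.0, innov_sd, size=total))
        inst = baseline[stage_samples] + amp * dip + noise
        inst = np.maximum(inst, 1.0)
        epoch = inst.reshape(n, spe).mean(axis=1)
        out.append((inst, EpochSeries(epoch)))
    (inst_hr, epoch_hr), (inst_br, epoch_br) = out
    return inst_hr, inst_br, epoch_hr, epoch_br


def _epoch_lags(n: int, config: DeviceConfig) -> np.ndarray:
    t_h = (np.arange(n) * EPOCH_SECONDS) / 3600.0
    shift_s = config.clock_offset_s + config.clock_drift_s_per_h * t_h
    return np.round(shift_s / EPOCH_SECONDS).astype(int)


def _shift_from_reference(values: np.ndarray, lags: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """dev[i] = ref[i − lag_i]; returns (shifted values, validity mask)."""
    n = len(values)
    src = np.arange(n) - lags
    valid = (src >= 0) & (src < n)
    out = np.full(n, np.nan)
    out[valid] = values[src[valid]]
    return out, valid


def gen_device_observation(
    ref_hr: EpochSeries,
    ref_br: EpochSeries,
    hyp: Hypnogram,
    config: DeviceConfig,
    seed=0,
) -> DeviceObservation:
    """Corrupt the reference into what the device would report.

    Applies, in order: the clock shift (device epoch i reads the
    reference at i − lag), the bias model
    ``dev = ref − constant − proportional·ref + N(0, c0 + c1·ref)``,
    Bernoulli coverage gaps, the logistic sleep score and its threshold,
    and movement bursts at wake-bout onsets mirrored into both systems'
    movement channels (the device's on its shifted clock).
    """
    config.validate()
    rng = _rng(seed)
    n = len(ref_hr)
    if len(ref_br) != n or len(hyp) != n:
        raise ValueError("reference series are on different grids")
    lags = _epoch_lags(n, config)

    devs = []
    for ref, cbias, pbias, c0, c1, cov in (
        (ref_hr, config.hr_bias, config.hr_prop_bias,
         config.hr_noise_c0, config.hr_noise_c1, config.hr_coverage),
        (ref_br, config.br_bias, config.br_prop_bias,
         config.br_noise_c0, config.br_noise_c1, config.br_coverage),
    ):
        shifted, valid = _shift_from_reference(ref.values, lags)
        sd = np.where(valid, c0 + c1 * np.nan_to_num(shifted), 0.0)
        if (sd < 0).any():
            raise ValueError(
                "negative noise SD at an observed reference value; "
                "check noise_c0/noise_c1"
            )
        vals = shifted - cbias - pbias * shifted + rng.normal(0.0, 1.0, n) * sd
        covered = valid & (rng.random(n) < cov)
        devs.append(EpochSeries(vals, covered=covered))
    dev_hr, dev_br = devs

    # sleep score on the device clock
    sleep_truth = hyp.is_sleep().astype(float)
    shifted_sleep, valid = _shift_from_reference(sleep_truth, lags)
    sleep_dev = np.nan_to_num(shifted_sleep, nan=0.0) > 0.5
    p_state = np.where(sleep_dev, config.score_sleep_p, config.score_wake_p)
    # AR(1) logit noise with the configured marginal SD, so predictions
    # form runs instead of flickering epoch to epoch
    phi = config.score_noise_ar
    innov = rng.normal(0.0, config.score_noise_sd * np.sqrt(1.0 - phi**2), n)
    noise = lfilter([1.0], [1.0, -phi], innov)
    score = expit(logit(p_state) + noise)
    pred_sleep = score >= config.score_threshold

    # movement bursts at wake-bout onsets (epoch 0 counts as one)
    wake = ~hyp.is_sleep()
    onsets = np.flatnonzero(wake & ~np.r_[False, wake[:-1]])
    base = np.abs(rng.normal(0.0, config.move_noise_sd, n))
    burst = np.zeros(n)
    for o in onsets:
        burst[o : o + 2] += config.move_burst_amp
    ref_move = EpochSeries(base + burst)
    shifted_move, valid_m = _shift_from_reference(ref_move.values, lags)
    dev_move_vals = np.nan_to_num(shifted_move) + np.abs(
        rng.normal(0.0, config.move_noise_sd, n)
    )
    dev_move = EpochSeries(dev_move_vals, covered=valid_m)

    lag0 = int(np.round(np.mean(lags)))
    return DeviceObservation(
        dev_hr=dev_hr, dev_br=dev_br, score=score, pred_sleep=pred_sleep,
        ref_move=ref_move, dev_move=dev_move, lag_epochs=lag0,
    )


def gen_cohort(
    config: CohortConfig | None = None,
    hyp_config: HypnogramConfig | None = None,
    vitals_config: VitalsConfig | None = None,
    device_config: DeviceConfig | None = None,
) -> list[SubjectRecord]:
    """Generate a reproducible cohort of subject-nights.

    Subject ``i`` uses ``default_rng(config.seed + i)``, so any subject
    can be regenerated in isolation.  Covariates feed the device model:
    the HR noise intercept gains ``bmi_noise_coef·(BMI − bmi_mean)``
    plus ``sex_noise_coef`` for women, floored at zero.
    """
    config = config or CohortConfig()
    config.validate()
    hyp_config = hyp_config or HypnogramConfig()
    vitals_config = vitals_config or VitalsConfig()
    device_config = device_config or DeviceConfig()
    device_config.validate()
    vitals_config.validate()

    records = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(config.seed + i)
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                            config.age_min, config.age_max))
        female = int(rng.random() < config.female_prop)
        bmi = float(np.clip(rng.normal(config.bmi_mean, config.bmi_sd), 16.0, 50.0))
        ahi = float(rng.lognormal(config.ahi_log_mean, config.ahi_log_sd))

        tib = int(np.clip(round(rng.normal(config.tib_mean_epochs,
                                           config.tib_sd_epochs)),
                          config.tib_min_epochs, config.tib_max_epochs))
        hcfg = replace(hyp_config, time_in_bed=tib)
        hyp = gen_hypnogram(hcfg, rng)
        scorers, expert = gen_scorer_panel(hyp, config.scorer_error_rate, rng)

        hr_offset = float(rng.normal(0.0, config.hr_between_sd))
        br_offset = float(rng.normal(0.0, config.br_between_sd))
        vcfg = replace(
            vitals_config,
            hr_baseline=np.asarray(vitals_config.hr_baseline, dtype=float)
            + hr_offset,
            br_baseline=np.asarray(vitals_config.br_baseline, dtype=float)
            + br_offset,
        )
        _, _, ref_hr, ref_br = gen_reference_vitals(hyp, vcfg, rng)

        artifact = rng.random(tib) < config.psg_artifact_prob
        ref_hr.artifact = artifact.copy()
        ref_br.artifact = artifact.copy()

        hr_noise_c0 = max(
            0.0,
            device_config.hr_noise_c0
            + config.bmi_noise_coef * (bmi - config.bmi_mean)
            + config.sex_noise_coef * female,
        )
        dcfg = replace(device_config, hr_noise_c0=hr_noise_c0)
        obs = gen_device_observation(ref_hr, ref_br, hyp, dcfg, rng)

        records.append(SubjectRecord(
            subject_id=f"s{i + 1:02d}",
            age=age, sex_female=female, bmi=bmi, ahi=ahi,
            hyp_truth=hyp, scorers=scorers, expert=expert,
            ref_hr=ref_hr, dev_hr=obs.dev_hr,
            ref_br=ref_br, dev_br=obs.dev_br,
            score=obs.score, pred_sleep=obs.pred_sleep,
            ref_move=obs.ref_move, dev_move=obs.dev_move,
            lights_off=hyp.lights_off, lights_on=hyp.lights_on,
            truth={
                "seed": config.seed + i,
                "time_in_bed": tib,
                "hr_bias": dcfg.hr_bias,
                "br_bias": dcfg.br_bias,
                "hr_prop_bias": dcfg.hr_prop_bias,
                "br_prop_bias": dcfg.br_prop_bias,
                "hr_noise_c0": dcfg.hr_noise_c0,
                "hr_noise_c1": dcfg.hr_noise_c1,
                "br_noise_c0": dcfg.br_noise_c0,
                "br_noise_c1": dcfg.br_noise_c1,
                "hr_coverage": dcfg.hr_coverage,
                "br_coverage": dcfg.br_coverage,
                "lag_epochs": obs.lag_epochs,
                "hr_offset": hr_offset,
                "br_offset": br_offset,
            },
        ))
    return records
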