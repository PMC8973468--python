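"""Synthetic digit-span pupillometry datasets.

Emulates the experimental structure the analysis assumes: each trial has a
2 s prestimulus fixation followed by a stimulus phase in which one digit is
shown per second — 3, 5 or 8 digits for low/medium/high difficulty — plus a
retention tail. The mean pupil trajectory sits at the subject's baseline
during fixation, ramps linearly while digits are encoded, peaks at the end
of digit presentation, and decays exponentially during retention. Dilation
amplitude grows with difficulty and is scaled by a subject-specific
sensitivity; baselines vary between subjects but are identical across
difficulty levels by construction (so baseline features carry no difficulty
signal). Measurement noise, small independent per-eye jitter, occasional
single-eye dropout, and blink runs (consecutive invalid samples) complete
the emulation.

What this generator does *not* emulate: luminance reflexes, gaze-dependent
foreshortening, fatigue or habituation across trials, and serial
correlation of the measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trace_io import Dataset, TrialRecord

DEFAULT_DIGITS_PER_LEVEL = {"low": 3, "medium": 5, "high": 8}
# peak dilation amplitudes per difficulty, mm above baseline
DEFAULT_AMPLITUDES = {"low": 0.12, "medium": 0.24, "high": 0.44}


@dataclass
class GeneratorConfig:
    """Study-design and physiology parameters of the generator.

    Defaults mirror the emulated study: 24 subjects, 12 trials per
    difficulty level, a 50 Hz tracker, a 2 s prestimulus fixation, one
    digit per second, and a 4 s retention tail after the last digit.
    """

    n_subjects: int = 24
    trials_per_level: int = 12
    sampling_rate: float = 50.0  # Hz
    prestimulus_s: float = 2.0
    digits_per_level: dict = field(default_factory=lambda: dict(DEFAULT_DIGITS_PER_LEVEL))
    post_digit_s: float = 4.0  # retention tail after the last digit
    baseline_mean: float = 4.0  # mm
    baseline_sd_between_subjects: float = 0.5  # mm
    amplitude_by_level: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    amplitude_subject_sd: float = 0.3  # sd of log-sensitivity (unit-median lognormal)
    decay_tau_s: float = 2.0  # post-peak exponential decay time constant
    noise_sd: float = 0.1  # mm, per-sample measurement noise on the common trajectory
    eye_jitter_sd: float = 0.02  # mm, independent per-eye jitter
    one_eye_missing_prob: float = 0.02  # per-sample chance one eye is untracked
    blink_prob: float = 0.002  # per-sample chance a blink run starts
    blink_run_samples: tuple = (2, 10)  # inclusive range of run lengths
    seed: int = 0

    def validate(self) -> None:
        levels = ("low", "medium", "high")
        if tuple(self.digits_per_level) != levels or tuple(self.amplitude_by_level) != levels:
            raise ValueError("digits_per_level and amplitude_by_level must map low/medium/high")
        if self.n_subjects < 1 or self.trials_per_level < 1:
            raise ValueError("need at least one subject and one trial per level")
        if self.sampling_rate <= 0 or self.prestimulus_s <= 0:
            raise ValueError("sampling_rate and prestimulus_s must be positive")


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject physiology: resting diameter and dilation sensitivity."""

    subject_id: str
    baseline: float  # mm, > 0
    sensitivity: float  # multiplicative dilation factor, > 0


def sample_subject(subject_id: str, config: GeneratorConfig, rng: np.random.Generator) -> SubjectProfile:
    """Draw a subject: truncated-normal baseline, unit-median lognormal sensitivity."""
    baseline = rng.normal(config.baseline_mean, config.baseline_sd_between_subjects)
    while baseline <= 0:
        baseline = rng.normal(config.baseline_mean, config.baseline_sd_between_subjects)
    if config.amplitude_subject_sd > 0:
        sensitivity = float(np.exp(rng.normal(0.0, config.amplitude_subject_sd)))
    else:
        sensitivity = 1.0
    return SubjectProfile(subject_id=subject_id, baseline=float(baseline), sensitivity=sensitivity)


def _mean_trajectory(t: np.ndarray, baseline: float, amplitude: float, peak_t: float, tau: float) -> np.ndarray:
    """Linear encoding ramp to a peak at ``peak_t``, then exponential decay."""
    shape = np.where(t <= peak_t, t / peak_t, np.exp(-(t - peak_t) / tau))
    return baseline + amplitude * shape


def _insert_blinks(n: int, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of samples lost to blink runs."""
    invalid = np.zeros(n, dtype=bool)
    if config.blink_prob <= 0:
        return invalid
    starts = np.flatnonzero(rng.random(n) < config.blink_prob)
    lo, hi = config.blink_run_samples
    for s in starts:
        run = int(rng.integers(lo, hi + 1))
        invalid[s : s + run] = True
    return invalid


def simulate_trial(
    subject: SubjectProfile,
    difficulty: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    trial_id: str = "t000",
) -> TrialRecord:
    """One trial of one subject at one difficulty level."""
    if difficulty not in config.digits_per_level:
        raise ValueError(f"unknown difficulty {difficulty!r}")
    fs = config.sampling_rate
    digits = config.digits_per_level[difficulty]
    n_pre = int(round(config.prestimulus_s * fs))
    n_stim = int(round((digits + config.post_digit_s) * fs))
    pre_t = -config.prestimulus_s + np.arange(n_pre) / fs
    stim_t = np.arange(n_stim) / fs
    t = np.concatenate([pre_t, stim_t])

    amplitude = subject.sensitivity * config.amplitude_by_level[difficulty]
    mean = np.concatenate(
        [
            np.full(n_pre, subject.baseline),
            _mean_trajectory(stim_t, subject.baseline, amplitude, float(digits), config.decay_tau_s),
        ]
    )
    common = mean + rng.normal(0.0, config.noise_sd, size=t.size) if config.noise_sd > 0 else mean
    if config.eye_jitter_sd > 0:
        left = common + rng.normal(0.0, config.eye_jitter_sd, size=t.size)
        right = common + rng.normal(0.0, config.eye_jitter_sd, size=t.size)
    else:
        left, right = common.copy(), common.copy()
    left = np.maximum(left, 0.1)  # diameters stay physical even at extreme noise draws
    right = np.maximum(right, 0.1)

    if config.one_eye_missing_prob > 0:
        drop = rng.random(t.size) < config.one_eye_missing_prob
        which_left = rng.random(t.size) < 0.5
        left[drop & which_left] = np.nan
        right[drop & ~which_left] = np.nan

    blink = _insert_blinks(t.size, config, rng)
    left[blink] = np.nan
    right[blink] = np.nan
    valid = ~blink

    return TrialRecord(
        subject_id=subject.subject_id,
        trial_id=trial_id,
        difficulty=difficulty,
        times=t,
        left=left,
        right=right,
        valid=valid,
    )


def simulate_dataset(config: GeneratorConfig | None = None, seed: int | None = None) -> Dataset:
    """A full dataset: every subject runs ``trials_per_level`` trials at each
    of the three difficulty levels, in randomised order within subject.

    Fully reproducible from ``config.seed`` (or the ``seed`` override).
    """
    config = config or GeneratorConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    trials: list[TrialRecord] = []
    width = max(2, len(str(config.n_subjects)))
    for i in range(config.n_subjects):
        subject = sample_subject(f"s{i:0{width}d}", config, rng)
        schedule = [
            level for level in ("low", "medium", "high") for _ in range(config.trials_per_level)
        ]
        order = rng.permutation(len(schedule))
        for k, j in enumerate(order):
            trials.append(
                simulate_trial(subject, schedule[j], config, rng, trial_id=f"t{k:03d}")
            )
    return Dataset(trials=trials)
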