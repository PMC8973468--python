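"""Trial cleaning: blink removal, binocular merging, validity gating, smoothing.

The cleaning pipeline, applied per trial:

1. drop samples flagged invalid by the tracker or carrying no diameter in
   either eye (blinks and tracking loss);
2. merge the two eyes — average when both are measured, pass the single
   measured eye through unchanged;
3. reject the trial if more than ``max_invalid_fraction`` (default 20%) of
   its samples were dropped;
4. smooth the stimulus-phase series with a Savitzky–Golay filter. The
   baseline is computed from the raw (cleaned, unsmoothed) prestimulus
   samples, so smoothing is applied to the stimulus phase only.

Rejection is reported as a value (:class:`Rejection`), not an exception,
so that a batch run can account for every input trial.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .trace_io import Dataset, PupilSample, TrialRecord

logger = logging.getLogger(__name__)

DEFAULT_MAX_INVALID_FRACTION = 0.20
DEFAULT_SMOOTHING_WINDOW = 7
DEFAULT_SMOOTHING_POLYORDER = 2


class EmptyTrialError(ValueError):
    """Every sample of a trial was invalid."""


class BaselineUndefinedError(ValueError):
    """No prestimulus samples survive cleaning; BLPS cannot be computed."""


@dataclass
class CleanTrial:
    """A trial that passed cleaning: gap-free per-phase diameter series."""

    subject_id: str
    trial_id: str
    difficulty: str
    pre_times: np.ndarray
    pre_diam: np.ndarray
    stim_times: np.ndarray
    stim_diam: np.ndarray
    n_dropped: int
    invalid_fraction: float


@dataclass(frozen=True)
class Rejection:
    """Why a trial was excluded from analysis."""

    subject_id: str
    trial_id: str
    reason: str


def merge_eyes(sample):
    """Merge one binocular sample into a single diameter in mm.

    Mean of the two eyes when both are present, the measured eye when only
    one is, NaN when neither is. Accepts a :class:`PupilSample` or a pair
    of array-likes ``(left, right)``.
    """
    if isinstance(sample, PupilSample):
        return _merge_arrays(np.asarray(sample.left), np.asarray(sample.right)).item()
    left, right = sample
    return _merge_arrays(np.asarray(left, dtype=float), np.asarray(right, dtype=float))


def _merge_arrays(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    both = ~np.isnan(left) & ~np.isnan(right)
    out = np.where(np.isnan(left), right, left)
    out = np.where(both, 0.5 * (left + right), out)
    return out


def drop_invalid(trial: TrialRecord) -> tuple[TrialRecord, float]:
    """Remove invalid or diameter-less samples; return the invalid fraction.

    A sample is invalid iff its validity flag is false or both eyes are
    missing. Raises :class:`EmptyTrialError` when nothing survives.
    """
    n = len(trial)
    if n == 0:
        raise EmptyTrialError(f"trial {trial.trial_id} has no samples")
    keep = trial.valid & ~(np.isnan(trial.left) & np.isnan(trial.right))
    frac = 1.0 - keep.sum() / n
    if not keep.any():
        raise EmptyTrialError(f"trial {trial.trial_id}: all {n} samples invalid")
    retained = TrialRecord.__new__(TrialRecord)
    # bypass __post_init__: the retained subset may momentarily violate the
    # >=3-stimulus-samples invariant, which preprocess_trial handles itself
    retained.subject_id = trial.subject_id
    retained.trial_id = trial.trial_id
    retained.difficulty = trial.difficulty
    retained.times = trial.times[keep]
    retained.left = trial.left[keep]
    retained.right = trial.right[keep]
    retained.valid = trial.valid[keep]
    return retained, float(frac)


def trial_is_valid(invalid_fraction: float, threshold: float = DEFAULT_MAX_INVALID_FRACTION) -> bool:
    """A trial is valid iff its invalid fraction does not exceed the threshold.

    The bound is inclusive: exactly 20% invalid records is still valid.
    """
    if not 0.0 <= invalid_fraction <= 1.0:
        raise ValueError(f"invalid_fraction must lie in [0, 1], got {invalid_fraction}")
    return invalid_fraction <= threshold


def smooth_trace(
    diam: np.ndarray,
    window: int = DEFAULT_SMOOTHING_WINDOW,
    polyorder: int = DEFAULT_SMOOTHING_POLYORDER,
) -> np.ndarray:
    """Savitzky–Golay smoothing of a diameter series.

    Local least-squares polynomial fitting of the given order over a
    sliding window; reproduces exactly any input that is a polynomial of
    degree <= ``polyorder``. Raises ``ValueError`` when the series is
    shorter than the window (the caller may then skip smoothing).
    """
    diam = np.asarray(diam, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError(f"window must be odd and exceed polyorder; got {window}, {polyorder}")
    if len(diam) < window:
        raise ValueError(f"series of length {len(diam)} is shorter than window {window}")
    return savgol_filter(diam, window_length=window, polyorder=polyorder)


@dataclass
class PreprocessConfig:
    max_invalid_fraction: float = DEFAULT_MAX_INVALID_FRACTION
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW
    smoothing_polyorder: int = DEFAULT_SMOOTHING_POLYORDER
    smooth: bool = True


def preprocess_trial(trial: TrialRecord, config: PreprocessConfig | None = None):
    """Clean one trial; return a :class:`CleanTrial` or a :class:`Rejection`.

    Raises :class:`BaselineUndefinedError` when cleaning leaves no
    prestimulus samples (batch callers convert this into a rejection).
    """
    config = config or PreprocessConfig()
    retained, frac = drop_invalid(trial)
    n_dropped = len(trial) - len(retained)
    if not trial_is_valid(frac, config.max_invalid_fraction):
        return Rejection(
            trial.subject_id,
            trial.trial_id,
            f"invalid_fraction {frac:.3f} > {config.max_invalid_fraction}",
        )
    diam = _merge_arrays(retained.left, retained.right)
    pre = retained.times < 0
    pre_times, pre_diam = retained.times[pre], diam[pre]
    stim_times, stim_diam = retained.times[~pre], diam[~pre]
    if pre_times.size == 0:
        raise BaselineUndefinedError(
            f"trial {trial.trial_id}: no prestimulus samples survive cleaning"
        )
    if stim_times.size < 3:
        return Rejection(
            trial.subject_id, trial.trial_id, f"only {stim_times.size} stimulus samples remain"
        )
    if config.smooth:
        if stim_diam.size >= config.smoothing_window:
            stim_diam = smooth_trace(
                stim_diam, config.smoothing_window, config.smoothing_polyorder
            )
        else:
            logger.warning(
                "trial %s: stimulus series (%d) shorter than smoothing window (%d); "
                "passed through unsmoothed",
                trial.trial_id,
                stim_diam.size,
                config.smoothing_window,
            )
    return CleanTrial(
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        difficulty=trial.difficulty,
        pre_times=pre_times,
        pre_diam=pre_diam,
        stim_times=stim_times,
        stim_diam=stim_diam,
        n_dropped=n_dropped,
        invalid_fraction=frac,
    )


def preprocess_dataset(
    dataset: Dataset, config: PreprocessConfig | None = None
) -> tuple[list[CleanTrial], list[Rejection]]:
    """Clean every trial; accepted and rejected trials partition the input."""
    clean: list[CleanTrial] = []
    rejected: list[Rejection] = []
    for trial in dataset.trials:
        try:
            result = preprocess_trial(trial, config)
        except (EmptyTrialError, BaselineUndefinedError) as exc:
            result = Rejection(trial.subject_id, trial.trial_id, str(exc))
            logger.warning("trial %s rejected: %s", trial.trial_id, exc)
        if isinstance(result, Rejection):
            rejected.append(result)
        else:
            clean.append(result)
    return clean, rejected
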