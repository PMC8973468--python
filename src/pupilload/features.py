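"""The seven per-trial pupillometric features.

All features are computed from a cleaned trial: a baseline (prestimulus)
diameter series and a stimulus-phase diameter series, both in mm, with
stimulus times in seconds from stimulus onset.

- BLPS    baseline pupil size: mean prestimulus diameter (mm)
- MPDC    mean pupil diameter change: mean stimulus diameter minus BLPS (mm)
- APCPS   average percentage change in pupil size: mean of the per-sample
          relative changes (PS_i - BLPS)/BLPS (dimensionless)
- PD      peak dilation: max stimulus diameter (PPD) minus BLPS (mm)
- E_pupil pupil entropy: Shannon entropy (bits) of the relative-frequency
          distribution of the discretised stimulus diameters
- TTP     time to peak: stimulus-onset-relative time of the (first) peak (s)
- PDS     peak dilation speed: arctangent of the least-squares slope of
          diameter vs. time over the segment from onset through the peak
          (radians; time axis in seconds, diameter in mm)

By construction APCPS * BLPS == MPDC (an exact algebraic identity) and
PD >= MPDC (a maximum dominates a mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CleanTrial

FEATURE_NAMES = ["BLPS", "MPDC", "APCPS", "PD", "E_pupil", "TTP", "PDS"]

DEFAULT_ENTROPY_BIN_WIDTH = 0.01  # mm; matches typical device quantisation


@dataclass(frozen=True)
class FeatureVector:
    subject_id: str
    trial_id: str
    difficulty: str
    BLPS: float
    MPDC: float
    APCPS: float
    PD: float
    E_pupil: float
    TTP: float
    PDS: float


def compute_blps(pre_diam: np.ndarray) -> float:
    """Mean prestimulus diameter (mm). Errors on an empty series."""
    pre_diam = np.asarray(pre_diam, dtype=float)
    if pre_diam.size == 0:
        raise ValueError("baseline undefined: empty prestimulus series")
    return float(np.mean(pre_diam))


def compute_mpdc(stim_diam: np.ndarray, blps: float) -> float:
    """Mean stimulus diameter minus baseline (mm); negative = constriction."""
    stim_diam = np.asarray(stim_diam, dtype=float)
    if stim_diam.size == 0:
        raise ValueError("empty stimulus series")
    return float(np.mean(stim_diam) - blps)


def compute_pcps(stim_diam: np.ndarray, blps: float) -> np.ndarray:
    """Per-sample relative change (PS_i - BLPS)/BLPS."""
    if blps <= 0:
        raise ValueError(f"baseline must be positive, got {blps}")
    return (np.asarray(stim_diam, dtype=float) - blps) / blps


def compute_apcps(pcps: np.ndarray) -> float:
    """Mean of the per-sample relative changes."""
    pcps = np.asarray(pcps, dtype=float)
    if pcps.size == 0:
        raise ValueError("empty PCPS series")
    return float(np.mean(pcps))


def compute_pd(stim_diam: np.ndarray, blps: float) -> tuple[float, float, int]:
    """Peak dilation: (PD, PPD, peak_index), ties broken by first occurrence."""
    stim_diam = np.asarray(stim_diam, dtype=float)
    if stim_diam.size == 0:
        raise ValueError("empty stimulus series")
    peak_index = int(np.argmax(stim_diam))  # argmax returns the first maximum
    ppd = float(stim_diam[peak_index])
    return ppd - blps, ppd, peak_index


def compute_entropy(stim_diam: np.ndarray, bin_width: float = DEFAULT_ENTROPY_BIN_WIDTH) -> float:
    """Shannon entropy (bits) of the discretised stimulus diameters.

    Diameters are binned at width ``bin_width`` anchored at the series
    minimum; the entropy is taken over the bins' relative frequencies.
    """
    stim_diam = np.asarray(stim_diam, dtype=float)
    if stim_diam.size == 0:
        raise ValueError("empty stimulus series")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    idx = np.floor((stim_diam - stim_diam.min()) / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    p = counts[counts > 0] / stim_diam.size
    return float(-(p * np.log2(p)).sum())


def compute_ttp(stim_times: np.ndarray, peak_index: int) -> float:
    """Stimulus-onset-relative time (s) of the peak sample."""
    stim_times = np.asarray(stim_times, dtype=float)
    if not 0 <= peak_index < stim_times.size:
        raise ValueError(f"peak_index {peak_index} out of range for {stim_times.size} samples")
    return float(stim_times[peak_index])


def compute_pds(stim_times: np.ndarray, stim_diam: np.ndarray, peak_index: int) -> float:
    """Arctangent (radians) of the OLS slope from stimulus onset to the peak.

    The regression runs over samples [0 .. peak_index] inclusive, with
    time in seconds and diameter in mm.
    """
    t = np.asarray(stim_times, dtype=float)[: peak_index + 1]
    d = np.asarray(stim_diam, dtype=float)[: peak_index + 1]
    if t.size < 2:
        raise ValueError("slope undefined: fewer than 2 samples up to the peak")
    n = t.size
    denom = np.sum(t * t) - np.sum(t) ** 2 / n
    if denom == 0:
        raise ValueError("slope undefined: zero time variance up to the peak")
    m = (np.sum(t * d) - np.sum(t) * np.sum(d) / n) / denom
    return float(np.arctan(m))


@dataclass
class FeatureConfig:
    entropy_bin_width: float = DEFAULT_ENTROPY_BIN_WIDTH


def extract_features(trial: CleanTrial, config: FeatureConfig | None = None) -> FeatureVector:
    """All seven features of one cleaned trial."""
    config = config or FeatureConfig()
    try:
        blps = compute_blps(trial.pre_diam)
        mpdc = compute_mpdc(trial.stim_diam, blps)
        apcps = compute_apcps(compute_pcps(trial.stim_diam, blps))
        pd_, _ppd, peak_index = compute_pd(trial.stim_diam, blps)
        e_pupil = compute_entropy(trial.stim_diam, config.entropy_bin_width)
        ttp = compute_ttp(trial.stim_times, peak_index)
        if peak_index == 0:
            # the peak sits at onset: no rise segment, the dilation speed is flat
            pds = 0.0
        else:
            pds = compute_pds(trial.stim_times, trial.stim_diam, peak_index)
    except ValueError as exc:
        raise ValueError(f"trial {trial.trial_id} ({trial.subject_id}): {exc}") from exc
    return FeatureVector(
        subject_id=trial.subject_id,
        trial_id=trial.trial_id,
        difficulty=trial.difficulty,
        BLPS=blps,
        MPDC=mpdc,
        APCPS=apcps,
        PD=pd_,
        E_pupil=e_pupil,
        TTP=ttp,
        PDS=pds,
    )


def feature_table(trials: list[CleanTrial], config: FeatureConfig | None = None) -> pd.DataFrame:
    """Per-trial feature matrix: one row per trial, one column per feature."""
    rows = [extract_features(t, config) for t in trials]
    df = pd.DataFrame([vars(r) for r in rows])
    if df.empty:
        df = pd.DataFrame(columns=["subject_id", "trial_id", "difficulty", *FEATURE_NAMES])
    return df
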