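"""Shared fixtures: synthetic study datasets at the sizes the analyses use.

Session scope keeps the expensive default-study simulation and feature
extraction to a single run shared across test modules.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("repro")

from pupilload import GeneratorConfig, feature_table, preprocess_dataset, simulate_dataset
from pupilload.trace_io import Dataset, TrialRecord


@pytest.fixture(scope="session")
def default_dataset():
    """The default study: 24 subjects x 12 trials/level at 50 Hz."""
    return simulate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_features(default_dataset):
    clean, _ = preprocess_dataset(default_dataset)
    return feature_table(clean)


@pytest.fixture(scope="session")
def small_features():
    """A small study (8 subjects x 6 trials/level, 25 Hz) for fast CV tests."""
    cfg = GeneratorConfig(n_subjects=8, trials_per_level=6, sampling_rate=25.0, seed=11)
    clean, _ = preprocess_dataset(simulate_dataset(cfg))
    return feature_table(clean)


def make_trial(
    times,
    diam=None,
    left=None,
    right=None,
    valid=None,
    subject_id="s00",
    trial_id="t000",
    difficulty="low",
):
    """Hand-built trial; pass ``diam`` to put the same series in both eyes."""
    times = np.asarray(times, dtype=float)
    if diam is not None:
        left = right = np.asarray(diam, dtype=float)
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if valid is None:
        valid = ~(np.isnan(left) & np.isnan(right))
    return TrialRecord(
        subject_id=subject_id,
        trial_id=trial_id,
        difficulty=difficulty,
        times=times,
        left=left.copy(),
        right=right.copy(),
        valid=np.asarray(valid, dtype=bool),
    )


@pytest.fixture
def tiny_dataset():
    """Two subjects, one clean hand-sized trial each."""
    t = np.array([-1.0, -0.5, 0.0, 0.5, 1.0, 1.5])
    d1 = np.array([4.0, 4.0, 4.1, 4.3, 4.2, 4.1])
    d2 = np.array([3.8, 3.9, 4.0, 4.4, 4.5, 4.2])
    return Dataset(
        trials=[
            make_trial(t, diam=d1, subject_id="sA", trial_id="t0", difficulty="low"),
            make_trial(t, diam=d2, subject_id="sB", trial_id="t0", difficulty="high"),
        ]
    )


def lmm_table(
    offsets=(0.0, 0.1, 0.3),
    n_subjects=24,
    trials_per_level=12,
    subject_sd=0.3,
    noise_sd=0.1,
    seed=0,
    response="MPDC",
):
    """Feature-level simulation straight from the mixed-model data process:
    y = subject intercept + level offset + noise. The independent route for
    parameter-recovery tests (no traces involved)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        b = rng.normal(0.0, subject_sd)
        for lev, off in zip(("low", "medium", "high"), offsets):
            for _ in range(trials_per_level):
                rows.append((f"s{s:02d}", lev, b + off + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows, columns=["subject_id", "difficulty", response])
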