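"""Data model and delimited-text I/O for pupil-diameter recordings.

A recording is a long-format table with one row per eye-tracker sample:

    subject_id,trial_id,difficulty,time_s,left_mm,right_mm,valid

Times are seconds relative to stimulus onset, so the 2 s prestimulus
fixation carries negative times. Diameters are millimetres; an empty cell
means the eye was not measured at that sample. ``valid`` is the device
validity flag (false during blinks or tracking loss).

Internally a :class:`TrialRecord` stores its samples as parallel numpy
arrays (missing diameters are NaN) so that preprocessing and feature
extraction stay vectorised; :class:`PupilSample` is the scalar view used
at API boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DIFFICULTY_LEVELS = ("low", "medium", "high")

COLUMNS = ["subject_id", "trial_id", "difficulty", "time_s", "left_mm", "right_mm", "valid"]


class ParseError(ValueError):
    """A row of the interchange file could not be parsed."""


class ValidationError(ValueError):
    """A record violates a data-model invariant."""


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class PupilSample:
    """One timestamped binocular diameter measurement.

    ``left``/``right`` are NaN when that eye was not measured. A sample
    flagged valid must carry at least one diameter, and diameters must be
    strictly positive.
    """

    time: float
    left: float = math.nan
    right: float = math.nan
    valid: bool = True

    def __post_init__(self) -> None:
        for name, v in (("left", self.left), ("right", self.right)):
            if not _is_missing(v) and v <= 0:
                raise ValidationError(f"{name} diameter must be positive, got {v}")
        if self.valid and _is_missing(self.left) and _is_missing(self.right):
            raise ValidationError("a valid sample needs at least one eye measured")


@dataclass
class TrialRecord:
    """One digit-span trial: prestimulus and stimulus samples of one subject.

    ``times`` must be strictly increasing, with at least one prestimulus
    sample (t < 0) and at least three stimulus samples (t >= 0).
    """

    subject_id: str
    trial_id: str
    difficulty: str
    times: np.ndarray
    left: np.ndarray
    right: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.times)
        if not (len(self.left) == len(self.right) == len(self.valid) == n):
            raise ValidationError("sample arrays must have equal length")
        if self.difficulty not in DIFFICULTY_LEVELS:
            raise ValidationError(
                f"unknown difficulty {self.difficulty!r}; expected one of {DIFFICULTY_LEVELS}"
            )
        if n and np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"trial {self.trial_id}: sample times must strictly increase")
        if np.count_nonzero(self.times < 0) < 1:
            raise ValidationError(f"trial {self.trial_id}: no prestimulus samples (t < 0)")
        if np.count_nonzero(self.times >= 0) < 3:
            raise ValidationError(f"trial {self.trial_id}: fewer than 3 stimulus samples")
        with np.errstate(invalid="ignore"):
            if np.any(self.left <= 0) or np.any(self.right <= 0):
                raise ValidationError(f"trial {self.trial_id}: non-positive diameter")
        both_missing = np.isnan(self.left) & np.isnan(self.right)
        if np.any(self.valid & both_missing):
            raise ValidationError(f"trial {self.trial_id}: valid sample with no diameters")

    @property
    def samples(self) -> list[PupilSample]:
        """Scalar per-sample view (constructed on demand)."""
        return [
            PupilSample(time=t, left=l, right=r, valid=bool(v))
            for t, l, r, v in zip(self.times, self.left, self.right, self.valid)
        ]

    @classmethod
    def from_samples(cls, subject_id, trial_id, difficulty, samples) -> "TrialRecord":
        samples = list(samples)
        return cls(
            subject_id=subject_id,
            trial_id=trial_id,
            difficulty=difficulty,
            times=np.array([s.time for s in samples], dtype=float),
            left=np.array([s.left for s in samples], dtype=float),
            right=np.array([s.right for s in samples], dtype=float),
            valid=np.array([s.valid for s in samples], dtype=bool),
        )

    def __len__(self) -> int:
        return len(self.times)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialRecord):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.trial_id == other.trial_id
            and self.difficulty == other.difficulty
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.left, other.left, equal_nan=True)
            and np.array_equal(self.right, other.right, equal_nan=True)
            and np.array_equal(self.valid, other.valid)
        )


@dataclass
class Dataset:
    """A collection of trials plus the roster of subjects they belong to."""

    trials: list[TrialRecord] = field(default_factory=list)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.subject_id, None)
        return list(seen)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_samples(self) -> int:
        return sum(len(t) for t in self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per sample."""
        if not self.trials:
            return pd.DataFrame(columns=COLUMNS)
        parts = [
            pd.DataFrame(
                {
                    "subject_id": t.subject_id,
                    "trial_id": t.trial_id,
                    "difficulty": t.difficulty,
                    "time_s": t.times,
                    "left_mm": t.left,
                    "right_mm": t.right,
                    "valid": t.valid,
                }
            )
            for t in self.trials
        ]
        return pd.concat(parts, ignore_index=True)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.trials == other.trials


_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


def _parse_bool(raw: str, line_no: int) -> bool:
    s = raw.strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ParseError(f"line {line_no}: cannot parse valid flag {raw!r}")


def read_trials(path) -> Dataset:
    """Read a long-format trace CSV into a :class:`Dataset`.

    Rows are grouped into trials by (subject_id, trial_id) in order of first
    appearance. Empty diameter cells become NaN. Malformed numeric cells
    raise :class:`ParseError` naming the offending line; an unknown
    difficulty label raises :class:`ValidationError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing required columns: {missing}")

    def to_float(col: str, required: bool) -> np.ndarray:
        # python float() is correctly rounded, so written values round-trip
        # bit-exactly (pandas' fast parser can be off by one ulp)
        raw = df[col].str.strip()
        out = np.empty(len(raw), dtype=float)
        for i, s in enumerate(raw):
            if s == "":
                if required:
                    raise ParseError(f"line {i + 2}: missing required value in {col}")
                out[i] = np.nan
                continue
            try:
                out[i] = float(s)
            except ValueError:
                raise ParseError(f"line {i + 2}: cannot parse {col}={s!r}") from None
        return out

    time_s = to_float("time_s", required=True)
    left = to_float("left_mm", required=False)
    right = to_float("right_mm", required=False)
    valid = np.array(
        [_parse_bool(v, i + 2) for i, v in enumerate(df["valid"])], dtype=bool
    )

    bad_diff = ~df["difficulty"].isin(DIFFICULTY_LEVELS)
    if bad_diff.any():
        first = df["difficulty"][bad_diff].iloc[0]
        raise ValidationError(
            f"unknown difficulty label {first!r}; expected one of {DIFFICULTY_LEVELS}"
        )

    trials: list[TrialRecord] = []
    positions = pd.Series(np.arange(len(df)), index=df.index)
    grouped = positions.groupby([df["subject_id"], df["trial_id"]], sort=False)
    for (subj, trial), pos in grouped:
        loc = pos.to_numpy()
        trials.append(
            TrialRecord(
                subject_id=subj,
                trial_id=trial,
                difficulty=df["difficulty"].iloc[loc[0]],
                times=time_s[loc],
                left=left[loc],
                right=right[loc],
                valid=valid[loc],
            )
        )
    return Dataset(trials=trials)


def write_trials(dataset: Dataset, path) -> None:
    """Write a Dataset as the long-format trace CSV (lossless round-trip)."""
    df = dataset.to_frame()
    df["valid"] = df["valid"].map({True: "true", False: "false"})
    df.to_csv(path, index=False, float_format="%.17g")
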