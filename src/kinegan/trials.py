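"""Trial container, preprocessing and label arithmetic.

A preprocessed trial is a 300-sample, 9-channel matrix (5 s at 60 Hz) with
task / impairment-group metadata. Trials shorter than 300 samples are
extended by repeating the final value; longer trials are cropped to the
first 300 samples (movement onset is at trial start in the source
protocol). Task and impairment group combine into a composite class code in
[0, 30): ``code = task_index * 3 + group_index``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .channels import (
    GROUPS,
    N_CHANNELS,
    N_CLASSES,
    N_GROUPS,
    N_TASKS,
    SAMPLE_RATE_HZ,
    TASKS,
    TRIAL_LENGTH,
)

#: FMMA-UE threshold splitting stroke survivors into mild vs moderate+severe.
#: A score of exactly 42 falls in the moderate+severe group (mild requires
#: a score strictly above the threshold).
FMMA_GROUP_THRESHOLD = 42

FMMA_MAX = 66


class InvalidTrialError(ValueError):
    """Raised when a signal matrix or trial metadata violates the contract."""


@dataclass(frozen=True)
class ClassLabel:
    """Composite task-by-impairment label: ``code = task_index*3 + group_index``."""

    code: int

    def __post_init__(self) -> None:
        if not 0 <= self.code < N_CLASSES:
            raise InvalidTrialError(f"class code {self.code} out of range [0, {N_CLASSES})")

    @property
    def task_index(self) -> int:
        return self.code // N_GROUPS

    @property
    def group_index(self) -> int:
        return self.code % N_GROUPS

    @property
    def task(self) -> str:
        return TASKS[self.task_index]

    @property
    def group(self) -> str:
        return GROUPS[self.group_index]


def encode_class(task_index: int, group_index: int) -> ClassLabel:
    """Map a (task, group) pair to its composite class label.

    The encoding is a bijection between the 10x3 grid and [0, 30).
    """
    if not 0 <= task_index < N_TASKS:
        raise InvalidTrialError(f"task_index {task_index} out of range [0, {N_TASKS})")
    if not 0 <= group_index < N_GROUPS:
        raise InvalidTrialError(f"group_index {group_index} out of range [0, {N_GROUPS})")
    return ClassLabel(task_index * N_GROUPS + group_index)


def decode_class(code: int) -> tuple[int, int]:
    """Inverse of :func:`encode_class`: class code -> (task_index, group_index)."""
    label = ClassLabel(code)
    return label.task_index, label.group_index


def pad_or_crop(signal: np.ndarray, target_len: int = TRIAL_LENGTH) -> np.ndarray:
    """Force a (T, 9) signal to exactly ``target_len`` rows.

    Longer signals are cropped to their first ``target_len`` samples; shorter
    signals are extended by repeating the final row. Idempotent.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2 or signal.shape[1] != N_CHANNELS:
        raise InvalidTrialError(f"expected a (T, {N_CHANNELS}) matrix, got shape {signal.shape}")
    t = signal.shape[0]
    if t == 0:
        raise InvalidTrialError("empty signal")
    if t >= target_len:
        return signal[:target_len].copy()
    pad = np.repeat(signal[-1:], target_len - t, axis=0)
    return np.vstack([signal, pad])


_POSITION_TO_CM = {"m": 100.0, "mm": 0.1, "cm": 1.0}
_ANGLE_TO_RAD = {"deg": np.pi / 180.0, "rad": 1.0}


def normalize_units(
    raw_signal: np.ndarray, position_unit: str = "m", angle_unit: str = "deg"
) -> np.ndarray:
    """Scale a raw (T, 9) signal into canonical units: cm for the T8
    positions (channels 0-2), radians for all angles (channels 3-8).
    """
    if position_unit not in _POSITION_TO_CM:
        raise KeyError(f"unknown position unit {position_unit!r}; expected one of {sorted(_POSITION_TO_CM)}")
    if angle_unit not in _ANGLE_TO_RAD:
        raise KeyError(f"unknown angle unit {angle_unit!r}; expected one of {sorted(_ANGLE_TO_RAD)}")
    raw_signal = np.asarray(raw_signal, dtype=float)
    if raw_signal.ndim != 2 or raw_signal.shape[1] != N_CHANNELS:
        raise InvalidTrialError(f"expected a (T, {N_CHANNELS}) matrix, got shape {raw_signal.shape}")
    scale = np.ones(N_CHANNELS)
    scale[:3] = _POSITION_TO_CM[position_unit]
    scale[3:] = _ANGLE_TO_RAD[angle_unit]
    return raw_signal * scale


def assign_impairment_group(fm_score: int | None, is_control: bool) -> str:
    """Assign control / mild / modsev from the FMMA-UE score.

    Stroke survivors with a score strictly above 42 are "mild"; at or below
    42 they join the pooled moderate+severe ("modsev") group. Controls have
    no score.
    """
    if is_control:
        return "control"
    if fm_score is None:
        raise InvalidTrialError("stroke trial without an FMMA-UE score")
    if not 0 <= fm_score <= FMMA_MAX:
        raise InvalidTrialError(f"FMMA-UE score {fm_score} out of range [0, {FMMA_MAX}]")
    return "mild" if fm_score > FMMA_GROUP_THRESHOLD else "modsev"


def severity_band(fm_score: int) -> str:
    """Clinical severity band of an FMMA-UE score: severe (<25),
    moderate (25-53), mild (>53). Partitions [0, 66]."""
    if not 0 <= fm_score <= FMMA_MAX:
        raise InvalidTrialError(f"FMMA-UE score {fm_score} out of range [0, {FMMA_MAX}]")
    if fm_score < 25:
        return "severe"
    if fm_score <= 53:
        return "moderate"
    return "mild"


@dataclass(frozen=True)
class KinematicTrial:
    """One preprocessed trial: a 300x9 signal plus metadata.

    ``provenance`` distinguishes experimentally recorded trials ("real")
    from generator output ("synthetic"); the augmentation protocol relies on
    this tag to keep synthetic trials out of test folds.
    """

    signal: np.ndarray
    task: str
    group: str
    subject_id: str = ""
    provenance: str = "real"
    sample_rate: float = SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.shape != (TRIAL_LENGTH, N_CHANNELS):
            raise InvalidTrialError(
                f"signal must be ({TRIAL_LENGTH}, {N_CHANNELS}), got {sig.shape}"
            )
        if not np.all(np.isfinite(sig)):
            raise InvalidTrialError("signal contains non-finite values")
        if self.task not in TASKS:
            raise InvalidTrialError(f"unknown task {self.task!r}")
        if self.group not in GROUPS:
            raise InvalidTrialError(f"unknown group {self.group!r}")
        if self.provenance not in ("real", "synthetic"):
            raise InvalidTrialError(f"provenance must be 'real' or 'synthetic', got {self.provenance!r}")
        if self.sample_rate != SAMPLE_RATE_HZ:
            raise InvalidTrialError(f"sample rate fixed at {SAMPLE_RATE_HZ} Hz")
        object.__setattr__(self, "signal", sig)

    @property
    def label(self) -> ClassLabel:
        return encode_class(TASKS.index(self.task), GROUPS.index(self.group))


@dataclass
class Dataset:
    """Ordered collection of trials with matching class labels."""

    trials: list[KinematicTrial] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    def __getitem__(self, idx):
        if isinstance(idx, (int, np.integer)):
            return self.trials[idx]
        if isinstance(idx, slice):
            return Dataset(self.trials[idx])
        return Dataset([self.trials[i] for i in np.asarray(idx)])

    @property
    def labels(self) -> np.ndarray:
        """Class codes, shape (N,)."""
        return np.array([t.label.code for t in self.trials], dtype=int)

    @property
    def task_labels(self) -> np.ndarray:
        """Task indices in [0, 10), shape (N,)."""
        return np.array([TASKS.index(t.task) for t in self.trials], dtype=int)

    @property
    def group_labels(self) -> np.ndarray:
        return np.array([GROUPS.index(t.group) for t in self.trials], dtype=int)

    @property
    def provenance(self) -> np.ndarray:
        return np.array([t.provenance for t in self.trials])

    def signals(self) -> np.ndarray:
        """Stacked signals, shape (N, 300, 9)."""
        if not self.trials:
            return np.empty((0, TRIAL_LENGTH, N_CHANNELS))
        return np.stack([t.signal for t in self.trials])

    def class_counts(self) -> np.ndarray:
        """Per-class trial counts over the 30-code label space."""
        return np.bincount(self.labels, minlength=N_CLASSES)

    def subset(self, mask: np.ndarray) -> "Dataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return Dataset([self.trials[i] for i in idx])

    def extend(self, other: "Dataset") -> "Dataset":
        return Dataset(self.trials + other.trials)

    def with_provenance(self, provenance: str) -> "Dataset":
        return Dataset([replace(t, provenance=provenance) for t in self.trials])

    def to_npz(self, path) -> None:
        """Tensorized cache: signals + metadata in a single .npz file."""
        np.savez_compressed(
            path,
            signals=self.signals(),
            tasks=np.array([t.task for t in self.trials]),
            groups=np.array([t.group for t in self.trials]),
            subjects=np.array([t.subject_id for t in self.trials]),
            provenance=self.provenance,
        )

    @classmethod
    def from_npz(cls, path) -> "Dataset":
        with np.load(path, allow_pickle=False) as f:
            trials = [
                KinematicTrial(
                    signal=f["signals"][i],
                    task=str(f["tasks"][i]),
                    group=str(f["groups"][i]),
                    subject_id=str(f["subjects"][i]),
                    provenance=str(f["provenance"][i]),
                )
                for i in range(f["signals"].shape[0])
            ]
        return cls(trials)
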