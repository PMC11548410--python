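"""Reading and writing trial collections as plain CSV files.

The default dialect is one wide CSV per trial (header row naming the nine
channels, one row per 60 Hz sample) plus a sidecar ``metadata.csv`` with
columns ``file, subject_id, task, fmma_ue, is_control`` (an optional
``provenance`` column is honored). Source units default to meters /
degrees, the usual inertial motion-capture export convention, and are
converted to cm / radians on load; the dialect can declare other units.

Trials that fail validation (missing channel, non-finite cell, unknown task
ID, missing FMMA score on a stroke trial) are rejected individually with a
logged reason; valid trials still load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNEL_NAMES, TASKS
from .trials import (
    Dataset,
    InvalidTrialError,
    KinematicTrial,
    assign_impairment_group,
    normalize_units,
    pad_or_crop,
)

logger = logging.getLogger(__name__)

METADATA_FILE = "metadata.csv"


@dataclass(frozen=True)
class DialectConfig:
    """How trial CSVs on disk are laid out and in which units."""

    position_unit: str = "m"
    angle_unit: str = "deg"
    metadata_file: str = METADATA_FILE

    @classmethod
    def canonical(cls) -> "DialectConfig":
        """Dialect of files written by :func:`write_trials`: already cm/rad."""
        return cls(position_unit="cm", angle_unit="rad")


def write_trials(dataset: Dataset, path, dialect: DialectConfig | None = None) -> None:
    """Write a dataset in the per-trial wide-CSV dialect (canonical units)."""
    if dialect is None:
        dialect = DialectConfig.canonical()
    if dialect.position_unit != "cm" or dialect.angle_unit != "rad":
        raise ValueError("write_trials writes canonical units (cm / rad) only")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, trial in enumerate(dataset):
        fname = f"trial_{i:05d}.csv"
        # default float formatting is the shortest round-trip repr: values
        # stored at full precision reload bit-identically
        pd.DataFrame(trial.signal, columns=list(CHANNEL_NAMES)).to_csv(path / fname, index=False)
        rows.append(
            {
                "file": fname,
                "subject_id": trial.subject_id,
                "task": trial.task,
                "fmma_ue": "",
                "is_control": trial.group == "control",
                "group": trial.group,
                "provenance": trial.provenance,
            }
        )
    pd.DataFrame(rows).to_csv(path / dialect.metadata_file, index=False)


def _resolve_group(row: pd.Series) -> str:
    """Group from an explicit column if present, else from FMMA score."""
    group = row.get("group")
    if isinstance(group, str) and group:
        return group
    is_control = bool(row.get("is_control", False))
    fm = row.get("fmma_ue")
    fm_score = None
    if fm is not None and not (isinstance(fm, float) and np.isnan(fm)) and f"{fm}" != "":
        fm_score = int(float(fm))
    return assign_impairment_group(fm_score, is_control)


def load_trials(path, dialect: DialectConfig | None = None) -> Dataset:
    """Load a trial directory into a validated, preprocessed :class:`Dataset`.

    Applies unit normalization and pad/crop to 300 samples. Invalid trials
    are skipped with a warning naming the reason.
    """
    if dialect is None:
        dialect = DialectConfig()
    path = Path(path)
    meta_path = path / dialect.metadata_file
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata file not found: {meta_path}")
    meta = pd.read_csv(meta_path)
    trials: list[KinematicTrial] = []
    for _, row in meta.iterrows():
        fname = row["file"]
        try:
            frame = pd.read_csv(path / fname, float_precision="round_trip")
            missing = [c for c in CHANNEL_NAMES if c not in frame.columns]
            if missing:
                raise InvalidTrialError(f"missing channels {missing}")
            raw = frame[list(CHANNEL_NAMES)].to_numpy(dtype=float)
            if not np.all(np.isfinite(raw)):
                raise InvalidTrialError("non-finite value in signal")
            task = str(row["task"])
            if task not in TASKS:
                raise InvalidTrialError(f"unknown task ID {task!r}")
            signal = pad_or_crop(
                normalize_units(raw, dialect.position_unit, dialect.angle_unit)
            )
            trials.append(
                KinematicTrial(
                    signal=signal,
                    task=task,
                    group=_resolve_group(row),
                    subject_id=str(row.get("subject_id", "")),
                    provenance=str(row.get("provenance", "real")),
                )
            )
        except (InvalidTrialError, OSError, ValueError, KeyError) as exc:
            logger.warning("rejected trial %s: %s", fname, exc)
    return Dataset(trials)
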