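"""Parametric reach-and-return movement simulator.

Generates 5-s, 9-channel trials that emulate the structure of goal-directed
upper-limb reaching after stroke: a bell-shaped (minimum-jerk) excursion
away from and back to a resting posture, per-task amplitude patterns, and
impairment-dependent compensation — trunk (T8) displacement grows and arm
(shoulder/elbow) range of motion shrinks with impairment severity. The
simulator provides class-conditioned data with a known ground-truth
structure for testing every downstream stage without the source recordings;
it makes no claim of biomechanical validity and does not model joint limits
or the absolute amplitudes of any real dataset.

Additive noise is Gaussian white noise lowpass-filtered at 4 Hz, so raw
simulated trials deliberately carry some energy above 2 Hz: the spectral
loss and the 2 Hz post-filter then have something to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .channels import (
    ARM_CHANNELS,
    GROUPS,
    N_CHANNELS,
    N_GROUPS,
    N_TASKS,
    SAMPLE_RATE_HZ,
    TASKS,
    TRIAL_LENGTH,
    TRUNK_CHANNELS,
)
from .trials import Dataset, KinematicTrial, encode_class

# Peak excursions per task at control level, one row per task in TASKS
# order, columns in channel order (cm for T8x/y/z, rad for angles).
# The rows are deliberately distinct so tasks are separable in
# range-of-motion space.
DEFAULT_TEMPLATES = np.array(
    [
        # T8x   T8y   T8z  T8th  Sthx  Sthy  Sthz  Ethx  Ethy
        [2.0,  1.0,  0.5, 0.05, 0.60, 0.20, 0.15, 0.80, 1.20],  # T02 thumb down
        [3.5,  1.5,  2.5, 0.08, 1.60, 0.50, 0.30, 1.40, 0.30],  # T03 overhead
        [1.5,  3.0,  0.8, 0.15, 0.40, 1.30, 0.50, 0.60, 0.40],  # T04 lateral
        [2.2,  0.8,  0.6, 0.05, 0.70, 0.25, 0.20, 0.90, -1.10], # T06 palm up
        [1.2,  0.6,  1.0, 0.04, 1.00, 0.30, 0.60, 1.20, 0.15],  # T08 stop gesture
        [1.0,  0.5,  0.4, 0.03, 0.50, 0.15, 0.25, 1.60, 0.50],  # T10 hand to mouth
        [2.8,  1.2,  1.0, 0.10, 0.80, 0.40, 0.35, 1.30, 0.90],  # T16 apple
        [3.0,  2.0,  0.7, 0.12, 0.60, 0.70, 0.45, 1.00, 0.60],  # T18 move cup
        [4.0,  2.5,  1.2, 0.18, 0.90, 0.90, 0.70, 0.70, 0.25],  # T19 move tray
        [2.5,  1.8,  0.5, 0.07, 0.55, 0.60, 0.90, 1.10, 0.70],  # T28 tennis ball
    ]
)

# Resting posture added to every trial (cm / rad).
DEFAULT_BASELINE = np.array([0.0, 0.0, 0.0, 0.0, 0.3, 0.1, 0.0, 1.2, 0.2])

DEFAULT_NOISE_SD = np.array([0.20, 0.20, 0.20, 0.010, 0.020, 0.020, 0.020, 0.025, 0.025])


@dataclass
class SimulatorParams:
    """Tunable structure of the simulated cohort.

    ``trunk_gain`` scales T8 channels upward with impairment (compensatory
    trunk motion); ``arm_gain`` scales shoulder/elbow channels downward
    (reduced active range). Gain orderings are enforced:
    trunk control <= mild <= modsev, arm control >= mild >= modsev.
    """

    templates: np.ndarray = field(default_factory=lambda: DEFAULT_TEMPLATES.copy())
    baseline: np.ndarray = field(default_factory=lambda: DEFAULT_BASELINE.copy())
    trunk_gain: dict = field(default_factory=lambda: {"control": 1.0, "mild": 1.5, "modsev": 2.2})
    arm_gain: dict = field(default_factory=lambda: {"control": 1.0, "mild": 0.80, "modsev": 0.55})
    movement_duration_s: float = 3.5
    duration_jitter_sd: float = 0.4
    amplitude_jitter_sd: float = 0.10
    noise_sd: np.ndarray = field(default_factory=lambda: DEFAULT_NOISE_SD.copy())
    noise_cutoff_hz: float = 4.0

    def validate(self) -> None:
        if self.templates.shape != (N_TASKS, N_CHANNELS):
            raise ValueError(f"templates must be ({N_TASKS}, {N_CHANNELS})")
        tg = [self.trunk_gain[g] for g in GROUPS]
        ag = [self.arm_gain[g] for g in GROUPS]
        if not (0 < tg[0] <= tg[1] <= tg[2]):
            raise ValueError("trunk_gain must satisfy 0 < control <= mild <= modsev")
        if not (ag[0] >= ag[1] >= ag[2] > 0):
            raise ValueError("arm_gain must satisfy control >= mild >= modsev > 0")

    def channel_gains(self, group: str) -> np.ndarray:
        g = np.ones(N_CHANNELS)
        g[list(TRUNK_CHANNELS)] = self.trunk_gain[group]
        g[list(ARM_CHANNELS)] = self.arm_gain[group]
        return g


def minimum_jerk_profile(t):
    """Smooth position profile 10t^3 - 15t^4 + 6t^5 on [0, 1].

    Monotone nondecreasing, 0 at t=0 and 1 at t=1, with zero velocity and
    acceleration at both ends — the standard model of a smooth point-to-point
    reach.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("minimum_jerk_profile requires t in [0, 1]")
    out = 10 * t**3 - 15 * t**4 + 6 * t**5
    return out if out.ndim else float(out)


def _reach_return_envelope(n: int, fs: float, duration_s: float, onset_s: float) -> np.ndarray:
    """Envelope rising 0->1 (minimum jerk) then falling 1->0 within the trial."""
    t = np.arange(n) / fs
    half = duration_s / 2.0
    env = np.zeros(n)
    rise = (t >= onset_s) & (t < onset_s + half)
    fall = (t >= onset_s + half) & (t <= onset_s + duration_s)
    env[rise] = minimum_jerk_profile((t[rise] - onset_s) / half)
    env[fall] = minimum_jerk_profile(np.clip((onset_s + duration_s - t[fall]) / half, 0.0, 1.0))
    return env


def _smooth_noise(rng: np.random.Generator, n: int, fs: float, cutoff_hz: float) -> np.ndarray:
    white = rng.standard_normal((n, N_CHANNELS))
    b, a = butter(4, cutoff_hz, btype="low", fs=fs)
    return filtfilt(b, a, white, axis=0)


def simulate_trial(
    task_index: int,
    group: str,
    params: SimulatorParams | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
) -> KinematicTrial:
    """One simulated reach-and-return trial for a (task, group) cell."""
    if params is None:
        params = SimulatorParams()
    params.validate()
    if rng is None:
        rng = np.random.default_rng()
    if not 0 <= task_index < N_TASKS:
        raise ValueError(f"task_index {task_index} out of range")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")

    n, fs = TRIAL_LENGTH, SAMPLE_RATE_HZ
    total_s = n / fs
    duration = float(
        np.clip(
            rng.normal(params.movement_duration_s, params.duration_jitter_sd),
            1.5,
            total_s,
        )
    )
    onset = float(rng.uniform(0.0, total_s - duration))
    env = _reach_return_envelope(n, fs, duration, onset)

    amp = params.templates[task_index] * params.channel_gains(group)
    amp = amp * rng.normal(1.0, params.amplitude_jitter_sd, size=N_CHANNELS)
    signal = params.baseline + np.outer(env, amp)
    signal = signal + _smooth_noise(rng, n, fs, params.noise_cutoff_hz) * params.noise_sd
    return KinematicTrial(
        signal=signal,
        task=TASKS[task_index],
        group=group,
        subject_id=subject_id,
        provenance="synthetic",
    )


def simulate_dataset(
    n_per_class: int,
    params: SimulatorParams | None = None,
    seed: int = 0,
    provenance: str = "real",
) -> Dataset:
    """Balanced dataset of ``30 * n_per_class`` trials.

    Each trial draws from its own counter-derived substream of a single
    seed, so the dataset is reproducible and invariant to generation order.
    ``provenance`` defaults to "real" because the simulator usually stands
    in for the experimental recordings in the augmentation protocol.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if params is None:
        params = SimulatorParams()
    params.validate()
    trials = []
    for task_index in range(N_TASKS):
        for group_index in range(N_GROUPS):
            code = encode_class(task_index, group_index).code
            for j in range(n_per_class):
                rng = np.random.default_rng(np.random.SeedSequence([seed, code, j]))
                trial = simulate_trial(
                    task_index,
                    GROUPS[group_index],
                    params,
                    rng,
                    subject_id=f"sim{code:02d}_{j:03d}",
                )
                if provenance == "real":
                    trial = KinematicTrial(
                        signal=trial.signal,
                        task=trial.task,
                        group=trial.group,
                        subject_id=trial.subject_id,
                        provenance="real",
                    )
                trials.append(trial)
    return Dataset(trials)
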