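"""Channel, task and impairment-group vocabularies for reaching trials.

Every trial carries nine kinematic degrees of freedom recorded at 60 Hz:
trunk motion proxied by the T8 thoracic landmark (x/y/z position in
centimeters plus z-axis orientation in radians), three shoulder angles and
two elbow angles (radians). The channel order is fixed and is the order in
which all arrays in this package are laid out.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Fixed channel order for all (T, 9) signal matrices.
CHANNEL_NAMES: tuple[str, ...] = (
    "T8x", "T8y", "T8z", "T8theta",
    "Sthx", "Sthy", "Sthz",
    "Ethx", "Ethy",
)

#: Physical unit of each channel after normalization.
CHANNEL_UNITS: tuple[str, ...] = ("cm", "cm", "cm", "rad", "rad", "rad", "rad", "rad", "rad")

#: Indices of the trunk (T8) channels and of the arm (shoulder/elbow) channels.
TRUNK_CHANNELS: tuple[int, ...] = (0, 1, 2, 3)
ARM_CHANNELS: tuple[int, ...] = (4, 5, 6, 7, 8)

#: The ten reach-and-return tasks, in label order.
TASKS: tuple[str, ...] = (
    "T02", "T03", "T04", "T06", "T08", "T10", "T16", "T18", "T19", "T28",
)

TASK_DESCRIPTIONS: dict[str, str] = {
    "T02": "Distal Thumb Down",
    "T03": "Overhead",
    "T04": "Lateral",
    "T06": "Distal Palm Up",
    "T08": "Stop Gesture",
    "T10": "Hand to Mouth",
    "T16": "Grab and Bite Apple",
    "T18": "Move Cup",
    "T19": "Move Tray",
    "T28": "Move Tennis Ball",
}

#: Impairment groups in label order: healthy controls, mildly impaired
#: stroke survivors, and the pooled moderate + severe group.
GROUPS: tuple[str, ...] = ("control", "mild", "modsev")

N_CHANNELS = 9
N_TASKS = len(TASKS)
N_GROUPS = len(GROUPS)
N_CLASSES = N_TASKS * N_GROUPS

SAMPLE_RATE_HZ = 60.0
TRIAL_LENGTH = 300  # 5 s at 60 Hz


@dataclass(frozen=True)
class ChannelSpec:
    """One kinematic degree of freedom: fixed index, name and unit."""

    index: int
    name: str
    unit: str

    def __post_init__(self) -> None:
        if not 0 <= self.index < N_CHANNELS:
            raise ValueError(f"channel index {self.index} out of range [0, {N_CHANNELS})")
        if CHANNEL_NAMES[self.index] != self.name:
            raise ValueError(
                f"channel {self.index} must be named {CHANNEL_NAMES[self.index]!r}, got {self.name!r}"
            )
        if CHANNEL_UNITS[self.index] != self.unit:
            raise ValueError(f"channel {self.name} must have unit {CHANNEL_UNITS[self.index]!r}")


CHANNELS: tuple[ChannelSpec, ...] = tuple(
    ChannelSpec(i, n, u) for i, (n, u) in enumerate(zip(CHANNEL_NAMES, CHANNEL_UNITS))
)
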