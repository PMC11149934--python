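"""Core data containers shared across the pipeline.

Coordinate convention (head frame, metres): x = right, y = anterior,
z = superior, origin at the centre of the conducting sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


class GeometryError(ValueError):
    """Invalid sensor/head geometry."""


@dataclass
class HeadModel:
    """Homogeneous conducting sphere."""

    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float = 0.09

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.radius <= 0:
            raise GeometryError("head-model radius must be positive")

    def contains(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        return np.linalg.norm(points - self.origin, axis=-1) < self.radius


@dataclass
class SensorArray:
    """Triaxial magnetometer array on a sphere around the head.

    ``orientations[i]`` holds three orthonormal unit vectors per sensor
    (radial, then two tangential), each measured independently, so the
    array yields ``3 * n_sensors`` channels.  Channel ordering is
    sensor-major: channels ``3i, 3i+1, 3i+2`` belong to sensor ``i``.
    """

    positions: np.ndarray          # (n_sensors, 3)
    orientations: np.ndarray       # (n_sensors, 3, 3)
    labels: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise GeometryError("positions must be (n_sensors, 3)")
        if self.orientations.shape != (self.n_sensors, 3, 3):
            raise GeometryError("orientations must be (n_sensors, 3, 3)")
        if len(self.labels) != self.n_channels:
            raise GeometryError("need one label per channel")
        gram = np.einsum("nij,nkj->nik", self.orientations, self.orientations)
        if not np.allclose(gram, np.eye(3), atol=1e-10):
            raise GeometryError("sensor triads must be orthonormal")

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    @property
    def n_channels(self) -> int:
        return 3 * self.n_sensors

    @property
    def channel_positions(self) -> np.ndarray:
        """(n_channels, 3): each channel sits at its sensor's position."""
        return np.repeat(self.positions, 3, axis=0)

    @property
    def channel_orientations(self) -> np.ndarray:
        """(n_channels, 3): the unit vector each channel projects B onto."""
        return self.orientations.reshape(self.n_channels, 3)

    def subset_channels(self, keep: np.ndarray) -> "ChannelGeometry":
        keep = np.asarray(keep, dtype=bool)
        return ChannelGeometry(
            positions=self.channel_positions[keep],
            orientations=self.channel_orientations[keep],
            labels=[l for l, k in zip(self.labels, keep) if k],
        )


@dataclass
class ChannelGeometry:
    """Per-channel geometry after bad channels have been dropped."""

    positions: np.ndarray     # (n_channels, 3)
    orientations: np.ndarray  # (n_channels, 3)
    labels: list[str]

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


def channel_geometry(array: SensorArray) -> ChannelGeometry:
    return ChannelGeometry(
        positions=array.channel_positions.copy(),
        orientations=array.channel_orientations.copy(),
        labels=list(array.labels),
    )


@dataclass
class Paradigm:
    """Alternating two-finger somatosensory stimulation.

    Each trial is ``stim_duration`` of tapping followed by
    ``rest_duration`` of rest; fingers alternate (index D2, little D5).
    """

    n_trials_per_finger: int = 42
    stim_duration: float = 0.5
    rest_duration: float = 3.0
    fingers: tuple[str, ...] = ("D2", "D5")
    lead_in: float = 1.0

    @property
    def trial_period(self) -> float:
        return self.stim_duration + self.rest_duration

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_finger * len(self.fingers)

    @property
    def task_duration(self) -> float:
        """Total stimulated task time (trials x period), excluding lead-in."""
        return self.n_trials * self.trial_period

    @property
    def total_duration(self) -> float:
        return self.lead_in + self.task_duration

    @property
    def onsets(self) -> np.ndarray:
        onsets = self.lead_in + self.trial_period * np.arange(self.n_trials)
        return onsets

    @property
    def trial_fingers(self) -> list[str]:
        return [self.fingers[i % len(self.fingers)] for i in range(self.n_trials)]


@dataclass
class Recording:
    """A continuous multichannel recording with geometry and task markers."""

    data: np.ndarray             # (n_channels, n_samples)
    fs: float
    geometry: ChannelGeometry
    paradigm: Paradigm
    subject_id: str = "S000"
    age: float = float("nan")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.data.shape[0] != self.geometry.n_channels:
            raise ValueError("channel count mismatch with geometry")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


@dataclass
class EpochSet:
    """Stimulus-locked epochs cut from a recording.

    Sample convention is half-open ``[t0, t1)`` relative to each onset:
    an epoch holds ``round((t1 - t0) * fs)`` samples starting at
    ``round((onset + t0) * fs)``.
    """

    data: np.ndarray           # (n_trials, n_channels, n_samples)
    fs: float
    window: tuple[float, float]
    fingers: list[str]
    trial_keep: np.ndarray     # bool per trial
    onsets: np.ndarray

    def __post_init__(self) -> None:
        self.trial_keep = np.asarray(self.trial_keep, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_samples) / self.fs

    @property
    def kept(self) -> np.ndarray:
        """Kept trials only, (n_kept, n_channels, n_samples)."""
        return self.data[self.trial_keep]

    @property
    def kept_fingers(self) -> list[str]:
        return [f for f, k in zip(self.fingers, self.trial_keep) if k]

    def concatenated(self) -> np.ndarray:
        """Kept trials joined along time, (n_channels, n_kept * n_samples)."""
        kept = self.kept
        return kept.transpose(1, 0, 2).reshape(self.n_channels, -1)

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Sample slice for a time window (seconds, epoch-relative)."""
        i0 = int(round((window[0] - self.window[0]) * self.fs))
        i1 = int(round((window[1] - self.window[0]) * self.fs))
        if i0 < 0 or i1 > self.n_samples:
            raise ValueError(f"window {window} outside epoch {self.window}")
        return slice(i0, i1)
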