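"""Shared in-memory containers used across the simulation and analysis stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GREEN = "green_detector"
RED = "red_detector"


@dataclass
class ImageStack:
    """A TIRF movie: ``frames`` is an (n_frames, H, W) intensity array.

    ``pixel_size`` is in micrometres and ``frame_rate`` in Hz.
    """

    frames: np.ndarray
    pixel_size: float
    frame_rate: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        if self.frame_rate <= 0 or self.pixel_size <= 0:
            raise ValueError("frame_rate and pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class FluorescenceTrace:
    """One spot's background-subtracted intensity time series.

    ``truth`` optionally carries the simulation ground truth (number of
    visible fluorophores, true bleach frames, censoring flag) so detectors
    can be scored against it.
    """

    spot_id: int
    intensities: np.ndarray
    frame_rate: float
    position: tuple[float, float] = (0.0, 0.0)
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("intensities must be one-dimensional")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensities.size


@dataclass
class PhotonStream:
    """Time-tagged photons from one detector.

    macrotimes are seconds since acquisition start (sorted ascending);
    microtimes are nanoseconds since the most recent laser pulse;
    pulse_origin identifies the originating laser (488 or 561 nm).
    ``labels`` tags each photon's simulated provenance (0 = signal,
    1 = crosstalk, 2 = background) when the stream is synthetic.
    """

    arrival_times: np.ndarray
    microtimes: np.ndarray
    pulse_origin: np.ndarray
    channel: str
    pulse_period: float = 100.0
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.arrival_times = np.asarray(self.arrival_times, dtype=float)
        self.microtimes = np.asarray(self.microtimes, dtype=float)
        self.pulse_origin = np.asarray(self.pulse_origin, dtype=np.int16)
        if not (
            self.arrival_times.shape
            == self.microtimes.shape
            == self.pulse_origin.shape
        ):
            raise ValueError("photon record arrays must have equal length")
        if self.arrival_times.size and np.any(np.diff(self.arrival_times) < 0):
            raise ValueError("arrival_times must be nondecreasing")
        if self.microtimes.size and (
            self.microtimes.min() < 0 or self.microtimes.max() >= self.pulse_period
        ):
            raise ValueError("microtimes must lie in [0, pulse_period)")
        if self.channel not in (GREEN, RED):
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def n_photons(self) -> int:
        return self.arrival_times.size

    @property
    def duration(self) -> float:
        return float(self.meta.get("duration", self.arrival_times[-1] if self.n_photons else 0.0))
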