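"""Core data containers for multichannel MCG recordings, averaged beats and maps.

Coordinate frame (used throughout the package): the subject is viewed from the
front with the sensor plane at z = 0.  +x points toward the subject's left,
+y toward the subject's inferior (feet).  Angles are measured from +x toward
+y and reported in degrees on (-180, 180], so the "lower-left" quadrant of the
clinical convention is (0deg, 90deg) and "lower-right" is (90deg, 180deg).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "wrap_angle_deg",
    "FormatError",
    "SensorGrid",
    "SubjectMeta",
    "MCGRecording",
    "Fiducials",
    "AveragedBeat",
    "FieldMap",
    "PCDMap",
    "MCGFeatures",
    "SubjectRecord",
    "FEATURE_NAMES",
]

#: The nine MCG parameters, in reporting order.
FEATURE_NAMES = [
    "QRSd",
    "NCD_R",
    "NCD_T",
    "CA_R",
    "CA_T",
    "PD_R",
    "PD_T",
    "FMA_R",
    "FMA_T",
]


def wrap_angle_deg(angle: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees onto (-180, 180]."""
    wrapped = -np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) + 180.0
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped


class FormatError(ValueError):
    """A container file or table violates the expected layout."""


@dataclass(frozen=True)
class SensorGrid:
    """Planar magnetometer array geometry on the z = 0 measurement plane.

    Parameters
    ----------
    channel_ids : list of str
        One identifier per channel.
    positions : (n_channels, 2) array
        Sensor (x, y) coordinates in metres.
    """

    channel_ids: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array of metres")
        if len(self.channel_ids) != pos.shape[0]:
            raise ValueError("channel_ids and positions length mismatch")
        if pos.shape[0] < 4:
            raise ValueError("a sensor grid needs at least 4 channels")
        if len({tuple(p) for p in pos.round(12)}) != pos.shape[0]:
            raise ValueError("sensor positions must be distinct")
        x_span = np.ptp(pos[:, 0])
        y_span = np.ptp(pos[:, 1])
        if x_span <= 0 or y_span <= 0:
            raise ValueError("grid bounding box must have positive area")

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) in metres."""
        return (
            float(self.positions[:, 0].min()),
            float(self.positions[:, 0].max()),
            float(self.positions[:, 1].min()),
            float(self.positions[:, 1].max()),
        )


@dataclass
class SubjectMeta:
    """Demographics and class label attached to a recording."""

    id: str = "unknown"
    age: float = float("nan")
    sex: str = "unknown"  # {"female", "male", "unknown"}
    label: str = "unknown"  # {"HC", "PH", "unknown"}


@dataclass
class MCGRecording:
    """Multichannel Bz time series plus the geometry it was measured on.

    ``samples`` is a channels x time matrix in tesla.
    """

    grid: SensorGrid
    sampling_rate: float
    samples: np.ndarray
    subject_meta: SubjectMeta = field(default_factory=SubjectMeta)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.samples.shape[0] != self.grid.n_channels:
            raise FormatError(
                "samples: row count %d does not match %d grid channels"
                % (self.samples.shape[0], self.grid.n_channels)
            )
        if not self.sampling_rate > 0:
            raise FormatError("sampling_rate: must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("samples: non-finite values present")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Fiducials:
    """Sample-index landmarks of one averaged cardiac cycle."""

    qrs_onset: Optional[int] = None
    r_peak: Optional[int] = None
    qrs_offset: Optional[int] = None
    t_peak: Optional[int] = None

    def complete(self) -> bool:
        return None not in (self.qrs_onset, self.r_peak, self.qrs_offset, self.t_peak)

    def validate(self, n_samples: int) -> None:
        if not self.complete():
            raise ValueError("fiducials incomplete")
        seq = (self.qrs_onset, self.r_peak, self.qrs_offset, self.t_peak)
        if any(i < 0 or i >= n_samples for i in seq):
            raise ValueError("fiducials out of beat bounds")
        if not (self.qrs_onset < self.r_peak < self.qrs_offset < self.t_peak):
            raise ValueError("fiducials must satisfy onset < R < offset < T")


@dataclass
class AveragedBeat:
    """Beat-averaged channels x time block spanning one cardiac cycle."""

    grid: SensorGrid
    sampling_rate: float
    samples: np.ndarray
    fiducials: Fiducials = field(default_factory=Fiducials)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape[0] != self.grid.n_channels:
            raise ValueError("beat channel count does not match grid")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class FieldMap:
    """Interpolated Bz raster at one instant.

    ``pixels`` is indexed [iy, ix]; ``extent`` is (x_min, x_max, y_min, y_max)
    in metres; ``instant`` is the beat sample index the map was computed at.
    """

    pixels: np.ndarray
    extent: tuple[float, float, float, float]
    instant: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 16:
            raise ValueError("field map raster must be at least 16 x 16")
        x_min, x_max, y_min, y_max = self.extent
        if not (x_max > x_min and y_max > y_min):
            raise ValueError("extent must have positive area")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_pitch(self) -> tuple[float, float]:
        """(dx, dy) physical size of one pixel in metres."""
        ny, nx = self.pixels.shape
        x_min, x_max, y_min, y_max = self.extent
        return ((x_max - x_min) / (nx - 1), (y_max - y_min) / (ny - 1))

    @property
    def x_coords(self) -> np.ndarray:
        x_min, x_max, _, _ = self.extent
        return np.linspace(x_min, x_max, self.pixels.shape[1])

    @property
    def y_coords(self) -> np.ndarray:
        _, _, y_min, y_max = self.extent
        return np.linspace(y_min, y_max, self.pixels.shape[0])


@dataclass
class PCDMap:
    """Pseudo-current-density vector raster (Hosaka-Cohen construction)."""

    cx: np.ndarray
    cy: np.ndarray
    magnitude: np.ndarray
    extent: tuple[float, float, float, float]
    instant: int

    def __post_init__(self) -> None:
        self.cx = np.asarray(self.cx, dtype=float)
        self.cy = np.asarray(self.cy, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if not (self.cx.shape == self.cy.shape == self.magnitude.shape):
            raise ValueError("cx, cy and magnitude must share a shape")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be non-negative")


@dataclass
class MCGFeatures:
    """The nine MCG parameters of one subject.

    QRSd is in milliseconds, NCD_* are dimensionless focality indices (>= 1),
    CA_* and FMA_* are degrees on (-180, 180], PD_* are raster pixels.
    """

    QRSd: float
    NCD_R: float
    NCD_T: float
    CA_R: float
    CA_T: float
    PD_R: float
    PD_T: float
    FMA_R: float
    FMA_T: float

    def __post_init__(self) -> None:
        if not self.QRSd > 0:
            raise ValueError("QRSd must be positive")
        if self.NCD_R < 1 or self.NCD_T < 1:
            raise ValueError("NCD focality index is >= 1 by construction")
        if self.PD_R < 0 or self.PD_T < 0:
            raise ValueError("polar distances are non-negative")
        for name in ("CA_R", "CA_T", "FMA_R", "FMA_T"):
            setattr(self, name, wrap_angle_deg(getattr(self, name)))

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FEATURE_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "MCGFeatures":
        return cls(**{name: float(d[name]) for name in FEATURE_NAMES})


@dataclass
class SubjectRecord:
    """One modelling row: demographics, label, features, optional ECG findings."""

    id: str
    age: float
    sex: str
    label: str
    features: MCGFeatures
    ecg_findings: Optional[dict[str, int]] = None
    extras: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {"id": self.id, "age": self.age, "sex": self.sex, "label": self.label}
        row.update(self.features.as_dict())
        row.update(self.extras)
        return row
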