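"""Field maps, pseudo-current-density maps and the nine MCG parameters.

The magnetic-field map (MFM) is a smooth raster interpolation of the sensor
Bz values at one instant; the pseudo-current-density (PCD) map is its
Hosaka-Cohen transform

    c = (dBz/dy, -dBz/dx)

i.e. the in-plane gradient rotated by 90 degrees, whose vectors align with
the underlying current direction.  From these two rasters at the R- and
T-peak instants come eight of the nine parameters (current angle CA,
normalized current density NCD from the PCD map; polar distance PD and
field-map angle FMA from the MFM); QRS duration comes from the butterfly
stage.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RBFInterpolator

from .containers import AveragedBeat, FieldMap, MCGFeatures, PCDMap, wrap_angle_deg
from .preprocess import qrs_bounds

__all__ = [
    "interpolate_field_map",
    "field_map_from_values",
    "pcd_transform",
    "current_angle",
    "normalized_current_density",
    "find_poles",
    "polar_distance",
    "field_map_angle",
    "extract_features",
]


def interpolate_field_map(beat: AveragedBeat, instant: int, raster_px: int = 100) -> FieldMap:
    """Interpolate channel Bz at ``instant`` onto a raster over the sensor box.

    Uses thin-plate-spline interpolation (smooth, exact at the sensor
    locations) — the standard choice for biomagnetic topographic maps.
    """
    if not 0 <= instant < beat.n_samples:
        raise ValueError(f"instant {instant} outside beat of length {beat.n_samples}")
    if raster_px < 16:
        raise ValueError("raster_px must be at least 16")
    values = beat.samples[:, instant]
    x_min, x_max, y_min, y_max = beat.grid.bounding_box
    interp = RBFInterpolator(beat.grid.positions, values, kernel="thin_plate_spline")
    xs = np.linspace(x_min, x_max, raster_px)
    ys = np.linspace(y_min, y_max, raster_px)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pixels = interp(pts).reshape(raster_px, raster_px)
    return FieldMap(pixels=pixels, extent=(x_min, x_max, y_min, y_max), instant=instant)


def field_map_from_values(
    pixels: np.ndarray, extent: tuple[float, float, float, float], instant: int = 0
) -> FieldMap:
    """Wrap an already-rasterised Bz array (e.g. a closed-form dipole field)."""
    return FieldMap(pixels=np.asarray(pixels, dtype=float), extent=extent, instant=instant)


def pcd_transform(fieldmap: FieldMap) -> PCDMap:
    """Hosaka-Cohen pseudo-current map: (cx, cy) = (dBz/dy, -dBz/dx).

    Central differences in the interior, one-sided at the raster border.
    """
    if min(fieldmap.pixels.shape) < 3:
        raise ValueError("raster must be at least 3 x 3 for gradients")
    if not np.all(np.isfinite(fieldmap.pixels)):
        raise ValueError("field map contains non-finite values")
    dx, dy = fieldmap.pixel_pitch
    dbz_dy, dbz_dx = np.gradient(fieldmap.pixels, dy, dx)
    cx = dbz_dy
    cy = -dbz_dx
    return PCDMap(
        cx=cx,
        cy=cy,
        magnitude=np.hypot(cx, cy),
        extent=fieldmap.extent,
        instant=fieldmap.instant,
    )


def current_angle(pcdmap: PCDMap) -> float:
    """Angle (degrees) of the vector-summed total current over all pixels."""
    sx = float(pcdmap.cx.sum())
    sy = float(pcdmap.cy.sum())
    if sx == 0.0 and sy == 0.0:
        raise ValueError("total current vector is zero; angle undefined")
    return wrap_angle_deg(np.degrees(np.arctan2(sy, sx)))


def normalized_current_density(pcdmap: PCDMap) -> float:
    """Dimensionless focality index: max / mean of the PCD magnitude (>= 1)."""
    mean = float(pcdmap.magnitude.mean())
    if mean <= 0.0:
        raise ValueError("all-zero PCD map; NCD undefined")
    return float(pcdmap.magnitude.max()) / mean


def find_poles(fieldmap: FieldMap) -> tuple[tuple[int, int], tuple[int, int]]:
    """Positive (argmax) and negative (argmin) pole pixels as (px, py) pairs."""
    pix = fieldmap.pixels
    if np.ptp(pix) == 0:
        raise ValueError("constant field map has no poles")
    iy_max, ix_max = np.unravel_index(np.argmax(pix), pix.shape)
    iy_min, ix_min = np.unravel_index(np.argmin(pix), pix.shape)
    return (int(ix_max), int(iy_max)), (int(ix_min), int(iy_min))


def polar_distance(
    positive: tuple[int, int], negative: tuple[int, int]
) -> float:
    """Euclidean pole-to-pole distance in pixels."""
    return float(np.hypot(positive[0] - negative[0], positive[1] - negative[1]))


def field_map_angle(
    positive: tuple[int, int],
    negative: tuple[int, int],
    fieldmap: FieldMap | None = None,
) -> float:
    """Angle (degrees) of the positive-to-negative pole axis.

    With a ``fieldmap`` the pixel offsets are converted to physical metres
    (handles anisotropic pixels); otherwise pixel units are used directly.
    """
    dx = negative[0] - positive[0]
    dy = negative[1] - positive[1]
    if dx == 0 and dy == 0:
        raise ValueError("coincident poles; field map angle undefined")
    if fieldmap is not None:
        px, py = fieldmap.pixel_pitch
        dx, dy = dx * px, dy * py
    return wrap_angle_deg(np.degrees(np.arctan2(dy, dx)))


def extract_features(beat: AveragedBeat, raster_px: int = 100) -> MCGFeatures:
    """Compose the nine MCG parameters from one averaged beat.

    Requires r_peak and t_peak fiducials; computes QRS bounds if missing.
    """
    fid = beat.fiducials
    if fid.r_peak is None or fid.t_peak is None:
        raise ValueError("beat fiducials (r_peak, t_peak) must be set; run locate_wave_peaks")
    if fid.qrs_onset is None or fid.qrs_offset is None:
        qrs_bounds(beat)
    qrsd = (fid.qrs_offset - fid.qrs_onset) / beat.sampling_rate * 1000.0

    out: dict[str, float] = {"QRSd": qrsd}
    for suffix, instant in (("R", fid.r_peak), ("T", fid.t_peak)):
        try:
            fmap = interpolate_field_map(beat, instant, raster_px)
            pcd = pcd_transform(fmap)
            out[f"CA_{suffix}"] = current_angle(pcd)
            out[f"NCD_{suffix}"] = normalized_current_density(pcd)
            pos, neg = find_poles(fmap)
            out[f"PD_{suffix}"] = polar_distance(pos, neg)
            out[f"FMA_{suffix}"] = field_map_angle(pos, neg, fmap)
        except ValueError as exc:
            raise ValueError(f"feature extraction failed at the {suffix}-peak instant: {exc}") from exc
    return MCGFeatures(**out)
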