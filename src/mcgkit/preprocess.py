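"""Raw recording -> averaged beat with fiducials (the butterfly-diagram stage).

The butterfly diagram overlays every channel of one averaged cycle; the R and
T peak instants are defined as the time at which the single channel with the
largest absolute amplitude peaks within the physiological search window, and
QRS duration comes from a relative-threshold crossing of the cross-channel
RMS trace.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import signal

from .containers import AveragedBeat, Fiducials, MCGRecording

__all__ = [
    "bandpass",
    "detect_r_peaks",
    "average_beats",
    "locate_wave_peaks",
    "qrs_bounds",
    "preprocess_recording",
]


def bandpass(recording: MCGRecording, low_hz: float, high_hz: float, order: int = 4) -> MCGRecording:
    """Zero-phase Butterworth band-pass applied channel-wise.

    ``low_hz = 0`` degenerates to a low-pass (no DC removal).
    """
    nyq = recording.sampling_rate / 2.0
    if not (0 <= low_hz < high_hz < nyq):
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) for fs={recording.sampling_rate}")
    if low_hz > 0:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=recording.sampling_rate, output="sos")
    else:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=recording.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    return MCGRecording(
        grid=recording.grid,
        sampling_rate=recording.sampling_rate,
        samples=filtered,
        subject_meta=recording.subject_meta,
    )


def _rms_trace(samples: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean(samples**2, axis=0))


def detect_r_peaks(
    recording: MCGRecording,
    threshold_fraction: float = 0.6,
    refractory_ms: float = 300.0,
) -> list[int]:
    """R-peak sample indices from the cross-channel RMS trace.

    A peak must exceed ``threshold_fraction`` of the maximum RMS excursion
    above baseline (median RMS), with a refractory period between peaks.
    """
    if recording.duration < 2.0:
        raise ValueError("need at least 2 s of data for R detection")
    rms = _rms_trace(recording.samples)
    baseline = np.median(rms)
    height = baseline + threshold_fraction * (rms.max() - baseline)
    if rms.max() <= baseline or height <= 0:
        return []
    distance = max(int(refractory_ms / 1000.0 * recording.sampling_rate), 1)
    peaks, _ = signal.find_peaks(rms, height=height, distance=distance)
    return [int(p) for p in peaks]


def average_beats(
    recording: MCGRecording,
    peaks: list[int],
    window_before_ms: float = 300.0,
    window_after_ms: float = 500.0,
) -> AveragedBeat:
    """Pointwise mean of R-aligned windows; r_peak fiducial = alignment sample."""
    before = int(round(window_before_ms / 1000.0 * recording.sampling_rate))
    after = int(round(window_after_ms / 1000.0 * recording.sampling_rate))
    usable = [p for p in peaks if p - before >= 0 and p + after < recording.n_samples]
    if not usable:
        raise ValueError("no peak with a full averaging window inside the recording")
    stack = np.stack([recording.samples[:, p - before : p + after + 1] for p in usable])
    return AveragedBeat(
        grid=recording.grid,
        sampling_rate=recording.sampling_rate,
        samples=stack.mean(axis=0),
        fiducials=Fiducials(r_peak=before),
    )


def locate_wave_peaks(
    beat: AveragedBeat,
    r_window_ms: float = 60.0,
    t_window_ms: tuple[float, float] = (150.0, 450.0),
) -> tuple[int, int, dict]:
    """R- and T-peak instants: argmax of |Bz| over channels and time per window.

    Returns (r_peak, t_peak, info) where info records the attaining channels,
    and updates the beat's fiducials in place.
    """
    if beat.fiducials.r_peak is None:
        raise ValueError("beat needs an alignment r_peak fiducial")
    fs = beat.sampling_rate
    align = beat.fiducials.r_peak
    r_lo = max(align - int(r_window_ms / 1000.0 * fs), 0)
    r_hi = min(align + int(r_window_ms / 1000.0 * fs) + 1, beat.n_samples)
    if r_hi <= r_lo:
        raise ValueError("empty R search window")
    absb = np.abs(beat.samples)
    r_ch, r_off = np.unravel_index(np.argmax(absb[:, r_lo:r_hi]), absb[:, r_lo:r_hi].shape)
    r_peak = r_lo + int(r_off)

    t_lo = r_peak + int(t_window_ms[0] / 1000.0 * fs)
    t_hi = min(r_peak + int(t_window_ms[1] / 1000.0 * fs) + 1, beat.n_samples)
    if t_hi <= t_lo:
        raise ValueError("empty T search window (beat too short)")
    t_ch, t_off = np.unravel_index(np.argmax(absb[:, t_lo:t_hi]), absb[:, t_lo:t_hi].shape)
    t_peak = t_lo + int(t_off)

    beat.fiducials.r_peak = r_peak
    beat.fiducials.t_peak = t_peak
    info = {"r_channel": beat.grid.channel_ids[int(r_ch)], "t_channel": beat.grid.channel_ids[int(t_ch)]}
    return r_peak, t_peak, info


def qrs_bounds(beat: AveragedBeat, k: float = 0.05) -> tuple[int, int, float]:
    """QRS onset/offset by relative RMS threshold; returns (onset, offset, QRSd ms).

    The threshold is baseline_RMS + k * (peak_RMS - baseline_RMS); onset is the
    last sample before the R peak below threshold (scanning backwards), offset
    the first after it (scanning forwards).  Updates the beat fiducials.
    """
    if beat.fiducials.r_peak is None:
        raise ValueError("r_peak fiducial must be set before qrs_bounds")
    rms = _rms_trace(beat.samples)
    r = beat.fiducials.r_peak
    baseline = float(np.median(rms))
    theta = baseline + k * (rms[r] - baseline)
    if rms[r] <= baseline:
        raise ValueError("unusable beat: R-peak RMS does not exceed baseline")
    below_before = np.nonzero(rms[:r] < theta)[0]
    below_after = np.nonzero(rms[r + 1 :] < theta)[0]
    if below_before.size == 0 or below_after.size == 0:
        raise ValueError("unusable beat: QRS threshold never crossed")
    onset = int(below_before[-1])
    offset = int(r + 1 + below_after[0])
    qrsd_ms = (offset - onset) / beat.sampling_rate * 1000.0
    beat.fiducials.qrs_onset = onset
    beat.fiducials.qrs_offset = offset
    return onset, offset, qrsd_ms


def preprocess_recording(
    recording: MCGRecording,
    band: Optional[tuple[float, float]] = (0.5, 40.0),
    window_before_ms: float = 300.0,
    window_after_ms: float = 500.0,
) -> AveragedBeat:
    """Full preprocessing: optional filtering, R detection, averaging, fiducials."""
    rec = bandpass(recording, *band) if band is not None else recording
    peaks = detect_r_peaks(rec)
    if not peaks:
        raise ValueError("no R peaks detected")
    beat = average_beats(rec, peaks, window_before_ms, window_after_ms)
    locate_wave_peaks(beat)
    qrs_bounds(beat)
    beat.fiducials.validate(beat.n_samples)
    return beat
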