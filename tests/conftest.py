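import numpy as np
import pytest

from mcgkit.containers import SensorGrid
from mcgkit.preprocess import preprocess_recording
from mcgkit.simulate import beat_source_model, default_grid, simulate_beat


@pytest.fixture(scope="session")
def grid() -> SensorGrid:
    return default_grid()


@pytest.fixture(scope="session")
def hc_beat(grid):
    """Noise-free averaged beat from a healthy-regime source (angle 40 deg)."""
    rec = simulate_beat(beat_source_model(qrs_angle_deg=40.0), grid, noise_sd=0.0, n_beats=4)
    return preprocess_recording(rec, band=None)


@pytest.fixture(scope="session")
def ph_beat(grid):
    """Noise-free averaged beat from a PH-regime source (angle 115 deg)."""
    rec = simulate_beat(
        beat_source_model(qrs_angle_deg=115.0, depth=0.045), grid, noise_sd=0.0, n_beats=4
    )
    return preprocess_recording(rec, band=None)


def make_recording(samples, fs=1000.0, grid=None):
    """Wrap a channels x time array into a recording on a small grid."""
    from mcgkit.containers import MCGRecording

    n_ch = samples.shape[0]
    if grid is None:
        side = int(np.ceil(np.sqrt(n_ch)))
        offs = np.arange(side) * 0.04
        xs, ys = np.meshgrid(offs, offs)
        pos = np.column_stack([xs.ravel(), ys.ravel()])[:n_ch]
        grid = SensorGrid([f"c{i}" for i in range(n_ch)], pos)
    return MCGRecording(grid=grid, sampling_rate=fs, samples=samples)
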