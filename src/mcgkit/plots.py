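"""Plotting helpers: butterfly diagram, field/PCD maps, ROC and calibration."""

from __future__ import annotations

import numpy as np

from .containers import AveragedBeat, FieldMap, PCDMap


def plot_butterfly(beat: AveragedBeat, ax=None):
    """All channel traces of one averaged cycle, fiducials marked."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    t = np.arange(beat.n_samples) / beat.sampling_rate * 1000.0
    ax.plot(t, beat.samples.T * 1e12, lw=0.6, color="0.3", alpha=0.7)
    for name in ("qrs_onset", "r_peak", "qrs_offset", "t_peak"):
        idx = getattr(beat.fiducials, name)
        if idx is not None:
            ax.axvline(t[idx], ls="--", lw=0.8)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("Bz (pT)")
    return ax


def plot_field_map(fmap: FieldMap, ax=None):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    x_min, x_max, y_min, y_max = fmap.extent
    im = ax.imshow(fmap.pixels * 1e12, origin="lower", extent=(x_min, x_max, y_min, y_max),
                   cmap="RdBu_r", aspect="equal")
    plt.colorbar(im, ax=ax, label="Bz (pT)")
    return ax


def plot_pcd_map(pcd: PCDMap, step: int = 6, ax=None):
    """Quiver of the pseudo-current vectors over the magnitude raster."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    x_min, x_max, y_min, y_max = pcd.extent
    ax.imshow(pcd.magnitude, origin="lower", extent=(x_min, x_max, y_min, y_max),
              cmap="viridis", aspect="equal")
    ny, nx = pcd.cx.shape
    xs = np.linspace(x_min, x_max, nx)[::step]
    ys = np.linspace(y_min, y_max, ny)[::step]
    gx, gy = np.meshgrid(xs, ys)
    ax.quiver(gx, gy, pcd.cx[::step, ::step], pcd.cy[::step, ::step], color="w", width=0.003)
    return ax


def plot_roc(scores, labels, ax=None):
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    thr = np.concatenate([[np.inf], np.sort(np.unique(scores))[::-1]])
    tpr = [(scores >= t)[labels == 1].mean() for t in thr]
    fpr = [(scores >= t)[labels == 0].mean() for t in thr]
    ax.plot(fpr, tpr, marker=".", ms=3)
    ax.plot([0, 1], [0, 1], ls="--", color="0.6")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    return ax


def plot_calibration(cal_table, ax=None):
    """Observed-vs-predicted from a quantile-binned calibration table."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    ax.errorbar(
        cal_table["mean_predicted"],
        cal_table["observed_rate"],
        yerr=[
            cal_table["observed_rate"] - cal_table["ci_lower"],
            cal_table["ci_upper"] - cal_table["observed_rate"],
        ],
        marker="o",
        ls="-",
    )
    ax.plot([0, 1], [0, 1], ls="--", color="0.6")
    ax.set_xlabel("predicted probability")
    ax.set_ylabel("observed event rate")
    return ax
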