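"""Live time-lapse analysis of aggregate growth.

The spatial mean of each network output frame, normalized over the
series, traces aggregate formation: a logistic (sigmoid) fit

    y(t) = b + A / (1 + exp(-k (t - t0)))

summarizes it, and the 5% / 95% crossings of the fitted curve split
the series into three regimes — diffuse protein, aggregate formation,
and steady state.  Dry mass and area trajectories are extracted per
frame from the prediction masks and the co-registered phase images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .model import PredictionImage, prediction_mask
from .qpi import PhaseImage, aggregate_dry_mass, dry_mass_density_map

__all__ = [
    "Trajectory",
    "SigmoidFit",
    "RegimeSegmentation",
    "intensity_trajectory",
    "fit_sigmoid",
    "segment_regimes",
    "mass_area_trajectory",
    "logistic",
]


def logistic(t, baseline, amplitude, rate, midpoint):
    return baseline + amplitude / (1.0 + np.exp(-rate * (t - midpoint)))


@dataclass
class Trajectory:
    """Per-frame mean prediction intensity, min-max normalized over the series."""

    times_min: np.ndarray
    mean_intensity: np.ndarray
    per_frame_std: np.ndarray
    per_frame_std_roi: np.ndarray | None = None
    degenerate: bool = False  # all-zero / constant series ("no aggregate formed")

    def __post_init__(self) -> None:
        if not (len(self.times_min) == len(self.mean_intensity) == len(self.per_frame_std)):
            raise ValueError("trajectory arrays must share length")


@dataclass
class SigmoidFit:
    amplitude: float
    baseline: float
    rate: float
    midpoint_min: float
    residual_norm: float
    degenerate: bool = False

    def __call__(self, t):
        return logistic(np.asarray(t, dtype=float), self.baseline,
                        self.amplitude, self.rate, self.midpoint_min)


@dataclass
class RegimeSegmentation:
    """Frame indices (b1, b2) splitting diffuse / formation / steady state."""

    boundaries: tuple[int, int]
    n_frames: int

    def __post_init__(self) -> None:
        b1, b2 = self.boundaries
        if not 0 <= b1 <= b2 <= self.n_frames:
            raise ValueError("boundaries must satisfy 0 <= b1 <= b2 <= n_frames")

    def regime_of(self, frame: int) -> int:
        b1, b2 = self.boundaries
        return 0 if frame < b1 else (1 if frame < b2 else 2)


def intensity_trajectory(
    predictions: list[PredictionImage],
    frame_interval_min: float = 2.0,
    roi_mask: np.ndarray | None = None,
) -> Trajectory:
    """Mean output intensity per frame, normalized to [0, 1] over the series.

    Per-frame standard deviations are the spatial std within each whole
    image; if an ROI mask is given the within-ROI std is emitted as
    well.  A constant series cannot be normalized and is flagged
    degenerate ("no aggregate formed").
    """
    if len(predictions) < 3:
        raise ValueError("need >= 3 frames")
    means = np.array([float(p.values.mean()) for p in predictions])
    stds = np.array([float(p.values.std()) for p in predictions])
    stds_roi = None
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        stds_roi = np.array([float(p.values[roi_mask].std()) for p in predictions])
    times = np.arange(len(predictions), dtype=float) * frame_interval_min

    lo, hi = means.min(), means.max()
    if hi == lo:
        warnings.warn("constant intensity series: no aggregate formed", stacklevel=2)
        return Trajectory(times, np.zeros_like(means), stds, stds_roi, degenerate=True)
    return Trajectory(times, (means - lo) / (hi - lo), stds, stds_roi)


def fit_sigmoid(traj: Trajectory, residual_threshold: float = 0.15) -> SigmoidFit:
    """Least-squares logistic fit of the intensity trajectory.

    The fit is flagged degenerate when the series is constant, spans
    less than half the normalized range, or leaves an RMS residual
    above ``residual_threshold``.  Decaying series fit with a negative
    rate and are likewise flagged (``rate < 0``).
    """
    t = np.asarray(traj.times_min, dtype=float)
    y = np.asarray(traj.mean_intensity, dtype=float)
    if traj.degenerate or np.ptp(y) < 0.5:
        return SigmoidFit(float(np.ptp(y)), float(y.min()), 0.0,
                          float(t.mean()), float(np.ptp(y)), degenerate=True)

    dt = np.median(np.diff(t)) if t.size > 1 else 1.0
    rising = y[-1] >= y[0]
    k0 = (1.0 if rising else -1.0) * 4.0 / max(t[-1] - t[0], dt) * 4
    t0_guess = float(np.interp(0.5, y if rising else y[::-1],
                               t if rising else t[::-1]))
    p0 = (float(y.min()), float(np.ptp(y)), k0, t0_guess)
    try:
        popt, _ = curve_fit(logistic, t, y, p0=p0, maxfev=20000)
    except RuntimeError:
        return SigmoidFit(np.ptp(y), float(y.min()), 0.0, float(t.mean()),
                          float(np.inf), degenerate=True)
    baseline, amplitude, rate, midpoint = (float(v) for v in popt)
    resid = float(np.sqrt(np.mean((logistic(t, *popt) - y) ** 2)))
    degenerate = resid > residual_threshold or rate < 0 or amplitude <= 0
    return SigmoidFit(amplitude, baseline, rate, midpoint, resid, degenerate)


def segment_regimes(
    traj: Trajectory,
    fit: SigmoidFit,
    low_frac: float = 0.05,
    high_frac: float = 0.95,
) -> RegimeSegmentation:
    """Three-regime split from the fitted curve's 5% / 95% crossings.

    Boundary 1 is the first frame where the fitted curve exceeds
    baseline + low_frac * amplitude; boundary 2 the first exceeding
    baseline + high_frac * amplitude.  For an ideal logistic these
    crossings sit at t0 -/+ ln(19)/k.  An all-diffuse (degenerate)
    series is entirely regime 1: boundaries (n, n).
    """
    n = len(traj.times_min)
    if fit.degenerate:
        return RegimeSegmentation((n, n), n)
    curve = fit(traj.times_min)
    lo = fit.baseline + low_frac * fit.amplitude
    hi = fit.baseline + high_frac * fit.amplitude
    above_lo = np.nonzero(curve > lo)[0]
    above_hi = np.nonzero(curve > hi)[0]
    b1 = int(above_lo[0]) if above_lo.size else n
    b2 = int(above_hi[0]) if above_hi.size else n
    return RegimeSegmentation((b1, max(b1, b2)), n)


def mass_area_trajectory(
    predictions: list[PredictionImage],
    phase_images: list[PhaseImage],
    frame_interval_min: float = 2.0,
    mask_method: str = "fixed",
    mask_level: float = 0.5,
    min_area_um2: float = 0.0,
) -> pd.DataFrame:
    """Per-frame aggregate dry mass (pg) and area (um^2) from predictions.

    Each frame's prediction is thresholded into a mask (fixed 0.5 cut
    by default, so pre-onset frames with no aggregate give empty
    masks); the mask area and the mask-integrated dry-mass density of
    the co-registered phase image are recorded.  Empty masks yield
    (0, 0).
    """
    if len(predictions) != len(phase_images):
        raise ValueError("need one phase image per prediction")
    rows = []
    for i, (pred, phase) in enumerate(zip(predictions, phase_images)):
        if pred.values.shape != phase.values.shape:
            raise ValueError(f"frame {i}: prediction and phase are misaligned")
        mask = prediction_mask(pred, method=mask_method, level=mask_level)
        pa = phase.optics.pixel_area_um2
        area = float(mask.sum() * pa)
        if area < min_area_um2:
            mask = np.zeros_like(mask)
            area = 0.0
        if mask.any():
            mass = aggregate_dry_mass(dry_mass_density_map(phase), mask)
        else:
            mass = 0.0
        rows.append({"frame": i, "time_min": i * frame_interval_min,
                     "area_um2": area, "dry_mass_pg": mass})
    return pd.DataFrame(rows)
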