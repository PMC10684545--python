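"""Validation metrics and the robustness / dataset-size experiments.

Per-image agreement between network output and fluorescence ground
truth is scored with the Pearson correlation (full-image and restricted
to aggregate regions), a normalized MSE, SSIM and binary overlap
metrics (Jaccard, Dice, pixelwise F1).  On top sit two simulation
experiments: a phase-noise robustness sweep (with an optional median /
Gaussian pre-filter on the input) and a subsampling study of how the
spread of aggregate morphology statistics converges with dataset size.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "MetricReport",
    "SubsampleCurve",
    "RobustnessResult",
    "pearson_r",
    "nmse",
    "overlap_metrics",
    "ssim",
    "intensity_sum_correlation",
    "noise_robustness_experiment",
    "subsample_convergence",
    "score_pair",
]


@dataclass
class MetricReport:
    """Per-image validation record."""

    pearson_full: float = math.nan
    pearson_roi: float = math.nan
    nmse_full: float = math.nan
    nmse_roi: float = math.nan
    ssim: float = math.nan
    jaccard: float = math.nan
    dice: float = math.nan
    f1: float = math.nan
    image_id: str = ""

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SubsampleCurve:
    """Mean |subsample std - population std| per sampled fraction."""

    fractions: list[float]
    discrepancy_area: list[float]
    discrepancy_circularity: list[float]
    n_repeats: int
    seed: int


@dataclass
class RobustnessResult:
    """Noise-sweep table: one row per (variance, prefilter, region)."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def mean_r(self, variance: float, prefilter: bool) -> float:
        sel = self.table[(self.table.variance == variance)
                         & (self.table.prefilter == prefilter)]
        return float(sel.pearson_full.mean())


def _in_scope(pred, truth, mask):
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes must match")
    if mask is None:
        return pred.ravel(), truth.ravel()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pred.shape:
        raise ValueError("mask shape must match the images")
    return pred[mask], truth[mask]


def pearson_r(pred, truth, mask=None) -> float:
    """Product-moment correlation over in-scope pixels.

    Returns NaN (an explicit not-a-value) when either side has zero
    variance in scope.
    """
    p, t = _in_scope(pred, truth, mask)
    if p.size < 2:
        raise ValueError("need at least 2 pixels in scope")
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        return math.nan
    return float(stats.pearsonr(p, t).statistic)


def nmse(pred, truth, mask=None, convention: str = "sum_of_squares") -> float:
    """Squared error normalized by the label's magnitude.

    ``sum_of_squares`` (default): sum((pred-truth)^2) / sum(truth^2) —
    dimensionally consistent, size-independent.  ``square_of_sum``
    divides by (sum(truth))^2 instead, which scales with image size and
    is kept only as an alternative reading of the normalization.
    """
    p, t = _in_scope(pred, truth, mask)
    err = float(np.sum((p - t) ** 2))
    if convention == "sum_of_squares":
        denom = float(np.sum(t ** 2))
    elif convention == "square_of_sum":
        denom = float(np.sum(t)) ** 2
    else:
        raise ValueError("unknown NMSE convention")
    if denom == 0:
        raise ValueError("all-zero truth: NMSE undefined")
    return err / denom


def overlap_metrics(mask_a, mask_b):
    """(Jaccard, Dice, pixelwise F1) between two binary masks.

    F1 treats ``mask_b`` as the truth; for binary masks it coincides
    with the Dice coefficient, which is asserted.  Two empty masks are
    defined as perfect agreement (1) with a warning.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share shape")
    inter = int((a & b).sum())
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        warnings.warn("both masks empty: overlap defined as 1", stacklevel=2)
        return 1.0, 1.0, 1.0
    union = na + nb - inter
    jaccard = inter / union if union else 0.0
    dice = 2 * inter / (na + nb)
    tp, fp, fn = inter, na - inter, nb - inter
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    assert abs(f1 - dice) < 1e-12
    return float(jaccard), float(dice), float(f1)


def _gaussian_kernel1d(win: int, sigma: float) -> np.ndarray:
    r = (win - 1) / 2
    x = np.arange(win) - r
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def ssim(pred, truth, win_size: int = 7, sigma: float = 1.5,
         k1: float = 0.01, k2: float = 0.03, data_range: float = 1.0) -> float:
    """Mean structural similarity with a Gaussian-weighted window.

    Local means, variances and covariance are kernel-weighted moments
    over a ``win_size`` Gaussian window (sigma 1.5); the mean is taken
    over the interior (a (win-1)/2 border is cropped).  Designed for
    images already normalized to [0, 1] (data_range 1).
    """
    x = np.asarray(pred, dtype=float)
    y = np.asarray(truth, dtype=float)
    if x.shape != y.shape:
        raise ValueError("images must share shape")
    k = _gaussian_kernel1d(win_size, sigma)

    def smooth(im):
        out = ndimage.correlate1d(im, k, axis=0, mode="nearest")
        return ndimage.correlate1d(out, k, axis=1, mode="nearest")

    ux, uy = smooth(x), smooth(y)
    uxx, uyy, uxy = smooth(x * x), smooth(y * y), smooth(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cxy = uxy - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * cxy + c2)) / (
        (ux ** 2 + uy ** 2 + c1) * (vx + vy + c2))
    pad = (win_size - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def intensity_sum_correlation(pred, truth, truth_mask) -> float:
    """Correlation of per-aggregate total intensity, prediction vs truth.

    Aggregates are the 8-connected components of the truth mask; each
    contributes its summed pixel intensity in both images.  Requires at
    least 3 aggregates for a meaningful correlation.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    mask = np.asarray(truth_mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n < 3:
        raise ValueError("need >= 3 aggregates for an intensity-sum correlation")
    idx = np.arange(1, n + 1)
    sums_p = ndimage.sum_labels(pred, labels, idx)
    sums_t = ndimage.sum_labels(truth, labels, idx)
    return pearson_r(sums_p, sums_t)


def score_pair(pred, truth, truth_mask=None, pred_mask=None,
               image_id: str = "") -> MetricReport:
    """Full per-image report against the fluorescence ground truth."""
    rep = MetricReport(image_id=image_id)
    rep.pearson_full = pearson_r(pred, truth)
    rep.nmse_full = nmse(pred, truth)
    rep.ssim = ssim(pred, truth)
    if truth_mask is not None and np.asarray(truth_mask).any():
        rep.pearson_roi = pearson_r(pred, truth, truth_mask)
        rep.nmse_roi = nmse(pred, truth, truth_mask)
        if pred_mask is not None:
            j, d, f = overlap_metrics(pred_mask, truth_mask)
            rep.jaccard, rep.dice, rep.f1 = j, d, f
    return rep


def prefilter_input(image: np.ndarray, method: str = "median",
                    size: int = 3) -> np.ndarray:
    """The 'simple pre-filtering step' applied before prediction."""
    if method == "median":
        return ndimage.median_filter(image, size=size)
    if method == "gaussian":
        return ndimage.gaussian_filter(image, sigma=size / 3.0)
    raise ValueError("prefilter must be 'median' or 'gaussian'")


def noise_robustness_experiment(
    predict_fn,
    scenes,
    variances,
    prefilter: bool = False,
    region: str = "global",
    filter_method: str = "median",
    filter_size: int = 3,
    seed: int = 0,
) -> RobustnessResult:
    """Score predictions across increasing phase-noise variances.

    For each variance, Gaussian noise is injected into every scene's
    phase map (globally or inside aggregates only), optionally passed
    through the pre-filter, predicted with ``predict_fn`` (raw phase
    map in rad -> prediction array in [0, 1]; the callable owns its
    input normalization) and scored against the clean fluorescence
    label.  The variance-0 rows reproduce the clean-scene scores
    exactly.
    """
    from .prep import normalize_minmax
    from .simulate import NoiseSpec, add_phase_noise, render_fluorescence

    variances = list(variances)
    if sorted(variances) != variances:
        raise ValueError("variances must be sorted ascending")

    rows = []
    for si, scene in enumerate(scenes):
        label = normalize_minmax(render_fluorescence(
            scene, NoiseSpec(fluor_photon_scale=1e5, seed=seed + si)))
        for var in variances:
            nspec = NoiseSpec(phase_noise_variance_rad2=var, region=region,
                              seed=seed + 1000 * si + int(var * 1e6) % 997)
            noisy = add_phase_noise(scene.phase_map, nspec,
                                    aggregate_mask=scene.aggregate_mask)
            if prefilter and var > 0:
                noisy = prefilter_input(noisy, filter_method, filter_size)
            pred = predict_fn(noisy)
            rep = score_pair(pred, label, truth_mask=scene.aggregate_mask)
            row = rep.to_dict()
            row.update(variance=var, prefilter=prefilter, region=region,
                       scene_index=si)
            rows.append(row)
    return RobustnessResult(pd.DataFrame(rows))


def subsample_convergence(
    records: pd.DataFrame,
    fractions,
    n_repeats: int = 10_000,
    seed: int = 0,
) -> SubsampleCurve:
    """How aggregate-morphology spread converges with dataset size.

    For each fraction f, draws ``n_repeats`` without-replacement
    subsamples of round(f * n) records and averages the absolute
    deviation of the subsample standard deviation (area and
    circularity, ddof=1) from the full-set standard deviation.
    Fraction 1.0 gives exactly zero.  Fractions leaving fewer than two
    records are skipped with a warning.
    """
    if not {"area_um2", "circularity"} <= set(records.columns):
        raise ValueError("records need 'area_um2' and 'circularity' columns")
    fractions = sorted(set(float(f) for f in fractions))
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    area = records["area_um2"].to_numpy(dtype=float)
    circ = records["circularity"].to_numpy(dtype=float)
    n = area.size
    full_sd_a = np.std(area, ddof=1)
    full_sd_c = np.std(circ, ddof=1)

    rng = np.random.default_rng(seed)
    out_f, out_a, out_c = [], [], []
    for f in fractions:
        k = int(round(f * n))
        if k < 2:
            warnings.warn(f"fraction {f} leaves <2 records; skipped", stacklevel=2)
            continue
        if k == n:
            out_f.append(f)
            out_a.append(0.0)
            out_c.append(0.0)
            continue
        da = dc = 0.0
        for _ in range(n_repeats):
            idx = rng.choice(n, size=k, replace=False)
            da += abs(np.std(area[idx], ddof=1) - full_sd_a)
            dc += abs(np.std(circ[idx], ddof=1) - full_sd_c)
        out_f.append(f)
        out_a.append(da / n_repeats)
        out_c.append(dc / n_repeats)
    return SubsampleCurve(out_f, out_a, out_c, n_repeats, seed)


def enumerate_subsample_discrepancy(values: np.ndarray, k: int) -> float:
    """Exhaustive mean |subset std - full std| over all C(n, k) subsets.

    Brute-force companion of :func:`subsample_convergence` for tiny
    record sets.
    """
    values = np.asarray(values, dtype=float)
    full_sd = np.std(values, ddof=1)
    devs = [abs(np.std(values[list(c)], ddof=1) - full_sd)
            for c in itertools.combinations(range(values.size), k)]
    return float(np.mean(devs))
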