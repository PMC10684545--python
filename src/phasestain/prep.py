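"""Data preparation: registration, projection, labels, tiles, splits.

Raw paired stacks become training-ready tensors here: planes are
co-registered to the central plane, fluorescence labels are built as
maximum z-projections, classification labels derive from them by Otsu
thresholding, images are min-max normalized to [0, 1] and cropped to
the network's input size, and acquisitions are split into
test/validation/train sets (10% test, then 20% of the remainder for
validation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import fourier_shift
from skimage.registration import phase_cross_correlation

from .qpi import PlaneStack

__all__ = [
    "SamplePair",
    "DatasetSplit",
    "register_planes",
    "max_z_projection",
    "otsu_threshold",
    "otsu_mask",
    "normalize_minmax",
    "crop_tiles",
    "split_dataset",
    "select_planes",
]

#: 1-based plane picks from an 8-plane stack, symmetric about the center.
PLANE_SUBSETS = {1: (4,), 2: (4, 5), 4: (2, 4, 5, 7), 8: tuple(range(1, 9))}


@dataclass
class SamplePair:
    """One training pair: label-free input stack plus fluorescence label."""

    input_stack: PlaneStack
    label_image: np.ndarray
    label_mask: np.ndarray | None = None
    acquisition_id: str = ""
    construct_tag: str = ""
    seed_lineage: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.label_image = np.asarray(self.label_image, dtype=float)
        if self.label_image.shape != self.input_stack.frame_shape:
            raise ValueError("input and label pixel grids must be identical")
        if self.label_image.min() < 0 or self.label_image.max() > 1:
            raise ValueError("label image must be normalized to [0, 1]")
        if self.label_mask is None:
            _, self.label_mask = otsu_mask(self.label_image)
        self.label_mask = np.asarray(self.label_mask, dtype=bool)


@dataclass(frozen=True)
class DatasetSplit:
    test_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    train_ids: tuple[str, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        sets = [set(self.test_ids), set(self.val_ids), set(self.train_ids)]
        total = sum(len(s) for s in sets)
        if len(set.union(*sets)) != total:
            raise ValueError("split id sets must be disjoint")

    @property
    def all_ids(self) -> set[str]:
        return set(self.test_ids) | set(self.val_ids) | set(self.train_ids)


def register_planes(stack: PlaneStack, upsample_factor: int = 20):
    """Align every plane to the central plane by translation.

    Shift estimation uses phase correlation with sub-pixel refinement;
    alignment applies the (negated) shift through a Fourier shift.
    A featureless (zero-variance) plane gets zero shift with a warning.

    Returns the registered stack and the per-plane (dy, dx) shifts that
    were detected.
    """
    if stack.n_planes < 2:
        raise ValueError("registration needs >= 2 planes")
    ref_idx = stack.n_planes // 2
    ref = stack.planes[ref_idx]
    registered = np.empty_like(stack.planes)
    shifts = np.zeros((stack.n_planes, 2))
    for j, plane in enumerate(stack.planes):
        if j == ref_idx:
            registered[j] = plane
            continue
        if np.ptp(plane) == 0 or np.ptp(ref) == 0:
            warnings.warn(f"plane {j}: featureless image, assuming zero shift",
                          stacklevel=2)
            registered[j] = plane
            continue
        shift, _err, _phase = phase_cross_correlation(
            ref, plane, upsample_factor=upsample_factor, normalization=None)
        shifts[j] = shift
        registered[j] = np.real(np.fft.ifft2(
            fourier_shift(np.fft.fft2(plane), shift)))
    out = PlaneStack(registered, stack.optics, modality=stack.modality)
    return out, shifts


def max_z_projection(stack: PlaneStack | np.ndarray) -> np.ndarray:
    """Per-pixel maximum across the stack's planes."""
    planes = stack.planes if isinstance(stack, PlaneStack) else np.asarray(stack)
    if planes.ndim == 2:
        return planes.copy()
    if planes.shape[0] < 1:
        raise ValueError("projection needs at least one plane")
    return planes.max(axis=0)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold on a fixed-bin histogram.

    The histogram spans [min, max] with ``nbins`` bins; the returned
    threshold is the bin edge that maximizes the between-class variance
    (ties go to the lowest edge).  Raises on a constant image.
    """
    image = np.asarray(image, dtype=float).ravel()
    lo, hi = image.min(), image.max()
    if lo == hi:
        raise ValueError("degenerate histogram: image is constant")
    counts, edges = np.histogram(image, bins=nbins, range=(lo, hi))
    p = counts / counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_t * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    between[~np.isfinite(between)] = -np.inf
    k = int(np.argmax(between[:-1]))  # split after bin k
    return float(edges[k + 1])


def otsu_mask(image: np.ndarray, nbins: int = 256):
    """(threshold, image > threshold) by Otsu's method."""
    t = otsu_threshold(image, nbins=nbins)
    return t, np.asarray(image, dtype=float) > t


def normalize_minmax(image: np.ndarray) -> np.ndarray:
    """Rescale an image to [0, 1]; a constant image maps to zeros (warned)."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        warnings.warn("constant image: min-max normalization returns zeros",
                      stacklevel=2)
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def crop_tiles(
    image: np.ndarray,
    size: int = 352,
    mode: str = "center",
    overlap: int = 0,
) -> list[np.ndarray]:
    """Crop 2-D images or (z, y, x) stacks to ``size`` x ``size`` tiles.

    ``center`` mode returns a single centered crop; ``grid`` mode tiles
    the field with the stated overlap, adding edge-flush tiles so the
    full image is covered.  Images smaller than ``size`` are an error
    (pad upstream if needed).
    """
    image = np.asarray(image)
    h, w = image.shape[-2:]
    if h < size or w < size:
        raise ValueError(
            f"image ({h}x{w}) smaller than tile size {size}; pad it first")
    if mode == "center":
        y0 = (h - size) // 2
        x0 = (w - size) // 2
        return [image[..., y0:y0 + size, x0:x0 + size].copy()]
    if mode != "grid":
        raise ValueError("mode must be 'center' or 'grid'")
    step = size - overlap
    if step <= 0:
        raise ValueError("overlap must be smaller than the tile size")
    ys = list(range(0, h - size + 1, step))
    if ys[-1] != h - size:
        ys.append(h - size)
    xs = list(range(0, w - size + 1, step))
    if xs[-1] != w - size:
        xs.append(w - size)
    return [image[..., y:y + size, x:x + size].copy() for y in ys for x in xs]


def grid_tile_count(extent: int, size: int, overlap: int) -> int:
    """Closed-form number of grid positions along one axis."""
    step = size - overlap
    n = int(np.ceil((extent - size) / step)) + 1 if extent > size else 1
    return n


def split_dataset(
    ids: list[str],
    seed: int = 0,
    construct_tags: dict[str, str] | None = None,
) -> DatasetSplit:
    """Shuffle acquisitions into test (10%), validation (20% of the rest) and train.

    Splitting operates on acquisition ids, so all frames of one
    time-lapse acquisition land on the same side of every boundary.
    With ``construct_tags`` the draw is stratified per tag.
    """
    ids = list(ids)
    n = len(ids)
    if n < 10:
        raise ValueError("need at least 10 acquisitions to split")
    if len(set(ids)) != n:
        raise ValueError("ids must be unique")

    rng = np.random.default_rng(seed)
    n_test = int(round(0.10 * n))
    n_val = int(round(0.20 * (n - n_test)))

    if construct_tags:
        groups: dict[str, list[str]] = {}
        for i in ids:
            groups.setdefault(construct_tags.get(i, ""), []).append(i)
        order: list[str] = []
        # interleave shuffled strata so fraction cuts stay stratified
        shuffled = {t: [g[k] for k in rng.permutation(len(g))]
                    for t, g in sorted(groups.items())}
        while any(shuffled.values()):
            for t in sorted(shuffled):
                if shuffled[t]:
                    order.append(shuffled[t].pop())
    else:
        order = [ids[k] for k in rng.permutation(n)]

    test = tuple(order[:n_test])
    val = tuple(order[n_test:n_test + n_val])
    train = tuple(order[n_test + n_val:])
    return DatasetSplit(test, val, train, seed=seed)


def select_planes(stack: PlaneStack, n_planes: int) -> PlaneStack:
    """Pick a 1/2/4-plane subset from an 8-plane stack, symmetric about center."""
    if n_planes not in PLANE_SUBSETS:
        raise ValueError(f"unsupported plane count {n_planes}")
    if stack.n_planes != 8 and n_planes != stack.n_planes:
        raise ValueError("plane selection expects an 8-plane source stack")
    picks = [p - 1 for p in PLANE_SUBSETS[n_planes]]
    return PlaneStack(stack.planes[picks],
                      stack.optics.with_planes(n_planes),
                      modality=stack.modality)
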