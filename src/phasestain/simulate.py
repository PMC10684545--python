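"""Synthetic specimens and a coherent microscope forward model.

Scenes emulate adherent cells carrying compact, high-phase protein
aggregates: smooth elliptical cell bodies with optical phase drawn from
a low interval, and aggregates drawn from a strictly higher interval,
optionally with a two-level core/shell radial profile.  Fluorophore
density is concentrated in aggregates on top of a diffuse background,
mimicking a GFP fusion readout.  Rendering covers a widefield
fluorescence channel with shot noise and a multi-plane brightfield
defocus stack (thin phase object propagated by the angular spectrum to
each plane), so the full phase-retrieval -> virtual-staining ->
quantification pipeline is exercisable without any external data.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .qpi import OpticalConfig, PhaseImage, PlaneStack, plane_offsets

__all__ = [
    "SceneSpec",
    "Scene",
    "NoiseSpec",
    "TimeLapseSpec",
    "AggregateTruth",
    "generate_scene",
    "generate_timelapse",
    "chimerize",
    "render_fluorescence",
    "render_brightfield_stack",
    "add_phase_noise",
]

_PLACEMENT_RETRIES = 500


@dataclass(frozen=True)
class AggregateTruth:
    """Ground truth for one synthetic aggregate."""

    centroid_px: tuple[float, float]
    area_um2: float
    mean_phase_rad: float
    fluor_amplitude: float = 1.0


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic field of view.

    Phase intervals are absolute levels in rad; the aggregate interval
    must sit strictly above the cell interval so that aggregate pixels
    always rise above the cell background.  ``diffuse_fluor_fraction``
    is the fraction of total fluorophore residing outside aggregates
    (diffuse pool); ``boundary_sigma_px`` is the Gaussian blur applied
    to the phase map, standing in for the diffraction-limited transfer
    of the optics.
    """

    field_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.111
    n_cells: int = 3
    cell_phase_range_rad: tuple[float, float] = (0.3, 0.8)
    n_aggregates: int = 2
    aggregate_area_range_um2: tuple[float, float] = (3.0, 30.0)
    aggregate_phase_range_rad: tuple[float, float] = (1.2, 2.0)
    core_shell: bool = False
    diffuse_fluor_fraction: float = 0.10
    diffuse_floor: float = 0.05
    boundary_sigma_px: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size_px
        if h < 16 or w < 16:
            raise ValueError("field must be at least 16 x 16 px")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.n_cells < 0 or self.n_aggregates < 0:
            raise ValueError("counts must be non-negative")
        for name in ("cell_phase_range_rad", "aggregate_phase_range_rad",
                     "aggregate_area_range_um2"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a finite non-negative interval")
        if self.n_aggregates and self.aggregate_phase_range_rad[0] <= self.cell_phase_range_rad[1]:
            raise ValueError("aggregate phase interval must lie strictly above the cell interval")
        if self.aggregate_area_range_um2[0] < 3 * self.pixel_area_um2:
            raise ValueError("aggregate area lower bound must cover at least 3 pixels")
        if not 0.0 <= self.diffuse_fluor_fraction < 0.5:
            raise ValueError("diffuse_fluor_fraction must be in [0, 0.5)")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um ** 2


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: Gaussian phase noise plus Poisson shot noise."""

    phase_noise_variance_rad2: float = 0.0
    region: str = "global"
    fluor_photon_scale: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase_noise_variance_rad2 < 0:
            raise ValueError("phase noise variance must be >= 0")
        if self.fluor_photon_scale <= 0:
            raise ValueError("photon scale must be > 0")
        if self.region not in ("global", "aggregate_only"):
            raise ValueError("region must be 'global' or 'aggregate_only'")


@dataclass(frozen=True)
class TimeLapseSpec:
    """Sigmoidal single-aggregate growth over a time-lapse series.

    The aggregate area follows a logistic curve with plateau
    ``final_area_um2``; frames before ``onset_frame`` contain only
    diffuse fluorophore.  Default 2-min frame interval matches typical
    live-cell acquisition of aggregate formation.
    """

    n_frames: int = 60
    frame_interval_min: float = 2.0
    onset_frame: int = 10
    growth_rate: float = 0.15  # logistic steepness, 1/min
    final_area_um2: float = 20.0
    drift_px_per_frame: float = 0.05

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("a time lapse needs >= 3 frames to express three regimes")
        if not 0 <= self.onset_frame < self.n_frames:
            raise ValueError("onset_frame must satisfy 0 <= onset < n_frames")
        if self.frame_interval_min <= 0 or self.growth_rate <= 0:
            raise ValueError("frame interval and growth rate must be positive")
        if self.final_area_um2 <= 0:
            raise ValueError("final area must be positive")


@dataclass
class Scene:
    """Synthetic ground truth: phase, aggregate mask, fluorophore density."""

    phase_map: np.ndarray
    aggregate_mask: np.ndarray
    fluor_density: np.ndarray
    per_aggregate_truth: list[AggregateTruth]
    spec: SceneSpec
    cell_phase_integral: float = 0.0  # rad*px contributed by cells (pre-blur)

    def __post_init__(self) -> None:
        if not (self.phase_map.shape == self.aggregate_mask.shape == self.fluor_density.shape):
            raise ValueError("phase, mask and fluorescence shapes must agree")

    @property
    def shape(self):
        return self.phase_map.shape

    def phase_image(self, optics: OpticalConfig | None = None) -> PhaseImage:
        optics = optics or OpticalConfig(pixel_size_um=self.spec.pixel_size_um)
        return PhaseImage(self.phase_map.copy(), optics)


# --------------------------------------------------------------------------
# geometry helpers

def _ellipse_q(shape, center, axes, theta):
    """Normalized squared elliptical radius over the full field."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2


def _rasterize_exact(shape, center, axis_ratio, theta, n_px):
    """Elliptical footprint with exactly ``n_px`` pixels.

    Pixels are ranked by their elliptical quadratic form and the
    ``n_px`` innermost are taken, so the truth area is exact to the
    pixel grid.
    """
    # semi-axes from target count: pi*a*b = n_px with b = a/ratio
    a = np.sqrt(n_px * axis_ratio / np.pi)
    b = a / axis_ratio
    q = _ellipse_q(shape, center, (a, b), theta)
    flat = np.argsort(q, axis=None, kind="stable")[:n_px]
    mask = np.zeros(shape, dtype=bool)
    mask.ravel()[flat] = True
    return mask, q


def _place_cells(spec: SceneSpec, rng: np.random.Generator):
    h, w = spec.field_size_px
    base = np.zeros((h, w))
    cells = []
    scale = min(h, w)
    for _ in range(spec.n_cells):
        cy = rng.uniform(0.2 * h, 0.8 * h)
        cx = rng.uniform(0.2 * w, 0.8 * w)
        a = rng.uniform(0.25, 0.45) * scale
        b = rng.uniform(0.22, 0.40) * scale
        theta = rng.uniform(0, np.pi)
        level = rng.uniform(*spec.cell_phase_range_rad)
        q = _ellipse_q((h, w), (cy, cx), (a, b), theta)
        base = np.maximum(base, level * (q < 1.0))
        cells.append(((cy, cx), (a, b), theta))
    return base, cells


def generate_scene(spec: SceneSpec) -> Scene:
    """Draw one synthetic specimen.

    Deterministic given ``spec.seed``.  Raises if the requested
    aggregates cannot be packed without overlap (infeasible packing is
    an error, never a silent truncation).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    pa = spec.pixel_area_um2

    cell_base, cells = _place_cells(spec, rng)

    agg_mask = np.zeros((h, w), dtype=bool)
    agg_phase = np.zeros((h, w))
    fluor_amp = np.zeros((h, w))
    truths: list[AggregateTruth] = []

    for _ in range(spec.n_aggregates):
        if not cells:
            raise ValueError("cannot place aggregates in a scene with no cells")
        placed = False
        for _attempt in range(_PLACEMENT_RETRIES):
            area = rng.uniform(*spec.aggregate_area_range_um2)
            n_px = max(int(round(area / pa)), 3)
            (cy, cx), (a, b), ctheta = cells[rng.integers(len(cells))]
            # sample a point well inside the chosen cell
            rr = np.sqrt(rng.uniform()) * 0.7
            ang = rng.uniform(0, 2 * np.pi)
            du, dv = rr * b * np.cos(ang), rr * a * np.sin(ang)
            ay = cy + du * np.sin(ctheta) + dv * np.cos(ctheta)
            ax = cx + du * np.cos(ctheta) - dv * np.sin(ctheta)
            ratio = rng.uniform(1.0, 1.8)
            theta = rng.uniform(0, np.pi)
            radius = np.sqrt(n_px * ratio / np.pi)
            if not (radius < ay < h - radius and radius < ax < w - radius):
                continue
            mask, q = _rasterize_exact((h, w), (ay, ax), ratio, theta, n_px)
            if (mask & agg_mask).any():
                continue
            level = rng.uniform(*spec.aggregate_phase_range_rad)
            profile = np.where(mask, level, 0.0)
            if spec.core_shell:
                # innermost 30% of pixels carry an elevated core level
                n_core = max(int(round(0.3 * n_px)), 1)
                core = np.zeros_like(mask)
                core.ravel()[np.argsort(q, axis=None, kind="stable")[:n_core]] = True
                core &= mask
                hi = min(level * 1.3, spec.aggregate_phase_range_rad[1])
                profile = np.where(core, hi, profile)
            amp = rng.uniform(0.7, 1.3)
            agg_phase = np.where(mask, profile, agg_phase)
            fluor_amp = np.where(mask, amp, fluor_amp)
            agg_mask |= mask
            ys, xs = np.nonzero(mask)
            truths.append(AggregateTruth(
                centroid_px=(float(ys.mean()), float(xs.mean())),
                area_um2=n_px * pa,
                mean_phase_rad=float(profile[mask].mean()),
                fluor_amplitude=float(amp),
            ))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"infeasible packing: could not place aggregate after "
                f"{_PLACEMENT_RETRIES} attempts"
            )

    phase = np.where(agg_mask, agg_phase, cell_base)
    cell_integral = float(phase[~agg_mask].sum())
    if spec.boundary_sigma_px > 0:
        phase = gaussian_filter(phase, spec.boundary_sigma_px, mode="reflect")

    fluor = _fluor_density(spec, agg_mask, fluor_amp)

    return Scene(phase, agg_mask, fluor, truths, spec, cell_integral)


def _fluor_density(spec: SceneSpec, agg_mask: np.ndarray, fluor_amp: np.ndarray) -> np.ndarray:
    """Diffuse pool plus aggregate-bound fluorophore.

    The diffuse level is solved so that the stated fraction of total
    fluorophore lies outside aggregates; without aggregates the density
    is the flat ``diffuse_floor``.
    """
    n_in = int(agg_mask.sum())
    n_out = agg_mask.size - n_in
    if n_in == 0:
        return np.full(agg_mask.shape, spec.diffuse_floor)
    f = spec.diffuse_fluor_fraction
    amp_sum = float(fluor_amp[agg_mask].sum())
    if f == 0.0:
        d = 0.0
    else:
        denom = n_out * (1.0 - f) - f * n_in
        if denom <= 0:
            raise ValueError("diffuse_fluor_fraction infeasible for this aggregate load")
        d = f * amp_sum / denom
    return d + np.where(agg_mask, fluor_amp, 0.0)


def generate_timelapse(spec: SceneSpec, tl: TimeLapseSpec) -> list[Scene]:
    """Render a growing-aggregate time lapse.

    One aggregate nucleates at ``onset_frame`` and its area follows a
    logistic curve with midpoint halfway between onset and the final
    frame, reaching ``final_area_um2`` at plateau.  Lateral drift is
    applied as a per-frame displacement of all scene coordinates, so the
    ground-truth masks stay exactly consistent with the rendered maps.
    """
    lo, hi = spec.aggregate_area_range_um2
    if not lo <= tl.final_area_um2 <= hi:
        raise ValueError("final_area_um2 must lie within the spec's aggregate area range")

    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    pa = spec.pixel_area_um2

    base_spec = replace(spec, n_aggregates=0)
    # fixed geometry for the whole series
    cell_rng = np.random.default_rng(rng.integers(2 ** 31))
    _, cells = _place_cells(spec, cell_rng)
    (cy, cx), (a, b), ctheta = cells[rng.integers(max(len(cells), 1))] if cells else ((h / 2, w / 2), (h / 4, w / 4), 0.0)
    ay = cy + rng.uniform(-0.2, 0.2) * a
    ax = cx + rng.uniform(-0.2, 0.2) * b
    ratio = rng.uniform(1.0, 1.5)
    theta = rng.uniform(0, np.pi)
    level = rng.uniform(*spec.aggregate_phase_range_rad)
    amp = rng.uniform(0.9, 1.1)
    drift_dir = rng.uniform(0, 2 * np.pi)
    dy = tl.drift_px_per_frame * np.sin(drift_dir)
    dx = tl.drift_px_per_frame * np.cos(drift_dir)

    t_onset = tl.onset_frame * tl.frame_interval_min
    t_last = (tl.n_frames - 1) * tl.frame_interval_min
    t_mid = 0.5 * (t_onset + t_last)

    frames: list[Scene] = []
    for i in range(tl.n_frames):
        shift = (i * dy, i * dx)
        # per-cell levels fixed across the series, geometry drifts
        lvl_rng = np.random.default_rng(spec.seed + 17)
        cell_base = np.zeros((h, w))
        for (ccy, ccx), (ca, cb), cth in cells:
            q = _ellipse_q((h, w), (ccy + shift[0], ccx + shift[1]), (ca, cb), cth)
            cell_base = np.maximum(cell_base, lvl_rng.uniform(*spec.cell_phase_range_rad) * (q < 1.0))

        t = i * tl.frame_interval_min
        if i < tl.onset_frame:
            area_i = 0.0
        else:
            area_i = tl.final_area_um2 / (1.0 + np.exp(-tl.growth_rate * (t - t_mid)))
        n_px = int(round(area_i / pa))

        agg_mask = np.zeros((h, w), dtype=bool)
        truths: list[AggregateTruth] = []
        phase = cell_base
        fluor_amp = np.zeros((h, w))
        if n_px >= 3:
            agg_mask, _ = _rasterize_exact(
                (h, w), (ay + shift[0], ax + shift[1]), ratio, theta, n_px)
            phase = np.where(agg_mask, level, cell_base)
            fluor_amp = np.where(agg_mask, amp, 0.0)
            ys, xs = np.nonzero(agg_mask)
            truths.append(AggregateTruth(
                centroid_px=(float(ys.mean()), float(xs.mean())),
                area_um2=n_px * pa,
                mean_phase_rad=level,
                fluor_amplitude=amp,
            ))
        cell_integral = float(phase[~agg_mask].sum())
        if spec.boundary_sigma_px > 0:
            phase = gaussian_filter(phase, spec.boundary_sigma_px, mode="reflect")
        fluor = _fluor_density(base_spec if not truths else spec, agg_mask, fluor_amp)
        frames.append(Scene(phase, agg_mask, fluor, truths, spec, cell_integral))
    return frames


def chimerize(scene: Scene, donor: Scene, fraction: float, seed: int = 0) -> Scene:
    """Replace a contiguous angular sector of each aggregate with donor background.

    Emulates heterogeneous, non-convex aggregates by splicing donor
    cell/background pixels (phase, fluorescence and mask) into the
    stated fraction of each aggregate's pixels.  The donor patch is
    resampled (translated) if it would bring in donor aggregate pixels;
    after bounded retries this is an error.
    """
    if scene.shape != donor.shape:
        raise ValueError("scene and donor must share geometry")
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")

    rng = np.random.default_rng(seed)
    phase = scene.phase_map.copy()
    fluor = scene.fluor_density.copy()
    mask = scene.aggregate_mask.copy()
    new_truths: list[AggregateTruth] = []
    pa = scene.spec.pixel_area_um2

    from scipy.ndimage import label as cc_label

    labels, n_comp = cc_label(mask, structure=np.ones((3, 3), dtype=int))
    for comp in range(1, n_comp + 1):
        ys, xs = np.nonzero(labels == comp)
        n = ys.size
        n_cut = int(round(fraction * n))
        old = _match_truth(scene.per_aggregate_truth, ys, xs)
        if n_cut == 0:
            new_truths.append(old)
            continue
        cy, cx = ys.mean(), xs.mean()
        ang = np.arctan2(ys - cy, xs - cx)
        theta0 = rng.uniform(0, 2 * np.pi)
        order = np.argsort((ang - theta0) % (2 * np.pi), kind="stable")
        cut = order[:n_cut]
        cys, cxs = ys[cut], xs[cut]

        donor_ok = False
        for _attempt in range(50):
            oy = int(rng.integers(scene.shape[0]))
            ox = int(rng.integers(scene.shape[1]))
            dmask = np.roll(np.roll(donor.aggregate_mask, oy, axis=0), ox, axis=1)
            if not dmask[cys, cxs].any():
                donor_ok = True
                break
        if not donor_ok:
            raise ValueError("could not find aggregate-free donor background after 50 retries")
        dphase = np.roll(np.roll(donor.phase_map, oy, axis=0), ox, axis=1)
        dfluor = np.roll(np.roll(donor.fluor_density, oy, axis=0), ox, axis=1)
        phase[cys, cxs] = dphase[cys, cxs]
        fluor[cys, cxs] = dfluor[cys, cxs]
        mask[cys, cxs] = False

        keep = order[n_cut:]
        kys, kxs = ys[keep], xs[keep]
        new_truths.append(AggregateTruth(
            centroid_px=(float(kys.mean()), float(kxs.mean())),
            area_um2=kys.size * pa,
            mean_phase_rad=old.mean_phase_rad,
            fluor_amplitude=old.fluor_amplitude,
        ))

    return Scene(phase, mask, fluor, new_truths, scene.spec, scene.cell_phase_integral)


def _match_truth(truths: Sequence[AggregateTruth], ys, xs) -> AggregateTruth:
    """Find the truth record whose centroid falls in this component."""
    cy, cx = ys.mean(), xs.mean()
    if not truths:
        return AggregateTruth((float(cy), float(cx)), 0.0, 0.0)
    dists = [np.hypot(t.centroid_px[0] - cy, t.centroid_px[1] - cx) for t in truths]
    return truths[int(np.argmin(dists))]


def render_fluorescence(scene: Scene, noise: NoiseSpec = NoiseSpec()) -> np.ndarray:
    """Widefield fluorescence image: shot noise around the density map.

    Pixel values are Poisson draws at ``fluor_photon_scale`` expected
    photons per unit density, rescaled back, so the expectation equals
    ``fluor_density`` and the relative noise shrinks as the scale grows.
    """
    rng = np.random.default_rng(noise.seed)
    lam = scene.fluor_density * noise.fluor_photon_scale
    return rng.poisson(lam).astype(float) / noise.fluor_photon_scale


def render_brightfield_stack(
    scene: Scene,
    optics: OpticalConfig | None = None,
    noise: NoiseSpec | None = None,
) -> PlaneStack:
    """Coherent defocus stack of the scene's phase map.

    The thin specimen imprints ``exp(i*phi)`` on a unit plane wave; the
    field is propagated to each plane offset with the (non-paraxial)
    angular-spectrum transfer function and the intensity is recorded.
    Evanescent components are cut.  At focus a weak phase object is
    nearly invisible; defocused planes gain contrast.  Optional shot
    noise uses ``noise.fluor_photon_scale`` as expected photons at unit
    intensity.
    """
    optics = optics or OpticalConfig(pixel_size_um=scene.spec.pixel_size_um)
    if optics.plane_spacing_um <= 0:
        raise ValueError("plane spacing must be positive")

    phi = scene.phase_map
    field0 = np.exp(1j * phi)
    fy = np.fft.fftfreq(phi.shape[0], optics.pixel_size_um)
    fx = np.fft.fftfreq(phi.shape[1], optics.pixel_size_um)
    lam = optics.wavelength_um
    arg = 1.0 - lam ** 2 * (fy[:, None] ** 2 + fx[None, :] ** 2)
    kz = 2.0 * np.pi / lam * np.sqrt(np.maximum(arg, 0.0))
    propagating = arg > 0

    spectrum = np.fft.fft2(field0)
    planes = np.empty((optics.n_planes,) + phi.shape)
    for j, z in enumerate(plane_offsets(optics)):
        transfer = np.where(propagating, np.exp(1j * kz * z), 0.0)
        planes[j] = np.abs(np.fft.ifft2(spectrum * transfer)) ** 2

    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        scale = noise.fluor_photon_scale
        planes = rng.poisson(planes * scale).astype(float) / scale

    return PlaneStack(planes, optics, modality="brightfield")


def add_phase_noise(
    phase: PhaseImage | np.ndarray,
    noise: NoiseSpec,
    aggregate_mask: np.ndarray | None = None,
) -> PhaseImage | np.ndarray:
    """Add zero-mean Gaussian noise of the stated variance to a phase map.

    With ``region='aggregate_only'`` noise lands only inside the given
    mask, emulating aggregates of degraded optical quality; pixels
    outside are untouched bit-exactly.
    """
    values = phase.values if isinstance(phase, PhaseImage) else np.asarray(phase, dtype=float)
    if noise.phase_noise_variance_rad2 == 0.0:
        out = values.copy()
    else:
        rng = np.random.default_rng(noise.seed)
        sigma = np.sqrt(noise.phase_noise_variance_rad2)
        if noise.region == "aggregate_only":
            if aggregate_mask is None:
                raise ValueError("aggregate_only noise requires an aggregate mask")
            aggregate_mask = np.asarray(aggregate_mask, dtype=bool)
            out = values.copy()
            out[aggregate_mask] = out[aggregate_mask] + rng.normal(
                0.0, sigma, size=int(aggregate_mask.sum()))
        else:
            out = values + rng.normal(0.0, sigma, size=values.shape)
    if isinstance(phase, PhaseImage):
        return PhaseImage(out, phase.optics)
    return out
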