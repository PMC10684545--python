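"""Ready-made synthetic datasets for training and evaluation.

Builds pixel-registered pairs of label-free inputs (phase maps or
brightfield planes) and normalized fluorescence labels from the scene
generator, at a desk-friendly field size (96 px, divisible by the
U-Net's 2^4 downsampling).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .prep import SamplePair, normalize_minmax, select_planes
from .qpi import OpticalConfig, PlaneStack
from .simulate import NoiseSpec, SceneSpec, Scene, generate_scene, render_brightfield_stack, render_fluorescence

__all__ = ["default_training_spec", "make_scene_variant",
           "make_virtual_staining_pairs", "scene_to_pair"]


def default_training_spec(field: int = 96, seed: int = 0) -> SceneSpec:
    """Scene recipe used for desk-scale training runs."""
    return SceneSpec(
        field_size_px=(field, field),
        n_cells=2,
        n_aggregates=2,
        aggregate_area_range_um2=(3.0, 8.0),
        seed=seed,
    )


def make_scene_variant(template: SceneSpec, seed: int,
                       rng: np.random.Generator) -> Scene:
    """One scene from the template with a jittered aggregate count.

    Counts are drawn uniformly from 0-3: like a scanned acquisition,
    a fraction of training fields contains no aggregate at all, which
    teaches the model that a bright *cell* stretched to 1.0 by
    per-image normalization is not an aggregate.  A draw whose random
    cell layout cannot host the requested aggregates is redrawn with a
    fresh seed (deterministically from ``rng``); the returned scene
    always carries its full aggregate count.
    """
    n_agg = int(rng.integers(0, 4))
    for _ in range(20):
        try:
            return generate_scene(replace(template, n_aggregates=n_agg,
                                          seed=seed))
        except ValueError:
            seed = int(rng.integers(2 ** 31))
    raise ValueError("could not draw a feasible scene in 20 attempts")


#: Calibration constant for phase inputs, in rad.  Quantitative phase
#: carries absolute units; dividing by a fixed full-scale value (the
#: top of the default aggregate interval) keeps the cytoplasm/aggregate
#: contrast intact across fields, which per-image min-max stretching
#: would destroy (see docs/methods.md).
PHASE_INPUT_SCALE_RAD = 2.0


def scene_to_pair(
    scene: Scene,
    in_planes: int = 1,
    input_modality: str = "phase",
    acquisition_id: str = "",
    label_noise_scale: float = 5000.0,
    label_seed: int = 0,
    phase_input_scale_rad: float = PHASE_INPUT_SCALE_RAD,
) -> SamplePair:
    """Render a scene into a normalized training pair.

    ``phase`` inputs are divided by the fixed calibration scale
    ``phase_input_scale_rad`` and clipped to [0, 1], replicated over
    the requested channel count; ``brightfield`` inputs are rendered
    defocus planes selected symmetrically from an 8-plane stack and
    min-max normalized per plane (intensity images carry no absolute
    scale).

    Labels are min-max normalized fluorescence renders.  A field whose
    rendered fluorescence shows no real contrast (peak-to-peak below
    its mean — pure diffuse background plus shot noise) gets an
    all-zero label: min-max stretching of shot noise would otherwise
    fabricate a bright label for a blank field.
    """
    optics = OpticalConfig(pixel_size_um=scene.spec.pixel_size_um,
                           n_planes=in_planes)
    if input_modality == "phase":
        phase = np.clip(scene.phase_map / phase_input_scale_rad,
                        0.0, 1.0).astype(np.float32)
        planes = np.repeat(phase[None], in_planes, axis=0)
        stack = PlaneStack(planes, optics, modality="phase")
    elif input_modality == "brightfield":
        full = render_brightfield_stack(
            scene, OpticalConfig(pixel_size_um=scene.spec.pixel_size_um))
        sub = select_planes(full, in_planes)
        planes = np.stack([normalize_minmax(p) for p in sub.planes])
        stack = PlaneStack(planes, optics, modality="brightfield")
    else:
        raise ValueError("input_modality must be 'phase' or 'brightfield'")
    rendered = render_fluorescence(
        scene, NoiseSpec(fluor_photon_scale=label_noise_scale, seed=label_seed))
    if np.ptp(rendered) < rendered.mean():
        # blank field: an all-zero label with an explicitly empty mask
        # (Otsu is undefined on a constant image)
        label = np.zeros_like(rendered)
        mask = np.zeros(label.shape, dtype=bool)
    else:
        label = normalize_minmax(rendered)
        mask = None  # SamplePair derives it by Otsu thresholding
    return SamplePair(stack, label, label_mask=mask,
                      acquisition_id=acquisition_id)


def make_virtual_staining_pairs(
    n_pairs: int = 200,
    seed: int = 0,
    template: SceneSpec | None = None,
    in_planes: int = 1,
    input_modality: str = "phase",
    return_scenes: bool = False,
):
    """A list of synthetic training pairs (and optionally their scenes)."""
    rng = np.random.default_rng(seed)
    template = template or default_training_spec()
    pairs, scenes = [], []
    for i in range(n_pairs):
        scene = make_scene_variant(template, seed=int(rng.integers(2 ** 31)),
                                   rng=rng)
        pair = scene_to_pair(scene, in_planes=in_planes,
                             input_modality=input_modality,
                             acquisition_id=f"acq_{i:04d}",
                             label_seed=int(rng.integers(2 ** 31)))
        pairs.append(pair)
        scenes.append(scene)
    if return_scenes:
        return pairs, scenes
    return pairs
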