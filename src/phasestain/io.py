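"""Reading and writing scenes, stacks and reports.

Stacks are stored as multi-page TIFF (planes as pages) next to a JSON
sidecar carrying the scene spec, seeds and per-aggregate ground truth;
aggregate records go to CSV and comparisons to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .qpi import OpticalConfig, PlaneStack
from .simulate import AggregateTruth, Scene, SceneSpec

__all__ = ["write_scene", "read_scene", "write_stack", "read_stack"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    return obj


def write_scene(scene: Scene, out_dir) -> Path:
    """Write phase/mask/fluorescence TIFFs plus a JSON truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "phase.tif", scene.phase_map.astype(np.float32))
    tifffile.imwrite(out / "aggregate_mask.tif",
                     scene.aggregate_mask.astype(np.uint8))
    tifffile.imwrite(out / "fluorescence.tif",
                     scene.fluor_density.astype(np.float32))
    sidecar = {
        "spec": _jsonable(scene.spec),
        "cell_phase_integral": scene.cell_phase_integral,
        "per_aggregate_truth": [_jsonable(t) for t in scene.per_aggregate_truth],
    }
    (out / "scene.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_scene(in_dir) -> Scene:
    src = Path(in_dir)
    sidecar = json.loads((src / "scene.json").read_text())
    spec_d = sidecar["spec"]
    spec_d["field_size_px"] = tuple(spec_d["field_size_px"])
    for key in ("cell_phase_range_rad", "aggregate_phase_range_rad",
                "aggregate_area_range_um2"):
        spec_d[key] = tuple(spec_d[key])
    truths = [AggregateTruth(centroid_px=tuple(t["centroid_px"]),
                             area_um2=t["area_um2"],
                             mean_phase_rad=t["mean_phase_rad"],
                             fluor_amplitude=t.get("fluor_amplitude", 1.0))
              for t in sidecar["per_aggregate_truth"]]
    return Scene(
        phase_map=tifffile.imread(src / "phase.tif").astype(float),
        aggregate_mask=tifffile.imread(src / "aggregate_mask.tif").astype(bool),
        fluor_density=tifffile.imread(src / "fluorescence.tif").astype(float),
        per_aggregate_truth=truths,
        spec=SceneSpec(**spec_d),
        cell_phase_integral=sidecar.get("cell_phase_integral", 0.0),
    )


def write_stack(stack: PlaneStack, path) -> Path:
    """Multi-page TIFF, one page per plane, plus an optics sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.planes.astype(np.float32))
    sidecar = {"optics": _jsonable(stack.optics), "modality": stack.modality}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_stack(path) -> PlaneStack:
    path = Path(path)
    planes = tifffile.imread(path).astype(float)
    if planes.ndim == 2:
        planes = planes[None]
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        optics = OpticalConfig(**sidecar["optics"])
        modality = sidecar.get("modality", "brightfield")
    else:
        optics = OpticalConfig(n_planes=planes.shape[0])
        modality = "brightfield"
    return PlaneStack(planes, optics, modality=modality)
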