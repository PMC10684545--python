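"""Per-aggregate morphology / dry-mass records and group statistics.

Segmentation masks (from network output or ground truth) are reduced to
one record per 8-connected component at or above a minimum area
(default 3 um^2, the smallest aggregates the virtual-staining approach
resolves): area, perimeter, circularity 4*pi*A/P^2, centroid and
integrated dry mass.  Populations of records grouped by protein
construct are compared with unpaired two-sided t-tests (Welch by
default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import measure

from .qpi import DryMassMap, OpticalConfig

__all__ = [
    "AggregateRecord",
    "ConstructComparison",
    "aggregate_records",
    "compare_constructs",
    "records_to_frame",
]


@dataclass(frozen=True)
class AggregateRecord:
    """Morphology and dry mass of one segmented aggregate."""

    id: str
    centroid_px: tuple[float, float]
    area_um2: float
    perimeter_um: float
    circularity: float
    dry_mass_pg: float
    construct_tag: str = ""
    fov_id: str = ""

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("area must be positive")
        if not 0 < self.circularity <= 1.05:
            raise ValueError("circularity outside (0, 1.05]")
        if not np.isfinite(self.dry_mass_pg):
            raise ValueError("dry mass must be finite")


@dataclass
class ConstructComparison:
    """Pairwise unpaired two-sided t-tests between construct groups."""

    groups: list[str]
    n: dict
    mean_pg: dict
    std_pg: dict
    t_stat: dict          # keyed by frozenset({a, b})
    p_value: dict
    flavor: str = "welch"

    def p(self, a: str, b: str) -> float:
        return self.p_value[frozenset((a, b))]

    def significance_band(self, a: str, b: str) -> str:
        p = self.p(a, b)
        for cut, band in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
            if p <= cut:
                return band
        return "ns"


def _component_perimeter(mask: np.ndarray, pixel_size_um: float) -> float:
    """Boundary length of a single component via marching-squares contours."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    length_px = 0.0
    for c in contours:
        length_px += float(np.sum(np.hypot(*np.diff(c, axis=0).T)))
    return length_px * pixel_size_um


def aggregate_records(
    mask: np.ndarray,
    dry_mass_map: DryMassMap | None = None,
    optics: OpticalConfig | None = None,
    min_area_um2: float = 3.0,
    construct_tag: str = "",
    fov_id: str = "",
) -> list[AggregateRecord]:
    """Extract one record per qualifying 8-connected component.

    Components below ``min_area_um2`` are dropped.  Without a dry-mass
    map the mass is recorded as 0.  An empty mask returns an empty
    list.
    """
    mask = np.asarray(mask, dtype=bool)
    if dry_mass_map is not None and dry_mass_map.shape != mask.shape:
        raise ValueError("dry-mass map must align with the mask")
    optics = optics or (dry_mass_map.optics if dry_mass_map is not None
                        else OpticalConfig())
    px = optics.pixel_size_um
    pa = optics.pixel_area_um2

    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    records = []
    for comp in range(1, n + 1):
        comp_mask = labels == comp
        n_px = int(comp_mask.sum())
        area = n_px * pa
        if area < min_area_um2:
            continue
        ys, xs = np.nonzero(comp_mask)
        perimeter = _component_perimeter(comp_mask, px)
        circ = 4 * np.pi * area / perimeter ** 2 if perimeter > 0 else 1.0
        circ = min(circ, 1.05)  # quantization slack on near-perfect disks
        mass = 0.0
        if dry_mass_map is not None:
            mass = float(dry_mass_map.density[comp_mask].sum() * pa)
        records.append(AggregateRecord(
            id=f"{fov_id}:{comp}" if fov_id else str(comp),
            centroid_px=(float(ys.mean()), float(xs.mean())),
            area_um2=area,
            perimeter_um=perimeter,
            circularity=circ,
            dry_mass_pg=mass,
            construct_tag=construct_tag,
            fov_id=fov_id,
        ))
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Records as a tidy DataFrame (one row per aggregate)."""
    rows = []
    for r in records:
        d = asdict(r)
        cy, cx = d.pop("centroid_px")
        d["centroid_y_px"], d["centroid_x_px"] = cy, cx
        rows.append(d)
    return pd.DataFrame(rows)


def compare_constructs(
    records,
    flavor: str = "welch",
    value: str = "dry_mass_pg",
) -> ConstructComparison:
    """Pairwise unpaired two-sided t-tests on a per-construct quantity.

    Welch (unequal variance) by default; ``flavor='student'`` pools
    variances.  Groups with fewer than 3 records are excluded with a
    warning.  No multiple-testing correction is applied.
    """
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if frame.empty:
        raise ValueError("no records to compare")
    groups = {}
    for tag, sub in frame.groupby("construct_tag"):
        vals = sub[value].to_numpy(dtype=float)
        if vals.size < 3:
            warnings.warn(f"group '{tag}' has n<3; excluded", stacklevel=2)
            continue
        groups[str(tag)] = vals
    if len(groups) < 2:
        raise ValueError("need at least two groups with n >= 3")

    names = sorted(groups)
    t_stat, p_value = {}, {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = stats.ttest_ind(groups[a], groups[b],
                                  equal_var=(flavor == "student"))
            key = frozenset((a, b))
            t_stat[key] = float(res.statistic)
            p_value[key] = float(res.pvalue)
    return ConstructComparison(
        groups=names,
        n={g: int(v.size) for g, v in groups.items()},
        mean_pg={g: float(v.mean()) for g, v in groups.items()},
        std_pg={g: float(v.std(ddof=1)) for g, v in groups.items()},
        t_stat=t_stat,
        p_value=p_value,
        flavor=flavor,
    )
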