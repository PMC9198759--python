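"""Cortical thickness sampling protocol and thickness-tau correlation.

Per subfield and case, nine manual-style thickness measurements are planned:
three coronal slides (where the subfield first appears, the midpoint of its
anterior-posterior extent, and its last appearance) times three medial-lateral
sites per slide (at 25/50/75% of the unit's in-slice extent).  With the nine
thickness-eligible entorhinal units (EMI is excluded because of sample-tube
deformation) and ten cases this yields 810 planned sites.

Thickness itself is the Euclidean pial-to-white distance in mm: from the pial
face of the unit's mask at the site to the nearest gray/white boundary face,
measured in-plane — the digital analogue of a manual ruler on a coronal slide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anatomy import THICKNESS_UNITS, UNITS
from .gradient import TrendResult, spearman_trend
from .heatmap3d import LabelVolume

__all__ = [
    "SamplingPlan",
    "PlannedSite",
    "plan_samples",
    "measure_thickness",
    "measure_case",
    "thickness_tau_correlation",
    "count_planned_sites",
    "PlanningError",
]

SITE_FRACTIONS = (0.25, 0.50, 0.75)
SLIDE_POSITIONS = ("first", "midpoint", "last")


class PlanningError(ValueError):
    pass


@dataclass(frozen=True)
class PlannedSite:
    unit: str
    slide_position: str  # first | midpoint | last
    site_index: int  # 1..3
    slice_index: int
    ml_index: int  # in-plane medial-lateral voxel column


@dataclass(frozen=True)
class SamplingPlan:
    unit: str
    sites: tuple[PlannedSite, ...]
    degenerate: bool = False  # unit spanned < 3 distinct slices


def plan_samples(volume: LabelVolume, unit: str) -> SamplingPlan:
    """3 slides x 3 medial-lateral sites for one unit in a label volume.

    Slides are the first, middle (rounding toward anterior) and last slices
    occupied by the unit; sites sit at 25/50/75% of the unit's medial-lateral
    extent on each slide.  A unit spanning fewer than three slices yields
    coincident slide positions and a ``degenerate`` flag.
    """
    mask = volume.unit_mask(unit)
    occupied = np.where(mask.any(axis=tuple(i for i in range(3) if i != volume.ap_axis)))[0]
    if occupied.size == 0:
        raise PlanningError(f"unit {unit!r} absent from volume")
    first, last = int(occupied[0]), int(occupied[-1])
    mid = (first + last) // 2  # rounds toward anterior on even extents
    if mid not in occupied:  # unit may be absent from interior slices
        mid = int(occupied[np.argmin(np.abs(occupied - mid))])
    slides = (first, mid, last)
    degenerate = len(set(slides)) < 3

    sites = []
    for pos, sl in zip(SLIDE_POSITIONS, slides):
        plane = np.take(mask, sl, axis=volume.ap_axis)
        # in-plane axes ordered; ml axis position after removing ap axis
        ml_in_plane = volume.ml_axis - (volume.ml_axis > volume.ap_axis)
        cols = np.where(plane.any(axis=1 - ml_in_plane))[0]
        c0, c1 = int(cols[0]), int(cols[-1])
        for i, frac in enumerate(SITE_FRACTIONS, start=1):
            ml = c0 + int(round(frac * (c1 - c0)))
            sites.append(PlannedSite(unit, pos, i, sl, ml))
    return SamplingPlan(unit, tuple(sites), degenerate)


def measure_thickness(volume: LabelVolume, unit: str, site: PlannedSite) -> float:
    """Euclidean pial-to-white distance (mm) at one planned site.

    The pial point is the outer face of the unit's most superficial voxel in
    the site's medial-lateral column; the gray/white boundary is the set of
    deep outer faces across the unit's in-slice extent.  The returned value is
    the straight-line distance to the nearest boundary face, scaled by the
    voxel size — so a flat slab of n voxels at v mm/voxel measures exactly
    n*v mm.
    """
    mask = volume.unit_mask(unit)
    plane = np.take(mask, site.slice_index, axis=volume.ap_axis)
    # name in-plane axes: rows = thickness axis, cols = ml axis
    ml_in_plane = volume.ml_axis - (volume.ml_axis > volume.ap_axis)
    if ml_in_plane == 0:
        plane = plane.T  # ensure axis 0 = thickness, axis 1 = ml
    vs = volume.voxel_size
    v_thick = vs[volume.thickness_axis]
    v_ml = vs[volume.ml_axis]

    col = plane[:, site.ml_index]
    rows = np.where(col)[0]
    if rows.size == 0:
        raise PlanningError(f"site {site} lies outside unit {unit!r}")
    flip = volume.pial_side != "low"
    pial_row = rows[-1] if flip else rows[0]
    pial_y = (pial_row + 0.5 if flip else pial_row - 0.5) * v_thick
    pial_x = site.ml_index * v_ml

    # deep boundary faces: for each occupied column, the outer face of the
    # deepest voxel (the gray/white interface of this slab geometry)
    ys, xs = [], []
    for c in np.where(plane.any(axis=0))[0]:
        r = np.where(plane[:, c])[0]
        deep = r[0] if flip else r[-1]
        ys.append((deep - 0.5 if flip else deep + 0.5) * v_thick)
        xs.append(c * v_ml)
    ys = np.asarray(ys)
    xs = np.asarray(xs)
    d = np.sqrt((ys - pial_y) ** 2 + (xs - pial_x) ** 2)
    return float(d.min())


def measure_case(volume: LabelVolume, case_id: str,
                 units: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Plan and measure all eligible units of one case's volume (tidy table)."""
    if units is None:
        units = tuple(u for u in THICKNESS_UNITS if volume.unit_mask(u).any())
    rows = []
    for unit in units:
        if UNITS.get(unit) is not None and UNITS[unit].thickness_excluded:
            continue
        plan = plan_samples(volume, unit)
        for site in plan.sites:
            rows.append(
                dict(case_id=case_id, unit=unit, slide_position=site.slide_position,
                     site_index=site.site_index,
                     thickness_mm=measure_thickness(volume, unit, site))
            )
    return pd.DataFrame(rows)


def count_planned_sites(plans: list[SamplingPlan]) -> int:
    """Total planned measurement sites across sampling plans."""
    return sum(len(p.sites) for p in plans)


def thickness_tau_correlation(thickness: pd.DataFrame,
                              matrix: pd.DataFrame) -> TrendResult:
    """Spearman correlation of per-unit mean thickness vs per-unit mean SQ.

    Each thickness-eligible unit contributes the mean of its samples (9 per
    case when complete) and its mean SQ score across all cases and levels;
    at least three units with both measures are required.
    """
    t_mean = thickness.groupby("unit")["thickness_mm"].mean()
    sq = matrix[["unit", "sq"]].dropna()
    sq_mean = sq.groupby("unit")["sq"].mean()
    units = sorted(set(t_mean.index) & set(sq_mean.index))
    if len(units) < 3:
        raise PlanningError(f"need >= 3 units with both measures, got {len(units)}")
    res = spearman_trend(t_mean[units].to_numpy(), sq_mean[units].to_numpy())
    return TrendResult(res.statistic_name, res.statistic, len(units), res.p_value,
                       undefined=res.undefined,
                       note=f"per-unit mean thickness vs mean SQ over {len(units)} units")
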