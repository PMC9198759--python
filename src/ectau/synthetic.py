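"""Synthetic inputs emulating the study's data structures, with ground truth.

Three generators cover everything the pipeline consumes:

* :func:`generate_slide` — a DAB-like 8-bit grayscale section: a white-matter
  background strip with prescribed gray statistics, a gray-matter region, and
  dark tau objects (tangle-like discs, thin random-walk neuropil threads,
  optionally a laminar band) placed either to hit a target tau-pixel fraction
  or at fixed object counts.  The binary ground-truth tau mask is returned.
* :func:`generate_cohort` — a 10-case cohort of SQ score matrices over the
  8 AP levels x subfield units, built from a latent burden surface with a
  posterior-increasing gradient (``ap_slope``), a lateral > medial offset, an
  age-gated anterior "second wave" boost, Gaussian latent noise rounded and
  clamped to the ordinal 0-4 scale, and per-unit cortical thickness negatively
  coupled to burden.  A second simulated rater re-reads the latent surface for
  inter-rater analyses.
* :func:`generate_label_volume` — a slab label volume per case in which each
  (level, unit) occupies a contiguous voxel block whose thickness (in voxels)
  matches the unit's thickness in mm, ordered along the anterior-posterior
  axis, ready for thickness sampling and 3D heat-map rendering.

All randomness flows from a single seed through named child streams, so every
artifact is reproducible from one integer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import filters

from . import heatmap3d
from .anatomy import THICKNESS_UNITS, UNITS, subfields_at_level
from .gradient import CaseRecord

__all__ = [
    "SlideSpec",
    "CohortSpec",
    "SlideResult",
    "CohortData",
    "GroundTruth",
    "generate_slide",
    "generate_cohort",
    "generate_label_volume",
    "slide_spec_for_score",
    "write_slide",
    "read_slide",
    "write_cohort_csvs",
    "GenerationError",
]

#: Ages of the default 10-case cohort (years); one case ships without
#: demographics, mirroring a real cohort where one hemisphere lacked records.
DEFAULT_AGES: tuple = (59, 59, 60, 60, 70, None, 73, 80, 82, 84)


class GenerationError(ValueError):
    pass


# --- slide generation ---------------------------------------------------------


@dataclass(frozen=True)
class SlideSpec:
    """Parameters of one synthetic DAB-like grayscale section.

    ``tau_fraction`` drives placement: objects are added (NFT discs vs thread
    polylines mixed in the ratio ``nft_count:thread_count``) until the target
    fraction of gray-matter pixels is tau-covered.  With ``tau_fraction=None``
    exactly ``nft_count`` discs and ``thread_count`` threads are placed
    (count-driven mode, used for the scorer's prototype regimes).
    """

    width: int = 256
    height: int = 256
    wm_mean: float = 165.0
    wm_sd: float = 10.0
    gm_mean: float = 195.0
    gm_sd: float = 10.0
    tau_fraction: float | None = 0.10
    nft_count: int = 30
    nft_radius_px: float = 4.0
    thread_count: int = 30
    thread_length_px: int = 40
    tau_darkness: float = 80.0
    tau_sd: float = 8.0
    band: bool = False
    band_height_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.tau_fraction is not None and not (0.0 <= self.tau_fraction <= 0.5):
            raise GenerationError("tau_fraction must be in [0, 0.5]")
        # tau objects must fall below the background-calibrated threshold
        if not self.tau_darkness < self.wm_mean - 0.75 * self.wm_sd:
            raise GenerationError(
                "tau_darkness must lie below wm_mean - 0.75*wm_sd by construction"
            )
        if self.width < 32 or self.height < 32:
            raise GenerationError("slide must be at least 32x32 px")


@dataclass
class SlideResult:
    image: np.ndarray  # uint8 HxW
    wm_mask: np.ndarray
    gm_mask: np.ndarray
    exclusion_mask: np.ndarray
    tau_mask: np.ndarray  # ground truth, subset of gm_mask


def _region_masks(spec: SlideSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    h, w = spec.height, spec.width
    cols = np.arange(w)
    wm = np.zeros((h, w), bool)
    gm = np.zeros((h, w), bool)
    ex = np.zeros((h, w), bool)
    wm[:, cols < int(0.38 * w)] = True
    gm[:, cols >= int(0.44 * w)] = True
    ex[:, (cols >= int(0.38 * w)) & (cols < int(0.44 * w))] = True  # tissue tear strip
    return wm, gm, ex


def _draw_disc(mask: np.ndarray, gm: np.ndarray, r: int, c: int, radius: float) -> None:
    h, w = mask.shape
    rr = int(np.ceil(radius))
    r0, r1 = max(0, r - rr), min(h, r + rr + 1)
    c0, c1 = max(0, c - rr), min(w, c + rr + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    disc = (yy - r) ** 2 + (xx - c) ** 2 <= radius**2
    mask[r0:r1, c0:c1] |= disc & gm[r0:r1, c0:c1]


def _draw_thread(mask: np.ndarray, gm: np.ndarray, rng: np.random.Generator,
                 r: float, c: float, length: int) -> None:
    h, w = mask.shape
    theta = rng.uniform(0, 2 * np.pi)
    for _ in range(length):
        theta += rng.normal(0, 0.35)
        r += np.sin(theta)
        c += np.cos(theta)
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < h and 0 <= ci < w):
            break
        if gm[ri, ci]:
            mask[ri, ci] = True
            # 1-2 px wide: thicken sideways half the time
            if rng.random() < 0.5 and ci + 1 < w and gm[ri, ci + 1]:
                mask[ri, ci + 1] = True


def _place_objects(spec: SlideSpec, gm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros_like(gm)
    gm_idx = np.argwhere(gm)
    n_gm = len(gm_idx)

    if spec.band:
        rows = np.where(gm.any(axis=1))[0]
        band_h = max(2, int(spec.band_height_frac * len(rows)))
        start = rows[0] + int(0.35 * len(rows))
        band = np.zeros_like(gm)
        band[start : start + band_h, :] = True
        mask |= band & gm

    if spec.tau_fraction is None:
        for _ in range(spec.nft_count):
            r, c = gm_idx[rng.integers(n_gm)]
            _draw_disc(mask, gm, r, c, rng.uniform(0.7, 1.3) * spec.nft_radius_px)
        for _ in range(spec.thread_count):
            r, c = gm_idx[rng.integers(n_gm)]
            _draw_thread(mask, gm, rng, float(r), float(c), spec.thread_length_px)
        return mask

    target = int(round(spec.tau_fraction * n_gm))
    if target == 0:
        return mask
    weights = np.array([max(spec.nft_count, 0), max(spec.thread_count, 0)], float)
    if weights.sum() == 0:
        raise GenerationError("tau_fraction > 0 needs a nonzero object mix")
    weights /= weights.sum()
    for _ in range(200_000):
        if int(mask.sum()) >= target:
            return mask
        if mask.sum() >= 0.95 * n_gm:
            break
        r, c = gm_idx[rng.integers(n_gm)]
        if rng.random() < weights[0]:
            _draw_disc(mask, gm, r, c, rng.uniform(0.7, 1.3) * spec.nft_radius_px)
        else:
            _draw_thread(mask, gm, rng, float(r), float(c), spec.thread_length_px)
    raise GenerationError("could not reach tau_fraction with this object model")


def generate_slide(spec: SlideSpec) -> SlideResult:
    """Render one synthetic section and its ground-truth tau mask.

    The white-matter strip carries N(wm_mean, wm_sd) pixel noise, gray matter
    N(gm_mean, gm_sd); tau-object pixels are drawn at N(tau_darkness, tau_sd)
    and blended with a narrow Gaussian edge so objects are not aliased hard.
    Identical specs (including seed) produce bit-identical images.
    """
    rng = np.random.default_rng(spec.seed)
    wm, gm, ex = _region_masks(spec)
    h, w = spec.height, spec.width
    img = np.full((h, w), 255.0)
    img[wm] = rng.normal(spec.wm_mean, spec.wm_sd, int(wm.sum()))
    img[gm] = rng.normal(spec.gm_mean, spec.gm_sd, int(gm.sum()))

    tau = _place_objects(spec, gm, rng)
    if tau.any():
        tau_vals = np.full((h, w), spec.gm_mean)
        tau_vals[tau] = rng.normal(spec.tau_darkness, spec.tau_sd, int(tau.sum()))
        alpha = filters.gaussian(tau.astype(float), sigma=0.5)
        alpha = np.clip((alpha - 0.25) / 0.5, 0.0, 1.0)
        img = img * (1 - alpha) + tau_vals * alpha

    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SlideResult(image, wm, gm, ex, tau)


#: Prototype object regimes, one per SQ score, for the automated scorer.
_SCORE_REGIMES: dict[int, dict] = {
    0: dict(nft_count=0, thread_count=0, band=False),
    1: dict(nft_count=2, thread_count=0, band=False),
    2: dict(nft_count=16, thread_count=5, band=False),
    3: dict(nft_count=26, thread_count=30, band=True),
    4: dict(nft_count=75, thread_count=64, band=True),
}


def slide_spec_for_score(score: int, seed: int = 0, size: int = 192) -> SlideSpec:
    """A count-driven SlideSpec whose object regime typifies one SQ score."""
    if score not in _SCORE_REGIMES:
        raise GenerationError(f"score must be 0-4, got {score!r}")
    return SlideSpec(width=size, height=size, tau_fraction=None, seed=seed,
                     **_SCORE_REGIMES[score])


# --- cohort generation --------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic scoring cohort.

    The latent burden at (case, level, unit) is

        base_sq + ap_slope*level + lateral_offset*[unit is _Lat]
        + anterior_boost*[age > wave_age_threshold][level <= 4] + N(0, noise_sd)

    rounded and clamped to the ordinal 0-4 scale.  Per-unit cortical thickness
    is ``thickness_base - thickness_tau_coeff * (unit mean SQ)`` plus noise.
    Defaults emulate the published cohort: ten hemispheres aged 59-84 (one
    without demographics), a posterior-rising gradient peaking near the gyrus
    intralimbicus, a lateral > medial offset, an anterior second wave in cases
    older than 75 y, and thickness averages spanning roughly 2.7-4.4 mm.
    """

    n_cases: int = 10
    ages: tuple | None = None  # None: DEFAULT_AGES for 10 cases, else sampled 59-84
    base_sq: float = 0.9
    ap_slope: float = 0.25
    lateral_offset: float = 0.75
    wave_age_threshold: float = 75.0
    anterior_boost: float = 2.0
    noise_sd: float = 0.5
    rater_b_noise_sd: float = 0.2
    thickness_base: float = 5.1
    thickness_tau_coeff: float = 0.83
    thickness_noise_sd: float = 0.25
    include_perirhinal: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_cases < 1:
            raise GenerationError("n_cases must be >= 1")
        if self.ages is not None and len(self.ages) != self.n_cases and len(self.ages) != 2:
            raise GenerationError(
                "ages must be a per-case list, a (lo, hi) range, or None"
            )


@dataclass
class GroundTruth:
    """Generating quantities retained for recovery checks."""

    latent: pd.DataFrame  # case_id, level, unit, latent (real-valued)
    unit_mean_thickness: dict[str, float]
    spec: CohortSpec


@dataclass
class CohortData:
    scores: pd.DataFrame  # case_id, level, unit, sq, sq_rater_b, tau_ratio
    thickness: pd.DataFrame  # case_id, unit, slide_position, site_index, thickness_mm
    cases: list[CaseRecord]
    truth: GroundTruth


def _resolve_ages(spec: CohortSpec, rng: np.random.Generator) -> list:
    if spec.ages is None:
        if spec.n_cases == len(DEFAULT_AGES):
            return list(DEFAULT_AGES)
        return [int(a) for a in rng.integers(59, 85, spec.n_cases)]
    if len(spec.ages) == spec.n_cases:
        return list(spec.ages)
    lo, hi = spec.ages
    return [int(a) for a in rng.integers(int(lo), int(hi) + 1, spec.n_cases)]


SLIDE_POSITIONS = ("first", "midpoint", "last")

_GRID_CACHE: dict[bool, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _entry_grid(include_perirhinal: bool):
    """Static (level, unit, is_lateral) arrays for one case's score entries."""
    if include_perirhinal not in _GRID_CACHE:
        levels, units, lat = [], [], []
        for level in range(1, 9):
            for unit in sorted(subfields_at_level(level, include_perirhinal=include_perirhinal)):
                levels.append(level)
                units.append(unit)
                lat.append(UNITS[unit].mediolateral == "lateral")
        _GRID_CACHE[include_perirhinal] = (
            np.asarray(levels), np.asarray(units, dtype=object), np.asarray(lat)
        )
    return _GRID_CACHE[include_perirhinal]


def generate_cohort(spec: CohortSpec = CohortSpec()) -> CohortData:
    """Simulate a full scoring cohort (scores, thickness, demographics, truth)."""
    root = np.random.SeedSequence(spec.seed)
    rng_demo, rng_scores, rng_thick = (
        np.random.default_rng(s) for s in root.spawn(3)
    )
    ages = _resolve_ages(spec, rng_demo)

    cases: list[CaseRecord] = []
    for i in range(spec.n_cases):
        age = ages[i]
        cases.append(
            CaseRecord(
                case_id=f"S{i + 1:02d}",
                hemisphere="RH" if rng_demo.random() < 0.3 else "LH",
                age=None if age is None else float(age),
                sex=None if age is None else ("M" if rng_demo.random() < 0.5 else "F"),
                braak_stage="I" if rng_demo.random() < 0.4 else "II",
                brain_weight_g=None if age is None
                else float(np.round(rng_demo.normal(1250.0, 120.0), 0)),
            )
        )

    grid_levels, grid_units, grid_lat = _entry_grid(spec.include_perirhinal)
    n_entries = grid_levels.size
    case_ids, boosted = [], []
    for case in cases:
        case_ids.append(case.case_id)
        boosted.append(case.age is not None and case.age > spec.wave_age_threshold)
    boosted = np.asarray(boosted)

    level_col = np.tile(grid_levels, spec.n_cases)
    unit_col = np.tile(grid_units, spec.n_cases)
    lat_col = np.tile(grid_lat, spec.n_cases)
    case_col = np.repeat(np.asarray(case_ids, dtype=object), n_entries)
    boost_col = np.repeat(boosted, n_entries) & (level_col <= 4)

    mean = (
        spec.base_sq
        + spec.ap_slope * level_col
        + spec.lateral_offset * lat_col
        + spec.anterior_boost * boost_col
    )
    total = mean.size
    latent_vals = mean + rng_scores.normal(0, spec.noise_sd, total)
    sq = np.clip(np.rint(latent_vals), 0, 4).astype(int)
    # the second rater re-reads the same realized sections: small perceptual
    # jitter around the realized latent burden, not an independent draw
    sq_b = np.clip(
        np.rint(latent_vals + rng_scores.normal(0, spec.rater_b_noise_sd, total)), 0, 4
    ).astype(int)
    tau_ratio = np.maximum(0.0, 0.055 * latent_vals + rng_scores.normal(0, 0.01, total))
    scores = pd.DataFrame(
        dict(case_id=case_col, level=level_col, unit=unit_col, sq=sq,
             sq_rater_b=sq_b, tau_ratio=tau_ratio)
    )
    latent = pd.DataFrame(
        dict(case_id=case_col, level=level_col, unit=unit_col, latent=latent_vals)
    )

    # thickness: negatively coupled to the unit's realized SQ burden per case;
    # EMI (deformed in the sample tube) is never measured
    eligible = scores[scores["unit"].isin(THICKNESS_UNITS)]
    cohort_sq = eligible.groupby("unit")["sq"].mean()
    unit_truth = {
        u: spec.thickness_base - spec.thickness_tau_coeff * float(cohort_sq[u])
        for u in THICKNESS_UNITS
    }
    case_unit_sq = eligible.groupby(["case_id", "unit"])["sq"].mean()
    n_samples_per_unit = len(SLIDE_POSITIONS) * 3
    t_case, t_unit, t_pos, t_site, t_center = [], [], [], [], []
    for cid in case_ids:
        for unit in THICKNESS_UNITS:
            center = spec.thickness_base - spec.thickness_tau_coeff * float(
                case_unit_sq[(cid, unit)]
            )
            for pos in SLIDE_POSITIONS:
                for site in (1, 2, 3):
                    t_case.append(cid)
                    t_unit.append(unit)
                    t_pos.append(pos)
                    t_site.append(site)
                    t_center.append(center)
    t_vals = np.asarray(t_center) + rng_thick.normal(
        0, spec.thickness_noise_sd, len(t_center)
    )
    thickness = pd.DataFrame(
        dict(case_id=t_case, unit=t_unit, slide_position=t_pos, site_index=t_site,
             thickness_mm=np.maximum(0.05, t_vals))
    )

    truth = GroundTruth(latent=latent, unit_mean_thickness=unit_truth, spec=spec)
    return CohortData(scores, thickness, cases, truth)


# --- label volumes ------------------------------------------------------------


def generate_label_volume(
    case_scores: pd.DataFrame,
    unit_thickness_mm: dict[str, float] | None = None,
    voxel_size: float = 0.5,
    slices_per_level: int = 4,
    unit_width_vox: int = 8,
    default_thickness_mm: float = 3.0,
) -> heatmap3d.LabelVolume:
    """Slab label volume for one case's scores.

    Each AP level occupies ``slices_per_level`` consecutive slices along axis 0
    (anterior -> posterior); within a slice, each present unit is a contiguous
    block ``round(thickness/voxel)`` voxels deep along axis 1 (pial surface at
    the low-index face) and ``unit_width_vox`` wide along the medial-lateral
    axis 2, separated by one background column.
    """
    if voxel_size <= 0:
        raise GenerationError("voxel size must be positive")
    if case_scores.empty:
        vol = np.zeros((1, 1, 1), dtype=np.int16)
        return heatmap3d.LabelVolume(vol, (voxel_size,) * 3, {})

    unit_thickness_mm = unit_thickness_mm or {}
    levels = sorted(case_scores["level"].unique())
    max_units = max(
        len(case_scores.loc[case_scores["level"] == lv]) for lv in levels
    )
    depth_vox = max(
        int(round(unit_thickness_mm.get(u, default_thickness_mm) / voxel_size))
        for u in case_scores["unit"].unique()
    )
    shape = (
        int(max(levels)) * slices_per_level,
        depth_vox + 2,
        max_units * (unit_width_vox + 1) + 1,
    )
    data = np.zeros(shape, dtype=np.int16)
    table: dict[int, heatmap3d.LabelEntry] = {}
    label = 0
    for lv in levels:
        grp = case_scores.loc[case_scores["level"] == lv].sort_values("unit")
        z0 = (int(lv) - 1) * slices_per_level
        for j, (_, row) in enumerate(grp.iterrows()):
            unit = row["unit"]
            t_mm = unit_thickness_mm.get(unit, default_thickness_mm)
            t_vox = max(1, int(round(t_mm / voxel_size)))
            label += 1
            y0 = 1  # one background row above the pial surface
            x0 = 1 + j * (unit_width_vox + 1)
            data[z0 : z0 + slices_per_level, y0 : y0 + t_vox, x0 : x0 + unit_width_vox] = label
            sq = row["sq"]
            table[label] = heatmap3d.LabelEntry(
                unit=str(unit), level=int(lv),
                score=None if pd.isna(sq) else int(sq),
            )
    return heatmap3d.LabelVolume(data, (voxel_size,) * 3, table)


# --- IO -----------------------------------------------------------------------


def write_slide(result: SlideResult, stem) -> dict[str, str]:
    """Write image + masks as 8-bit grayscale TIFFs; returns the path map."""
    import tifffile

    stem = str(stem)
    paths = {}
    for name, arr in [
        ("image", result.image),
        ("wm_mask", result.wm_mask),
        ("gm_mask", result.gm_mask),
        ("exclusion_mask", result.exclusion_mask),
        ("tau_mask", result.tau_mask),
    ]:
        path = f"{stem}_{name}.tif"
        data = arr if arr.dtype == np.uint8 else (arr.astype(np.uint8) * 255)
        tifffile.imwrite(path, data)
        paths[name] = path
    return paths


def read_slide(paths: dict[str, str]) -> SlideResult:
    """Round-trip loader for :func:`write_slide` output."""
    import tifffile

    image = tifffile.imread(paths["image"])
    masks = {
        name: tifffile.imread(paths[name]) > 0
        for name in ("wm_mask", "gm_mask", "exclusion_mask", "tau_mask")
    }
    return SlideResult(image, masks["wm_mask"], masks["gm_mask"],
                       masks["exclusion_mask"], masks["tau_mask"])


def write_cohort_csvs(data: CohortData, outdir) -> dict[str, str]:
    """Tidy CSV export (scores, thickness, cases) plus a ground-truth JSON sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scores": str(outdir / "scores.csv"),
        "thickness": str(outdir / "thickness.csv"),
        "cases": str(outdir / "cases.csv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    data.scores.to_csv(paths["scores"], index=False, float_format="%.6f")
    data.thickness.to_csv(paths["thickness"], index=False, float_format="%.6f")
    pd.DataFrame([c.__dict__ for c in data.cases]).to_csv(paths["cases"], index=False)
    truth = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in data.truth.spec.__dict__.items()},
        "unit_mean_thickness": data.truth.unit_mean_thickness,
        "latent": data.truth.latent.to_dict(orient="list"),
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
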