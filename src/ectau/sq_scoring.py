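"""Five-point semi-quantitative (SQ) tau-density scale, automated scorer, colors, kappa.

The ordinal 0-4 scale grades phospho-tau burden in a cortical region from the
joint density of neurofibrillary tangles (NFTs) and the continuity of neuropil
threads (NTs):

    0  no visible tau-positive structures
    1  isolated NFTs, almost no NTs
    2  NFTs more numerous / more densely packed, NTs present but discontinuous
    3  densely packed NFTs forming a laminar (layer II/III) band, NTs nearly
       homogeneous
    4  band engulfed by closely packed NFTs, homogeneous NT blanket

The published scale is qualitative; the operational cutoffs that make it
computable live in :class:`ScorerConfig` and are deliberately tunable.  The
automated scorer exists to exercise the pipeline on synthetic sections, not to
reproduce human judgment on real histology.

Scores map onto a fixed five-color palette (blue, green, orange, rust,
burgundy) used for label volumes and heat maps, and inter-rater agreement is
summarized with unweighted Cohen's kappa (asymptotic 95% CI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from . import tau_quant

__all__ = [
    "SQScore",
    "ScoreColor",
    "KappaResult",
    "ScorerConfig",
    "SCORE_COLORS",
    "score_from_features",
    "extract_slide_features",
    "score_slide",
    "cohens_kappa",
    "color_for_score",
    "write_color_lut",
    "ScoringError",
]

SQ_VALUES = (0, 1, 2, 3, 4)


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class SQScore:
    value: int
    nft_density_class: str = ""  # none | isolated | dense | packed
    nt_continuity_class: str = ""  # none | sparse | discontinuous | moderate | homogeneous
    laminar_band_flag: bool = False

    def __post_init__(self):
        if self.value not in SQ_VALUES:
            raise ScoringError(f"SQ score must be 0-4, got {self.value}")


@dataclass(frozen=True)
class ScoreColor:
    score: int
    name: str
    rgb: tuple[int, int, int]


# Score->color code as used on the labeled volumes.  RGB values for orange,
# rust and burgundy are this package's fixed defaults (recorded here so
# rendered output is exactly reproducible).
SCORE_COLORS: dict[int, ScoreColor] = {
    0: ScoreColor(0, "blue", (0, 0, 255)),
    1: ScoreColor(1, "green", (0, 170, 0)),
    2: ScoreColor(2, "orange", (255, 165, 0)),
    3: ScoreColor(3, "rust", (183, 65, 14)),
    4: ScoreColor(4, "burgundy", (128, 0, 32)),
}


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci95: tuple[float, float]
    n_items: int
    undefined: bool = False  # both raters constant -> chance agreement is 1


@dataclass(frozen=True)
class ScorerConfig:
    """Operational cutoffs that make the qualitative 0-4 scale computable.

    Densities are NFT-like objects per mm^2 of region; NT coverage is the
    fraction of the region lying within ``nt_blanket_radius_px`` of a thread
    pixel (a "blanketing" notion of continuity).  A score of 2 needs NFT
    density at ``dense_factor`` times the isolated reference density or
    discontinuous NT coverage; scores 3 and 4 additionally require the laminar
    band and progressively homogeneous NT coverage.
    """

    mm_per_px: float = 0.01
    isolated_density: float = 0.8  # objects / mm^2 regarded as "isolated NFTs"
    dense_factor: float = 5.0  # score >= 2 when density >= factor * isolated
    packed_density: float = 15.0  # objects / mm^2 for the score-4 regime
    nt_sparse_coverage: float = 0.02
    nt_discontinuous_coverage: float = 0.10
    nt_moderate_coverage: float = 0.30
    nt_homogeneous_coverage: float = 0.50
    nt_blanket_radius_px: int = 6
    min_object_px: int = 4
    min_thread_px: int = 6  # smaller thin components are treated as noise specks
    band_row_density: float = 0.30
    band_min_rows: int = 4

    @property
    def dense_density(self) -> float:
        return self.dense_factor * self.isolated_density


def _density_class(density: float, cfg: ScorerConfig) -> str:
    if density <= 0:
        return "none"
    if density >= cfg.packed_density:
        return "packed"
    if density >= cfg.dense_density:
        return "dense"
    return "isolated"


def _nt_class(coverage: float, cfg: ScorerConfig) -> str:
    if coverage >= cfg.nt_homogeneous_coverage:
        return "homogeneous"
    if coverage >= cfg.nt_moderate_coverage:
        return "moderate"
    if coverage >= cfg.nt_discontinuous_coverage:
        return "discontinuous"
    if coverage > cfg.nt_sparse_coverage:
        return "sparse"
    return "none"


def score_from_features(
    nft_count_density: float,
    nt_coverage: float,
    band_flag: bool,
    config: ScorerConfig = ScorerConfig(),
) -> SQScore:
    """Map (NFT density, NT coverage, laminar-band flag) onto the 0-4 scale.

    The mapping is monotone: raising any feature never lowers the score.  The
    laminar band is required for scores >= 3.
    """
    if nft_count_density < 0:
        raise ScoringError("NFT density must be nonnegative")
    if not (0.0 <= nt_coverage <= 1.0):
        raise ScoringError("NT coverage must be in [0, 1]")

    dcls = _density_class(nft_count_density, config)
    ncls = _nt_class(nt_coverage, config)

    value = 0
    if nft_count_density > 0 or nt_coverage > 0 or band_flag:
        value = 1
    if nft_count_density >= config.dense_density or ncls in (
        "discontinuous",
        "moderate",
        "homogeneous",
    ):
        value = 2
    if (
        band_flag
        and nft_count_density >= config.dense_density
        and ncls in ("moderate", "homogeneous")
    ):
        value = 3
    if (
        band_flag
        and nft_count_density >= config.packed_density
        and ncls == "homogeneous"
    ):
        value = 4
    return SQScore(value, dcls, ncls, band_flag)


def extract_slide_features(
    tau_mask: np.ndarray,
    region_mask: np.ndarray,
    config: ScorerConfig = ScorerConfig(),
) -> tuple[float, float, bool]:
    """(NFT density /mm^2, NT blanket coverage, laminar-band flag) from a tau mask.

    A morphological opening with a small disk separates compact tangle-like
    blobs from 1-2 px neuropil threads even where they touch: blobs survive
    the opening and are counted (a surviving component spanning most of the
    region's width is the laminar band, not a tangle); the thin residue is the
    thread compartment.  NT coverage is the fraction of the region within
    ``nt_blanket_radius_px`` of a thread pixel.  The band flag fires when a
    contiguous run of image rows holds a high fraction of tau-positive region
    pixels, emulating a layer II/III band.
    """
    region = np.asarray(region_mask, dtype=bool)
    n_region = int(region.sum())
    if n_region == 0:
        raise ScoringError("empty region mask")
    mask = np.asarray(tau_mask, dtype=bool) & region

    footprint = morphology.disk(2)
    opened = ndimage.binary_opening(mask, structure=footprint)
    labels = measure.label(opened, connectivity=2)
    region_width = int(np.ptp(np.where(region.any(axis=0))[0])) + 1 if region.any() else 1
    nft_count = 0
    for prop in measure.regionprops(labels):
        if prop.area < config.min_object_px:
            continue
        width = prop.bbox[3] - prop.bbox[1]
        if width >= 0.6 * region_width:
            continue  # laminar band, handled by the row-density detector
        nft_count += 1

    area_mm2 = n_region * config.mm_per_px**2
    density = nft_count / area_mm2

    thread_mask = mask & ~ndimage.binary_dilation(opened, structure=footprint)
    # drop isolated noise specks so background pixel noise never reads as NTs
    tl, n_tl = ndimage.label(thread_mask, structure=np.ones((3, 3)))
    if n_tl:
        sizes = ndimage.sum_labels(thread_mask, tl, index=np.arange(1, n_tl + 1))
        keep = np.flatnonzero(sizes >= config.min_thread_px) + 1
        thread_mask = np.isin(tl, keep)
    blanket = ndimage.binary_dilation(
        thread_mask, structure=morphology.disk(config.nt_blanket_radius_px)
    )
    coverage = float((blanket & region).sum()) / n_region

    # laminar band: contiguous rows whose in-region tau fraction is high
    row_region = region.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        row_density = np.where(row_region > 0, mask.sum(axis=1) / row_region, 0.0)
    hot = row_density >= config.band_row_density
    band = False
    run = 0
    for h in hot:
        run = run + 1 if h else 0
        if run >= config.band_min_rows:
            band = True
            break
    return density, coverage, band


def score_slide(
    image: np.ndarray,
    region_mask: np.ndarray,
    wm_mask: np.ndarray,
    exclusion_mask: np.ndarray | None = None,
    config: ScorerConfig = ScorerConfig(),
    k: float = tau_quant.DEFAULT_K,
) -> SQScore:
    """Automated SQ score of one region on a grayscale section.

    Thresholds the image against its white-matter background (the quantitative
    protocol), then grades the resulting tau mask with
    :func:`extract_slide_features` and :func:`score_from_features`.
    """
    stats = tau_quant.white_matter_stats(image, wm_mask, exclusion_mask)
    thr = tau_quant.compute_threshold(stats, tau_quant.ThresholdParams(k))
    mask = np.asarray(image) < thr
    if exclusion_mask is not None:
        mask &= ~np.asarray(exclusion_mask, dtype=bool)
    feats = extract_slide_features(mask, region_mask, config)
    return score_from_features(*feats, config)


# --- inter-rater agreement ----------------------------------------------------


def cohens_kappa(rater_a, rater_b, n_categories: int = 5) -> KappaResult:
    """Unweighted Cohen's kappa over the 5x5 score contingency, with 95% CI.

    The CI uses the large-sample variance of Fleiss, Cohen & Everitt.  When
    both raters are constant the expected agreement is 1 and kappa is
    undefined; the result is flagged rather than raised.
    """
    a = np.asarray(rater_a, dtype=int)
    b = np.asarray(rater_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ScoringError("rater score lists must be equal-length 1-D sequences")
    if a.size == 0:
        raise ScoringError("empty score lists")
    if ((a < 0) | (a >= n_categories) | (b < 0) | (b >= n_categories)).any():
        raise ScoringError(f"scores must be integers in 0..{n_categories - 1}")
    n = a.size
    table = np.zeros((n_categories, n_categories))
    np.add.at(table, (a, b), 1.0)
    p = table / n
    po = float(np.trace(p))
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    pe = float(row @ col)
    if pe >= 1.0 - 1e-12:
        return KappaResult(math.nan, (math.nan, math.nan), n, undefined=True)
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss, Cohen & Everitt asymptotic variance
    i = np.arange(n_categories)
    diag = p[i, i]
    term1 = float(np.sum(diag * ((1 - pe) - (row + col) * (1 - po)) ** 2))
    pair = (col[:, None] + row[None, :]) ** 2  # (p_.i + p_j.)^2 for cell (i,j)
    off = (p * pair).copy()
    np.fill_diagonal(off, 0.0)
    term2 = float((1 - po) ** 2 * off.sum())
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    se = math.sqrt(max(var, 0.0))
    ci = (kappa - 1.959963984540054 * se, kappa + 1.959963984540054 * se)
    return KappaResult(float(kappa), ci, n)


def color_for_score(score: int) -> ScoreColor:
    """Fixed score -> color mapping (0 blue ... 4 burgundy)."""
    if score not in SCORE_COLORS:
        raise ScoringError(f"SQ score must be 0-4, got {score!r}")
    return SCORE_COLORS[score]


def score_for_color(rgb: tuple[int, int, int]) -> int:
    """Inverse palette lookup (exact match); used to round-trip renders."""
    for sc in SCORE_COLORS.values():
        if tuple(rgb) == sc.rgb:
            return sc.score
    raise ScoringError(f"rgb {rgb!r} is not in the score palette")


def write_color_lut(path) -> None:
    """FreeSurfer-style color lookup table for score labels (label name R G B A)."""
    with open(path, "w") as fh:
        fh.write("# ectau SQ score colormap\n")
        for sc in SCORE_COLORS.values():
            r, g, b = sc.rgb
            fh.write(f"{sc.score} SQ{sc.score}_{sc.name} {r} {g} {b} 0\n")
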