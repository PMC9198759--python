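# Methods

`ectau` models the computational side of a preclinical tau-pathology study of
the human entorhinal cortex (EC): grading phospho-tau burden (neurofibrillary
tangles, NFTs, and neuropil threads, NTs) per cytoarchitectonic subfield at
standardized coronal levels, testing the spatial and age structure of that
burden, and rendering it as 3D heat maps. Because the tissue, section images
and per-case scores of such studies are not released, the package pairs every
analysis stage with a synthetic-data generator that reproduces the *structure*
of the study inputs with known ground truth. This note documents the models,
the tunable parameters, the numerical choices, and what the synthetic tests do
and do not establish.

## Anatomical model

The EC is represented by ten scoring units derived from the eight classical
subfields (EO, ER, ELr, EMI, EI, ELc, ECs, ECL): EI and ECs are split into
`_Med`/`_Lat` bank units because the medial-to-lateral burden gradient is
scored per bank. Two perirhinal units (BA35a, BA35b) run through the same
machinery. Eight anterior–posterior (AP) levels anchored to amygdala and
hippocampal landmarks carry the set of units typically visible at that level
(level 1: EO only … level 7: ECs + ECL at the gyrus intralimbicus, level 8:
ECL only). ECs presence at level 7 is anatomically variable; it is encoded as
expected-but-optional. EMI is flagged thickness-excluded: in ex vivo scanning
the gyrus ambiens deforms against the sample tube, so its thickness is never
measured. The table ships as code and as a versioned CSV; alternative
parcellations can be loaded from the same CSV layout.

Age groups follow the gerontology convention used for such cohorts:
youngest-old 59–74 y, middle-old 75–84 y, oldest-old ≥ 85 y. Ages below 59
are outside the scheme; `age_group_of` maps them to youngest-old with a
warning rather than failing, keeping batch metadata processing total.

## Quantitative tau burden (tau ratio)

DAB-stained tau is darker than unstained tissue on the 8-bit grayscale
conversion of a digitized section. Each slide is self-calibrated on its white
matter (WM), which carries no specific staining: with WM pixel mean μ and
population SD σ (holes, tears and overlaps excluded by mask),

    threshold = μ − k·σ,   k = 0.75 (default, configurable)

and a region pixel is tau-positive iff its gray value is *strictly below* the
threshold. The burden readout is `tau_ratio = n_positive / n_negative`.
Choices worth recording:

* Pixels exactly at the threshold count negative ("under threshold" read
  strictly); this makes the k→∞ limit give ratio 0.
* The SD uses the population (n) divisor, the same divisor that exactly
  reproduces the cohort summary statistics below; it is applied uniformly.
* A region with zero negative pixels returns a flagged infinite ratio instead
  of raising, so batch runs complete; downstream statistics drop non-finite
  values.
* No color deconvolution and no physical pixel size: the ratio is
  scale-invariant, and quantification operates on grayscale.
* When several slides cover one level, per-slide ratios are averaged
  unweighted (pooled-pixel mode is a trivial variant the caller can compute
  from the returned counts).

Correctness is anchored two ways: exact equality with a per-pixel brute-force
loop on small random images, and end-to-end recovery on synthetic slides —
across ground-truth tau fractions 0.02–0.30 the measured ratio tracks the
true mask fraction with Spearman ρ > 0.95 (measured ≈ 1.0, relative error
< 1.5% at default contrast).

## Semi-quantitative (SQ) scale and the automated scorer

The ordinal 0–4 scale grades the joint density of NFTs and continuity of NTs
(0 none; 1 isolated NFTs, almost no NTs; 2 more/denser NFTs, discontinuous
NTs; 3 densely packed NFTs forming a laminar layer II/III band, NTs near
homogeneous; 4 band engulfed, homogeneous NT blanket). The scale is
qualitative by nature; `ScorerConfig` declares the operational cutoffs that
make it computable (defaults: score ≥ 2 at 5× the isolated reference density
of 0.8 objects/mm²; NT coverage classes at 0.10/0.30/0.50 of the region; the
laminar band required for scores ≥ 3; 0.01 mm/px assumed only for the density
features). These numbers are package choices, not published values, and exist
so the pipeline is testable; the automated scorer makes no claim of
reproducing human ratings on real histology.

Feature extraction on a thresholded tau mask: a morphological opening with a
2-px disk separates compact tangle-like blobs (which survive and are counted)
from 1–2 px threads (the residue), even where they touch — component-shape
classification alone fails at high thread density because tangles merge into
thread components. A surviving component spanning ≥ 60% of the region width
is the laminar band, not a tangle. NT "coverage" is blanketing coverage: the
fraction of the region within 6 px of a thread pixel. Thread residue smaller
than 6 px is discarded as noise, so background pixel noise never reads as
NTs. The band flag fires on a contiguous run of ≥ 4 image rows whose
in-region tau fraction is ≥ 0.30.

The score mapping is monotone by construction (raising any feature never
lowers the score), and on synthetic sections generated from five prototype
object regimes the scorer recovers the generating class in ≈ 99% of seeded
replicates (≥ 90% required).

Scores map to the fixed palette blue/green/orange/rust/burgundy (0…4). RGB
values for orange, rust and burgundy are package defaults recorded in code so
renders are exactly reproducible.

Inter-rater agreement uses unweighted Cohen's kappa over the 5×5 contingency
with the Fleiss–Cohen–Everitt asymptotic variance for the 95% CI (a
linear-weighted variant is deliberately not the default since the scale is
named unweighted); two constant raters leave κ undefined and flagged.

## Gradient, wave and cohort statistics

The unit of observation is the per-(case, level, unit) score, treated as
independent — a simplification that mirrors how ordinal pathology scores are
commonly tested, and the reason the synthetic calibration below matters.

* **Level trend.** The AP profile is the per-level mean ± population SD. The
  trend statistic is Spearman ρ between level index and per-level mean. The
  per-level means pool different numbers of entries (levels host 1–4 units),
  so their variances differ and the classical n=8 rank-permutation null is
  anticonservative; the p-value therefore comes from permuting the *level
  labels of the underlying entries* (2000 shuffles, fixed internal seed).
* **Subfield effects.** Kruskal–Wallis with tie correction; p by group-label
  permutation (4000 shuffles) for pooled n ≤ 500, χ² above. Dunn pairwise
  z-tests follow, Bonferroni-adjusted by default (Holm via config). Constant
  data leave H undefined and flagged.
* **Medial–lateral contrast.** Two-sided Mann–Whitney U on pooled `_Lat` vs
  `_Med` scores of EI or ECs. For ≤ 10 observations per side the p-value is
  exact by enumerating rank assignments (conditioning on ties); above that, a
  tie-corrected normal approximation.
* **Spearman utility.** Generic `spearman_trend` (used e.g. for the
  thickness–burden correlation) uses average ranks and an exact permutation
  p for n ≤ 10 via cached permutation tables, t-approximation beyond.
* **Wave classification.** A case's anterior burden is its mean SQ over
  levels 1–4, posterior over 5–8. `second_wave` iff anterior mean ≥ 2.0 (the
  cutoff is a package operationalization of a qualitative description, and is
  configurable). Cases without anterior entries are unclassifiable (error).
* **Age–anterior correlation.** Pearson r between age and level-1 mean SQ;
  cases with missing age are excluded, ≥ 3 usable cases required.
* **Cohort summaries.** Min/max/mean/SD over non-missing ages and brain
  weights with the population (n) divisor — the divisor that reproduces the
  printed reference summaries (69.67 ± 9.94 y; 1251.77 ± 121.55 g over the
  nine cases with demographics) — plus counts by sex, hemisphere, age group
  and Braak stage.

Calibration: with all generator effects at zero, the type-I rate of each of
the five pipeline tests (trend, subfield KW, ECs lateral contrast, age
correlation, thickness coupling) is 0.043–0.049 at α = 0.05 over 1000
replicate cohorts, inside the 0.05 ± 0.02 band the suite enforces.

## Cortical thickness

Per subfield and case, nine sites: the first, midpoint and last AP slices the
unit occupies (midpoint rounding toward anterior on even extents), times
three medial–lateral sites at 25/50/75% of the unit's in-slice extent
("equidistant" operationalized as straight-line extent fractions). Nine
eligible units × 10 cases gives 810 planned sites, matching the protocol
total. Units spanning fewer than three slices get coincident positions and a
degeneracy flag.

Thickness is the in-plane Euclidean distance from the pial face of the mask
column at the site to the *nearest* deep (gray/white) boundary face — a
point-to-surface distance emulating a manual ruler, not a streamline method.
Distances are measured between outer voxel faces, so a flat slab of n voxels
at v mm/voxel measures exactly n·v mm; analytic slabs reproduce ground truth
to within half a voxel diagonal, and wedges give strictly increasing site
series. The thickness–burden stage correlates per-unit mean thickness with
per-unit mean SQ via the Spearman utility (n = 9 units → exact p).

## 3D heat maps

A label volume assigns one integer label per (unit, SQ score) combination —
unit identity survives in the voxel data, with a collapsed score field
derived on demand. Conventions: 0-based indices, axis 0 anterior→posterior,
axis 1 pial→white (pial at the low-index face), axis 2 medial→lateral;
hemisphere is sidecar metadata so left/right cohorts render consistently.
Exports: NIfTI-1 with a JSON label-table sidecar and a FreeSurfer-style color
LUT; meshes as PLY with per-face palette colors (STL optional); slice renders
as RGB PNG over a black background.

Isosurfaces are extracted per score from the binary score region, marching
cubes at iso-level 0.5 on a 2× supersampled, zero-padded field. The
supersampling places the contour on the voxel boundary instead of collapsing
single voxels to octahedra (volume 1/6 of the voxel), so enclosed mesh volume
approximates voxel-count volume: a single voxel reconstructs to ≈ 0.9× its
volume, boxes to within 10%, and doubling resolution converges the ratio to
within 5%. Surfaces are unsmoothed by default. Watertightness is checked and
recorded, not required.

## Synthetic data: what it emulates, and what it does not

**Slides.** A WM strip with N(μ_wm, σ_wm) pixel noise, a gray-matter field
with N(μ_gm, σ_gm), a tear/gap strip as the exclusion mask, and dark tau
objects: tangles as filled discs (radius ~4 px, ±30%), threads as random-walk
polylines 1–2 px wide, optionally a dense laminar band; object pixels drawn
at N(80, 8) and blended with a narrow Gaussian edge. Placement is either
fraction-driven (objects added in the NFT:thread mix until the target
gray-matter tau fraction is reached, realized within ±10% relative) or
count-driven (the scorer's five prototype regimes). Gray-value defaults
(WM 165 ± 10, GM 195 ± 10) are calibration-free choices — stain intensity
distributions of real sections are not published — and are exposed in the
spec/config. The generator validates that tau darkness lies below the
WM-calibrated threshold by construction.

**Cohorts.** The latent burden at (case, level, unit) is

    base + slope·level + lat·[lateral unit] + boost·[age > 75][level ≤ 4] + ε,
    ε ~ N(0, noise_sd),

rounded and clamped to 0–4 (the simplest ordinal-generating mechanism for
the scale). Defaults: 10 cases with the reference-style age list 59–84 y
including one case without demographics (propagated as missing to age
analyses), base 0.9, slope 0.25/level, lateral offset 0.75, anterior boost
2.0 above 75 y, noise SD 0.5. The slope and base put unit means in the
published 1.3–2.9 SQ range with the peak at levels 7–8; the lateral offset is
larger than the ≈ 0.25 difference visible in the published per-unit averages
because it is set for *detectability*: a 10-case cohort yields only 30
observations per ECs bank, and 0.75 is the smallest round value at which the
lateral contrast is recovered with p < 0.05 in ≳ 99% of cohorts (0.25 gives
30% power — a test of the machinery would mostly measure noise). A second
simulated rater re-reads the realized latent burden with jitter SD 0.2,
giving κ ≈ 0.79, the agreement level reported for the human raters.
Per-unit thickness is `5.1 − 0.83 · (unit mean SQ)` plus N(0, 0.25) per
sample — the line through the published per-subfield (thickness, SQ)
averages — with nine samples per unit and case, EMI never measured.

**Volumes.** Each case's scores become a slab volume: levels are consecutive
4-slice blocks along the AP axis; within a level each unit is a contiguous
block `round(thickness/voxel)` voxels deep and 8 voxels wide, one background
column apart (0.5 mm isotropic voxels by default).

What passing synthetic tests shows: the estimators recover the signs and
rough magnitudes of effects they were built to detect, their null behavior is
calibrated, and every IO path round-trips. What it does not show: performance
on real histology — no stain chemistry, no real NFT/NT morphology, no
registration error, no human rating behavior, no real MRI geometry. The
scorer cutoffs and the generator regimes are co-designed; agreement between
them validates the plumbing, not the scale.

## Pipeline and reproducibility

`run_pipeline` executes simulate → quantify → score → analyze → thickness →
heatmap → report under one YAML-serializable config. A single root seed fans
out through named `SeedSequence` child streams per stage, so any stage can be
re-run in isolation; all derived seeds stay below 2³¹. Outputs are tidy CSVs
(fixed float format), NIfTI + sidecars, PLY meshes, PNG renders, a JSON
statistics report, a JSON-lines log, and a manifest of SHA-256 checksums —
identical config + seed reproduce an identical manifest. The pipeline refuses
to write into a non-empty directory unless forced, and any stage error aborts
with the stage named. Monte Carlo p-values use fixed internal permutation
seeds, so reported statistics are deterministic given the data.

Problem sizes used by the shipped tests and the acceptance script — 10-case
cohorts (360 score entries), 256² slides, 1000-replicate null calibration,
100-cohort recovery, 100 scorer replicates at 192² — were chosen so the whole
suite illustrates every claim in a few minutes on one CPU; all of them are
config parameters, not limits of the method.

## Known limitations

* Scores are treated as independent observations; the case-level correlation
  structure of real repeated-measures data is not modeled, which is exactly
  why the permutation calibration is run on the generator's null.
* The thickness measurement is point-to-nearest-surface on voxel masks; it
  underestimates thickness on strongly curved or steeply sloped interfaces
  relative to streamline definitions.
* The exact Mann–Whitney/Spearman enumerations are O(C(n₁+n₂,n₁)) and O(n!)
  and are capped at 10 per side / n = 10 (the regime of such cohorts);
  larger samples switch to tie-corrected approximations.
* The tau-ratio's slide generator draws WM and GM from Gaussians; real
  sections have spatially structured background (vessels, folds) that the
  exclusion-mask contract is designed to absorb but the generator does not
  produce.
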