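# ectau

Tau-burden mapping of entorhinal cortex subfields: background-calibrated
quantification of DAB-immunostained sections, ordinal semi-quantitative (SQ)
scoring, anterior–posterior gradient and age-wave statistics, cortical
thickness sampling, and 3D score heat maps — with a synthetic-data generator
so the entire pipeline runs and is tested end to end without any external
data.

## The problem

Neurofibrillary tangles (NFTs) and neuropil threads (NTs) appear in the
entorhinal cortex (EC) decades before dementia symptoms. In preclinical
(Braak I–II) tissue the burden is not uniform: it rises from anterior to
posterior levels, peaks near the gyrus intralimbicus, is heavier on the
lateral banks of the bifurcated EI/ECs subfields than on the medial banks,
and in older cases a "second wave" adds anterior pathology. Quantifying that
structure requires (a) an objective per-region burden measure on stained
sections, (b) an ordinal rating scale with inter-rater statistics, (c) the
gradient/age statistics, (d) a thickness protocol relating burden to
atrophy, and (e) a way to paint scores back onto 3D anatomy. `ectau`
implements all five for researchers building or validating such protocols.

## Core quantities

**Tau ratio.** Each 8-bit grayscale slide is self-calibrated on its white
matter (mean μ, population SD σ over included WM pixels):

    threshold = μ − 0.75·σ
    tau_ratio = #{region px < threshold} / #{region px ≥ threshold}

**SQ scale.** Ordinal 0–4 from NFT density, NT continuity and the laminar
(layer II/III) band; colors blue/green/orange/rust/burgundy; agreement via
unweighted Cohen's κ with asymptotic 95% CI.

**Gradient statistics.** Spearman trend of per-level mean burden along the
eight AP levels (entry-permutation p), Kruskal–Wallis + Dunn across the ten
subfield units, exact Mann–Whitney U for lateral-vs-medial contrasts, Pearson
r of age vs anterior burden, first/second-wave calls per case.

**Thickness.** 3 slides × 3 medial–lateral sites per subfield and case
(9 eligible units × 10 cases = 810 sites), Euclidean pial-to-white distance
on label volumes, Spearman correlation of per-unit mean thickness vs mean SQ.

## Worked example

```python
from ectau import (CohortSpec, SlideSpec, generate_cohort, generate_slide,
                   white_matter_stats, compute_threshold, quantify_region,
                   level_trend_test, medial_lateral_test, cohens_kappa,
                   thickness_tau_correlation)

slide = generate_slide(SlideSpec(tau_fraction=0.10, seed=1))
stats = white_matter_stats(slide.image, slide.wm_mask, slide.exclusion_mask)
thr = compute_threshold(stats)
res = quantify_region(slide.image, slide.gm_mask, slide.exclusion_mask, thr)
print(f"WM background: {stats.mean_gray:.1f} +/- {stats.sd_gray:.1f}  ->  threshold {thr:.1f}")
print(f"tau ratio: {res.tau_ratio:.4f}  ({res.n_positive} positive / {res.n_negative} negative px)")

cohort = generate_cohort(CohortSpec(seed=1))
trend = level_trend_test(cohort.scores)
print(f"AP level trend: rho = {trend.statistic:.3f}, p = {trend.p_value:.4f}")
ml = medial_lateral_test(cohort.scores, "ECs")
print(f"ECs lateral vs medial: U = {ml.statistic:.0f}, p = {ml.p_value:.4f}")
kap = cohens_kappa(cohort.scores["sq"], cohort.scores["sq_rater_b"])
print(f"inter-rater kappa: {kap.kappa:.3f} (95% CI {kap.ci95[0]:.3f}-{kap.ci95[1]:.3f})")
tc = thickness_tau_correlation(cohort.thickness, cohort.scores)
print(f"thickness vs tau: rho = {tc.statistic:.3f}, p = {tc.p_value:.2e}")
```

prints

```
WM background: 164.9 +/- 9.9  ->  threshold 157.5
tau ratio: 0.1114  (3696 positive / 33168 negative px)
AP level trend: rho = 0.857, p = 0.0160
ECs lateral vs medial: U = 739, p = 0.0000
inter-rater kappa: 0.799 (95% CI 0.748-0.850)
thickness vs tau: rho = -1.000, p = 5.51e-06
```

Reading it: the synthetic slide was generated with a true tau fraction of
0.10 of gray-matter pixels, i.e. a true positive/negative ratio of 0.111 —
the background-calibrated measurement recovers 0.1114. The 10-case cohort
carries a posterior-rising gradient (the level trend is strongly positive),
a heavier lateral ECs bank (U far above the null midpoint of 450), two
simulated raters at substantial agreement, and per-unit thickness that falls
monotonically with burden (ρ = −1 over the nine eligible units).

The same stages run from the shell:

```sh
ectau run-all --seed 42 --out results/run42
ectau simulate --seed 7 --n-cases 10 --out cohort/
ectau quantify --image s.tif --wm-mask wm.tif --region-mask gm.tif --k 0.75 --out q.csv
ectau analyze --scores cohort/scores.csv --cases cohort/cases.csv --out report/
ectau heatmap --volume results/run42/heatmaps/S01_labels.nii --min-score 1 --out meshes/
```

`run-all` writes tidy CSVs, NIfTI label volumes with JSON sidecars and a
FreeSurfer-style color LUT, PLY isosurface meshes, PNG slice renders, a JSON
statistics report and a SHA-256 manifest; the same config and seed reproduce
the manifest byte for byte.

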