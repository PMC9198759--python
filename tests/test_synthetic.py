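"""Synthetic slide/cohort/volume generators: determinism, ground truth, contracts."""

import numpy as np
import pandas as pd
import pytest

from ectau import gradient, synthetic
from ectau.anatomy import THICKNESS_UNITS, subfields_at_level
from ectau.synthetic import CohortSpec, GenerationError, SlideSpec


class TestSlideGeneration:
    def test_fixed_seed_is_bit_identical(self):
        a = synthetic.generate_slide(SlideSpec(seed=3))
        b = synthetic.generate_slide(SlideSpec(seed=3))
        assert (a.image == b.image).all()
        assert (a.tau_mask == b.tau_mask).all()

    def test_zero_fraction_has_empty_mask(self):
        res = synthetic.generate_slide(SlideSpec(tau_fraction=0.0, seed=1))
        assert not res.tau_mask.any()

    def test_realized_fraction_within_ten_percent(self):
        res = synthetic.generate_slide(SlideSpec(width=512, height=512,
                                                 tau_fraction=0.10, seed=2))
        frac = res.tau_mask.sum() / res.gm_mask.sum()
        assert 0.09 <= frac <= 0.11

    def test_wm_statistics_match_spec_within_two_percent(self):
        spec = SlideSpec(seed=4)
        res = synthetic.generate_slide(spec)
        wm = res.image[res.wm_mask].astype(float)
        assert wm.mean() == pytest.approx(spec.wm_mean, rel=0.02)
        assert wm.std(ddof=0) == pytest.approx(spec.wm_sd, rel=0.02)

    def test_tau_mask_confined_to_gray_matter(self, default_slide):
        assert not (default_slide.tau_mask & ~default_slide.gm_mask).any()

    def test_masks_are_disjoint(self, default_slide):
        s = default_slide
        overlap = (s.wm_mask.astype(int) + s.gm_mask.astype(int)
                   + s.exclusion_mask.astype(int))
        assert overlap.max() <= 1

    def test_tau_darkness_invariant_enforced(self):
        with pytest.raises(GenerationError):
            SlideSpec(tau_darkness=200.0)

    def test_excessive_fraction_rejected(self):
        with pytest.raises(GenerationError):
            SlideSpec(tau_fraction=0.7)

    def test_infeasible_object_mix_raises(self):
        with pytest.raises(GenerationError):
            synthetic.generate_slide(
                SlideSpec(tau_fraction=0.1, nft_count=0, thread_count=0, seed=1)
            )

    def test_image_round_trips_losslessly(self, default_slide, tmp_path):
        paths = synthetic.write_slide(default_slide, tmp_path / "s")
        loaded = synthetic.read_slide(paths)
        assert (loaded.image == default_slide.image).all()
        assert (loaded.tau_mask == default_slide.tau_mask).all()
        assert (loaded.wm_mask == default_slide.wm_mask).all()


class TestCohortGeneration:
    def test_deterministic_under_seed(self):
        a = synthetic.generate_cohort(CohortSpec(seed=9))
        b = synthetic.generate_cohort(CohortSpec(seed=9))
        assert a.scores.equals(b.scores)
        assert a.thickness.equals(b.thickness)

    def test_zero_effects_zero_noise_constant_surface(self):
        spec = CohortSpec(ap_slope=0, lateral_offset=0, anterior_boost=0,
                          noise_sd=0, base_sq=2.0, seed=1)
        data = synthetic.generate_cohort(spec)
        assert (data.scores["sq"] == 2).all()

    def test_anterior_boost_raises_anterior_scores_of_old_cases(self):
        spec = CohortSpec(n_cases=2, ages=(80, 60), anterior_boost=2.0, seed=5)
        data = synthetic.generate_cohort(spec)
        ant = data.scores[data.scores.level <= 2]
        old = ant[ant.case_id == "S01"]["sq"].mean()
        young = ant[ant.case_id == "S02"]["sq"].mean()
        assert old > young

    def test_ap_slope_recovered_by_trend_estimator(self):
        data = synthetic.generate_cohort(CohortSpec(ap_slope=0.4, noise_sd=0.3, seed=8))
        res = gradient.level_trend_test(data.scores)
        assert res.statistic > 0.8 and res.p_value < 0.05

    def test_profile_peaks_posteriorly(self):
        data = synthetic.generate_cohort(CohortSpec(ap_slope=0.4, seed=12))
        prof = gradient.level_profile(data.scores)
        assert prof["mean"].idxmax() + 1 in (7, 8)

    def test_scores_clamped_to_scale(self):
        data = synthetic.generate_cohort(CohortSpec(base_sq=5.0, noise_sd=3.0, seed=2))
        assert data.scores["sq"].between(0, 4).all()

    def test_units_follow_anatomy(self, default_cohort):
        for level, grp in default_cohort.scores.groupby("level"):
            allowed = subfields_at_level(int(level), include_perirhinal=True)
            assert set(grp["unit"]) == allowed

    def test_emi_has_no_thickness_and_thickness_positive(self, default_cohort):
        assert "EMI" not in set(default_cohort.thickness["unit"])
        assert set(default_cohort.thickness["unit"]) == set(THICKNESS_UNITS)
        assert (default_cohort.thickness["thickness_mm"] > 0).all()

    def test_nine_samples_per_unit_per_case(self, default_cohort):
        counts = default_cohort.thickness.groupby(["case_id", "unit"]).size()
        assert (counts == 9).all()

    def test_missing_age_case_supported(self, default_cohort):
        missing = [c for c in default_cohort.cases if c.age is None]
        assert len(missing) == 1
        # propagated to age analyses as an exclusion
        res = gradient.age_anterior_correlation(default_cohort.scores,
                                                default_cohort.cases)
        assert res.n == 9

    def test_thickness_recovers_generating_line_within_two_sds(self, default_cohort):
        spec = default_cohort.truth.spec
        per_unit = default_cohort.thickness.groupby("unit")["thickness_mm"].mean()
        sq = default_cohort.scores.groupby("unit")["sq"].mean()
        for unit in THICKNESS_UNITS:
            expect = spec.thickness_base - spec.thickness_tau_coeff * sq[unit]
            tol = 2 * spec.thickness_noise_sd
            assert abs(per_unit[unit] - expect) <= tol

    def test_invalid_specs_rejected(self):
        with pytest.raises(GenerationError):
            CohortSpec(n_cases=0)
        with pytest.raises(GenerationError):
            CohortSpec(n_cases=5, ages=(60, 61, 62))

    def test_csv_export_round_trip(self, default_cohort, tmp_path):
        paths = synthetic.write_cohort_csvs(default_cohort, tmp_path)
        scores = pd.read_csv(paths["scores"])
        assert len(scores) == len(default_cohort.scores)
        assert (scores["sq"] == default_cohort.scores["sq"]).all()


class TestLabelVolumes:
    def test_block_thickness_matches_voxel_arithmetic(self):
        scores = pd.DataFrame([dict(case_id="c", level=1, unit="EO", sq=2)])
        vol = synthetic.generate_label_volume(scores, {"EO": 3.0}, voxel_size=0.5)
        mask = vol.unit_mask("EO")
        rows = np.where(mask.any(axis=(0, 2)))[0]
        assert rows.size == 6  # 3.0 mm / 0.5 mm

    def test_empty_case_empty_volume(self):
        vol = synthetic.generate_label_volume(pd.DataFrame(columns=["case_id", "level", "unit", "sq"]))
        assert (vol.data == 0).all()

    def test_full_case_label_count(self, default_cohort):
        cs = default_cohort.scores[default_cohort.scores.case_id == "S01"]
        vol = synthetic.generate_label_volume(cs)
        assert len(vol.voxel_counts()) == len(cs)

    def test_levels_ordered_along_ap_axis(self, default_cohort):
        cs = default_cohort.scores[default_cohort.scores.case_id == "S01"]
        vol = synthetic.generate_label_volume(cs)
        starts = {}
        for label, entry in vol.label_table.items():
            z = np.where((vol.data == label).any(axis=(1, 2)))[0]
            starts.setdefault(entry.level, z[0])
        levels = sorted(starts)
        assert all(starts[a] < starts[b] for a, b in zip(levels, levels[1:]))

    def test_nonpositive_voxel_size_rejected(self, default_cohort):
        cs = default_cohort.scores[default_cohort.scores.case_id == "S01"]
        with pytest.raises(GenerationError):
            synthetic.generate_label_volume(cs, voxel_size=0.0)
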