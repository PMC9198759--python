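"""Rank statistics, wave classification and cohort summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ectau import gradient, synthetic
from ectau.gradient import (
    AnalysisError,
    CaseRecord,
    classify_wave,
    cohort_summary,
    level_profile,
    make_score_matrix,
    mann_whitney,
    medial_lateral_test,
    spearman_trend,
    subfield_effects,
    validate_score_matrix,
)


def matrix_from(rows):
    return make_score_matrix(pd.DataFrame(rows))


class TestLevelProfile:
    def test_constant_matrix(self):
        rows = [dict(case_id="c", level=lv, unit="EO", sq=2) for lv in range(1, 9)]
        prof = level_profile(matrix_from(rows))
        assert (prof["mean"] == 2).all() and (prof["sd"] == 0).all()

    def test_missing_level_flagged_not_zero(self):
        rows = [dict(case_id="c", level=1, unit="EO", sq=3)]
        prof = level_profile(matrix_from(rows))
        assert prof.loc[prof.level == 2, "n"].item() == 0
        assert math.isnan(prof.loc[prof.level == 2, "mean"].item())

    def test_nondecreasing_by_construction(self):
        rows = [dict(case_id="c", level=lv, unit="EO", sq=round(lv / 2))
                for lv in range(1, 9)]
        prof = level_profile(matrix_from(rows))
        means = prof["mean"].to_numpy()
        assert (np.diff(means) >= 0).all()

    def test_saturated_tau_ratios_dropped(self):
        rows = [dict(case_id="c", level=1, unit="EO", sq=1, tau_ratio=math.inf),
                dict(case_id="c", level=1, unit="ER", sq=1, tau_ratio=0.2)]
        prof = level_profile(matrix_from(rows), measure="tau_ratio")
        assert prof.loc[prof.level == 1, "n"].item() == 1


class TestSpearman:
    def test_perfect_monotone(self):
        up = spearman_trend([1, 2, 3, 4, 5], [2, 4, 5, 7, 11])
        dn = spearman_trend([1, 2, 3, 4, 5], [11, 7, 5, 4, 2])
        assert up.statistic == pytest.approx(1.0)
        assert dn.statistic == pytest.approx(-1.0)
        # only identity/reversal reach |rho|=1 for n=5 -> exact p = 2/5!
        assert up.p_value == pytest.approx(2 / 120)

    def test_antisymmetry(self, rng):
        x = rng.random(8)
        y = rng.random(8)
        a = spearman_trend(x, y)
        b = spearman_trend(x, -y)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_invariant_to_strictly_monotone_transforms(self, rng):
        x = rng.random(9)
        y = rng.random(9)
        base = spearman_trend(x, y)
        trans = spearman_trend(np.exp(3 * x), y**3 + 5 * y)
        assert trans.statistic == pytest.approx(base.statistic)
        assert trans.p_value == pytest.approx(base.p_value)

    def test_matches_scipy_rho_with_ties(self, rng):
        x = rng.integers(0, 4, 30).astype(float)
        y = rng.integers(0, 4, 30).astype(float)
        res = spearman_trend(x, y)
        assert res.statistic == pytest.approx(sps.spearmanr(x, y).statistic)

    def test_constant_input_flagged(self):
        res = spearman_trend([1, 2, 3], [5, 5, 5])
        assert res.undefined

    def test_too_short_raises(self):
        with pytest.raises(AnalysisError):
            spearman_trend([1, 2], [3, 4])


class TestMannWhitney:
    def test_identical_samples(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(8.0)  # n1*n2/2
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        res = mann_whitney([4, 4, 4, 4], [1, 1, 1, 1])
        assert res.statistic == pytest.approx(16.0)
        assert res.p_value == pytest.approx(2 / 70)  # C(8,4)=70 rankings

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(5):
            x = rng.random(6)
            y = rng.random(7) + 0.2
            ours = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.statistic == pytest.approx(float(ref.statistic))
            assert ours.p_value == pytest.approx(float(ref.pvalue))

    def test_empty_side_raises(self):
        with pytest.raises(AnalysisError):
            mann_whitney([], [1.0])

    def test_lateral_offset_detected(self):
        hits = 0
        for seed in range(20):
            data = synthetic.generate_cohort(
                synthetic.CohortSpec(seed=seed, lateral_offset=1.0)
            )
            res = medial_lateral_test(data.scores, "ECs")
            lat = data.scores.loc[data.scores.unit == "ECs_Lat", "sq"].median()
            med = data.scores.loc[data.scores.unit == "ECs_Med", "sq"].median()
            hits += (lat >= med) and res.p_value < 0.05
        assert hits >= 18

    def test_unknown_pair_rejected(self, default_cohort):
        with pytest.raises(AnalysisError):
            medial_lateral_test(default_cohort.scores, "EO")


class TestKruskalDunn:
    def test_matches_bruteforce_rank_computation(self):
        groups = {"g1": [1, 1, 1], "g2": [4, 4, 4], "g3": [4, 4, 4]}
        rows = [dict(case_id="c", level=1, unit=g, sq=v)
                for g, vals in groups.items() for v in vals]
        res = subfield_effects(matrix_from(rows), p_method="permutation")

        # independent oracle: explicit midrank + tie-corrected H
        pooled = [v for vals in groups.values() for v in vals]
        ranks = {}
        for v in set(pooled):
            idx = [i for i, p in enumerate(sorted(pooled)) if p == v]
            ranks[v] = sum(i + 1 for i in idx) / len(idx)
        n = len(pooled)
        h = 12 / (n * (n + 1)) * sum(
            sum(ranks[v] for v in vals) ** 2 / len(vals) for vals in groups.values()
        ) - 3 * (n + 1)
        ties = {v: pooled.count(v) for v in set(pooled)}
        c = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
        assert res.statistic == pytest.approx(h / c)

        # Dunn: the deviant group is flagged against both others, the equal
        # pair is not
        ph = {frozenset(pair): p for pair, _, p in res.posthoc}
        assert ph[frozenset(("g1", "g2"))] < 0.05
        assert ph[frozenset(("g1", "g3"))] < 0.05
        assert ph[frozenset(("g2", "g3"))] == pytest.approx(1.0)

    def test_constant_groups_flagged(self):
        rows = [dict(case_id="c", level=1, unit=u, sq=2)
                for u in ("g1", "g2") for _ in range(3)]
        res = subfield_effects(matrix_from(rows))
        assert res.undefined

    def test_single_group_raises(self):
        rows = [dict(case_id="c", level=1, unit="g1", sq=v) for v in (1, 2, 3)]
        with pytest.raises(AnalysisError):
            subfield_effects(matrix_from(rows))

    def test_permutation_and_chi2_agree_on_large_samples(self, rng):
        rows = []
        for g, shift in (("g1", 0.0), ("g2", 0.8)):
            for v in rng.normal(shift, 1.0, 60):
                rows.append(dict(case_id="c", level=1, unit=g, sq=np.nan, tau_ratio=abs(v)))
        m = matrix_from(rows)
        p_perm = subfield_effects(m, measure="tau_ratio", p_method="permutation").p_value
        p_chi2 = subfield_effects(m, measure="tau_ratio", p_method="chi2").p_value
        assert p_perm == pytest.approx(p_chi2, abs=0.02)

    def test_holm_adjustment_never_exceeds_bonferroni(self, default_cohort):
        bon = subfield_effects(default_cohort.scores, adjust="bonferroni")
        holm = subfield_effects(default_cohort.scores, adjust="holm")
        for (pair_b, _, pb), (pair_h, _, ph) in zip(bon.posthoc, holm.posthoc):
            assert pair_b == pair_h
            assert ph <= pb + 1e-12


class TestWaveClassification:
    def case(self, cid="c1", age=70.0):
        return CaseRecord(case_id=cid, age=age)

    def test_posterior_only_burden_is_first_wave(self):
        rows = [dict(case_id="c1", level=lv, unit="EO", sq=0) for lv in (1, 2, 3, 4)]
        rows += [dict(case_id="c1", level=lv, unit="ECL", sq=3) for lv in (7, 8)]
        wc = classify_wave(matrix_from(rows), self.case())
        assert wc.call == "first_wave" and wc.anterior_burden == 0

    def test_bilateral_burden_is_second_wave(self):
        rows = [dict(case_id="c1", level=lv, unit="EO", sq=3) for lv in (1, 2)]
        rows += [dict(case_id="c1", level=lv, unit="ECL", sq=3) for lv in (7, 8)]
        wc = classify_wave(matrix_from(rows), self.case())
        assert wc.call == "second_wave"

    def test_cutoff_is_inclusive(self):
        rows = [dict(case_id="c1", level=1, unit="EO", sq=2),
                dict(case_id="c1", level=8, unit="ECL", sq=2)]
        assert classify_wave(matrix_from(rows), self.case()).call == "second_wave"

    def test_missing_anterior_entries_unclassifiable(self):
        rows = [dict(case_id="c1", level=8, unit="ECL", sq=3)]
        with pytest.raises(AnalysisError):
            classify_wave(matrix_from(rows), self.case())


class TestAgeCorrelation:
    def test_perfect_linearity(self):
        rows = [dict(case_id=f"c{i}", level=1, unit="EO", sq=s)
                for i, s in enumerate([1, 2, 3])]
        cases = [CaseRecord(case_id=f"c{i}", age=a) for i, a in enumerate([60, 70, 80])]
        res = gradient.age_anterior_correlation(matrix_from(rows), cases)
        assert res.statistic == pytest.approx(1.0)

    def test_constant_burden_flagged(self):
        rows = [dict(case_id=f"c{i}", level=1, unit="EO", sq=2) for i in range(4)]
        cases = [CaseRecord(case_id=f"c{i}", age=60 + i) for i in range(4)]
        assert gradient.age_anterior_correlation(matrix_from(rows), cases).undefined

    def test_missing_age_cases_excluded(self):
        rows = [dict(case_id=f"c{i}", level=1, unit="EO", sq=s)
                for i, s in enumerate([1, 2, 3, 4])]
        cases = [CaseRecord(case_id="c0", age=60), CaseRecord(case_id="c1", age=70),
                 CaseRecord(case_id="c2", age=80), CaseRecord(case_id="c3", age=None)]
        res = gradient.age_anterior_correlation(matrix_from(rows), cases)
        assert res.n == 3

    def test_too_few_usable_cases_raises(self):
        rows = [dict(case_id="c0", level=1, unit="EO", sq=1),
                dict(case_id="c1", level=1, unit="EO", sq=2)]
        cases = [CaseRecord(case_id="c0", age=60), CaseRecord(case_id="c1", age=70)]
        with pytest.raises(AnalysisError):
            gradient.age_anterior_correlation(matrix_from(rows), cases)


class TestCohortSummary:
    def test_single_case_sd_zero(self):
        s = cohort_summary([CaseRecord(case_id="c", age=70, brain_weight_g=1200)])
        assert s["age"]["sd"] == 0 and s["age"]["mean"] == 70

    def test_missing_values_excluded_from_moments(self):
        s = cohort_summary([
            CaseRecord(case_id="a", age=60, sex="M", hemisphere="LH"),
            CaseRecord(case_id="b", age=None, sex=None, hemisphere="LH"),
        ])
        assert s["age"]["n"] == 1
        assert s["sex_counts"] == {"M": 1, "unknown": 1}
        assert s["hemisphere_counts"] == {"LH": 2}


class TestMatrixValidation:
    def test_duplicate_entries_rejected(self):
        rows = [dict(case_id="c", level=1, unit="EO", sq=1)] * 2
        with pytest.raises(AnalysisError):
            validate_score_matrix(matrix_from(rows))

    def test_anatomically_impossible_unit_rejected(self):
        rows = [dict(case_id="c", level=8, unit="EO", sq=1)]
        with pytest.raises(AnalysisError):
            validate_score_matrix(matrix_from(rows))

    def test_default_cohort_is_valid(self, default_cohort):
        validate_score_matrix(default_cohort.scores)
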