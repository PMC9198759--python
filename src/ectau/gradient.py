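"""Gradient and cohort statistics over subfield tau-score matrices.

A score matrix is a tidy table with one row per (case, AP level, subfield
unit) carrying the ordinal SQ score (0-4) and/or the quantitative tau ratio.
This module implements the statistical battery run on such matrices:

* per-level burden profiles (mean +/- SD across cases and units),
* Spearman rank trend of burden along the anterior-posterior axis,
* Kruskal-Wallis across subfield units with Dunn post-hoc z-tests,
* Mann-Whitney U contrasts of lateral vs medial bifurcations (EI, ECs),
* Pearson correlation of age with anterior (level-1) burden,
* first/second-wave classification of each case, and
* demographic cohort summaries (population-SD divisor).

Rank tests use exact conditional p-values when samples are small (Spearman by
full permutation enumeration for n <= 10; Mann-Whitney by enumeration of rank
assignments for <= 10 per side) and tie-corrected large-sample approximations
otherwise.  Scores are treated as independent observations per (case, level,
unit), mirroring how ordinal pathology scores are usually tested; this is a
documented simplification.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .anatomy import age_group_of, subfields_at_level

__all__ = [
    "CaseRecord",
    "TrendResult",
    "WaveCall",
    "make_score_matrix",
    "validate_score_matrix",
    "level_profile",
    "spearman_trend",
    "level_trend_test",
    "subfield_effects",
    "mann_whitney",
    "medial_lateral_test",
    "classify_wave",
    "age_anterior_correlation",
    "cohort_summary",
    "AnalysisError",
]

ANTERIOR_LEVELS = (1, 2, 3, 4)
POSTERIOR_LEVELS = (5, 6, 7, 8)
DEFAULT_WAVE_CUTOFF = 2.0


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class CaseRecord:
    """Demographics/metadata for one hemisphere (one case)."""

    case_id: str
    hemisphere: str = ""
    age: float | None = None
    sex: str | None = None
    braak_stage: str | None = None
    pmi_h: float | None = None
    brain_weight_g: float | None = None

    @property
    def age_group(self) -> str | None:
        if self.age is None:
            return None
        return age_group_of(self.age)


@dataclass(frozen=True)
class TrendResult:
    statistic_name: str
    statistic: float
    n: int
    p_value: float
    posthoc: list | None = None
    undefined: bool = False
    note: str = ""


@dataclass(frozen=True)
class WaveCall:
    case_id: str
    anterior_burden: float
    posterior_burden: float
    call: str  # "first_wave" | "second_wave"
    cutoff: float = DEFAULT_WAVE_CUTOFF


# --- score-matrix plumbing ----------------------------------------------------

MATRIX_COLUMNS = ["case_id", "level", "unit", "sq", "tau_ratio"]


def make_score_matrix(entries) -> pd.DataFrame:
    """Build a tidy score matrix from (case_id, level, unit, sq[, tau_ratio]) rows."""
    df = pd.DataFrame(entries)
    for col in MATRIX_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[MATRIX_COLUMNS]


def validate_score_matrix(matrix: pd.DataFrame, check_anatomy: bool = True) -> None:
    """Check uniqueness of (case, level, unit) and anatomical admissibility."""
    if matrix.duplicated(subset=["case_id", "level", "unit"]).any():
        raise AnalysisError("duplicate (case, level, unit) entries in score matrix")
    sq = matrix["sq"].dropna()
    if ((sq < 0) | (sq > 4)).any():
        raise AnalysisError("SQ scores must lie in 0..4")
    if check_anatomy:
        for level, grp in matrix.groupby("level"):
            allowed = subfields_at_level(int(level), include_perirhinal=True)
            bad = set(grp["unit"]) - allowed
            if bad:
                raise AnalysisError(f"units {sorted(bad)} not expected at level {level}")


def _values(matrix: pd.DataFrame, measure: str) -> pd.DataFrame:
    if measure not in ("sq", "tau_ratio"):
        raise AnalysisError(f"measure must be 'sq' or 'tau_ratio', got {measure!r}")
    out = matrix[["case_id", "level", "unit", measure]].rename(columns={measure: "value"})
    out = out[np.isfinite(out["value"].astype(float))]  # drops NaN and saturated inf
    return out


# --- level profile ------------------------------------------------------------


def level_profile(matrix: pd.DataFrame, measure: str = "sq") -> pd.DataFrame:
    """Mean +/- SD of the measure at each AP level (pooled over cases and units).

    Levels with no usable entries are reported with NaN mean/SD and n = 0
    (explicitly missing, never silently zero).  SD uses the population divisor.
    """
    vals = _values(matrix, measure)
    if vals.empty:
        raise AnalysisError("score matrix has no usable entries")
    rows = []
    for level in range(1, 9):
        v = vals.loc[vals["level"] == level, "value"].to_numpy(dtype=float)
        if v.size == 0:
            rows.append({"level": level, "mean": np.nan, "sd": np.nan, "n": 0})
        else:
            rows.append(
                {"level": level, "mean": v.mean(), "sd": v.std(ddof=0), "n": v.size}
            )
    return pd.DataFrame(rows)


# --- Spearman with exact small-sample p --------------------------------------


@lru_cache(maxsize=10)
def _all_perms(n: int) -> np.ndarray:
    # cached permutation index matrix; n <= 10 (3.6M x 10 int8 = 36 MB at most)
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho, conditioning on ties."""
    n = xr.size
    center = n * xr.mean() * yr.mean()
    t_obs = abs(float(xr @ yr) - center)
    eps = 1e-9 * max(1.0, t_obs)
    s = yr[_all_perms(n)] @ xr
    return float((np.abs(s - center) >= t_obs - eps).mean())


def spearman_trend(x, y, exact_max_n: int = 10) -> TrendResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p-value by exact permutation enumeration for n <= ``exact_max_n``
    (conditioning on the observed tie pattern), t-approximation otherwise.
    Constant input yields an undefined, flagged result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise AnalysisError(f"need >= 3 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TrendResult("spearman_rho", math.nan, n, math.nan, undefined=True,
                           note="constant input")
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    if n <= exact_max_n:
        p = _spearman_exact_p(xr, yr)
        note = "exact permutation p"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        note = "t approximation"
    return TrendResult("spearman_rho", rho, n, p, note=note)


def level_trend_test(matrix: pd.DataFrame, measure: str = "sq",
                     n_perm: int = 2000, perm_seed: int = 0) -> TrendResult:
    """Anterior-posterior trend: Spearman rho of AP level vs per-level mean.

    The statistic is the rank correlation between the level indices and the
    per-level mean burden (the profile actually plotted for such gradients).
    Because the per-level means pool different numbers of (case, unit)
    entries, their variances differ, so the p-value comes from permuting the
    level labels of the underlying entries (a conditional test that respects
    the unbalanced design) rather than from the n=8 rank-permutation null.
    """
    vals = _values(matrix, measure)
    if vals.empty:
        raise AnalysisError("score matrix has no usable entries")
    v = vals["value"].to_numpy(dtype=float)
    lv = vals["level"].to_numpy(dtype=int)
    levels = np.unique(lv)
    if levels.size < 3:
        raise AnalysisError("need >= 3 levels with data")
    onehot = (lv[:, None] == levels[None, :]).astype(float)
    onehot /= onehot.sum(axis=0, keepdims=True)
    means = v @ onehot
    if np.ptp(means) == 0:
        return TrendResult("spearman_rho", math.nan, levels.size, math.nan,
                           undefined=True, note="constant level means")
    lr = sps.rankdata(levels)

    def _rho(m: np.ndarray) -> np.ndarray:
        mr = sps.rankdata(m, axis=-1)
        mrc = mr - mr.mean(axis=-1, keepdims=True)
        lrc = lr - lr.mean()
        denom = np.sqrt((mrc**2).sum(axis=-1) * (lrc**2).sum())
        return (mrc @ lrc) / denom

    rho_obs = float(_rho(means[None, :])[0])
    rng = np.random.default_rng(perm_seed)
    perms = rng.permuted(np.broadcast_to(v, (n_perm, v.size)), axis=1)
    rho_perm = _rho(perms @ onehot)
    exceed = int((np.abs(rho_perm) >= abs(rho_obs) - 1e-12).sum())
    p = (1 + exceed) / (n_perm + 1)
    return TrendResult("spearman_rho", rho_obs, levels.size, p,
                       note=f"level-label permutation p ({n_perm} shuffles)")


# --- Kruskal-Wallis + Dunn ----------------------------------------------------


def _dunn_posthoc(groups: dict[str, np.ndarray], adjust: str) -> list[tuple]:
    pooled = np.concatenate(list(groups.values()))
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    pos = 0
    for name, g in groups.items():
        mean_ranks[name] = ranks[pos : pos + g.size].mean()
        sizes[name] = g.size
        pos += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    names = list(groups)
    raw = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            raw.append(((a, b), math.nan, math.nan))
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        raw.append(((a, b), float(z), float(p)))
    m = len(raw)
    if adjust == "bonferroni":
        return [(pair, z, min(1.0, p * m) if np.isfinite(p) else p) for pair, z, p in raw]
    if adjust == "holm":
        order = sorted(range(m), key=lambda i: (np.isnan(raw[i][2]), raw[i][2]))
        adj = [math.nan] * m
        running = 0.0
        for rank, i in enumerate(order):
            p = raw[i][2]
            if not np.isfinite(p):
                continue
            running = max(running, (m - rank) * p)
            adj[i] = min(1.0, running)
        return [(raw[i][0], raw[i][1], adj[i]) for i in range(m)]
    raise AnalysisError(f"unknown multiplicity adjustment {adjust!r}")


def _kw_h(rank_rows: np.ndarray, onehot: np.ndarray, sizes: np.ndarray,
          tie_c: float) -> np.ndarray:
    n = rank_rows.shape[-1]
    rsums = rank_rows @ onehot
    h = 12.0 / (n * (n + 1)) * ((rsums**2) / sizes).sum(axis=-1) - 3 * (n + 1)
    return h / tie_c


def subfield_effects(
    matrix: pd.DataFrame,
    measure: str = "sq",
    group_by: str = "unit",
    adjust: str = "bonferroni",
    p_method: str = "auto",
    n_perm: int = 4000,
    perm_seed: int = 0,
) -> TrendResult:
    """Kruskal-Wallis across groups (subfield units by default, or AP levels),
    with Dunn pairwise z-tests adjusted for multiplicity.

    ``p_method``: "permutation" shuffles group labels (``n_perm`` times) and is
    exact up to Monte Carlo error — the default for the modest, heavily tied
    samples of a 10-case cohort; "chi2" is the classical tie-corrected
    approximation; "auto" picks permutation when the pooled sample has <= 500
    observations.  Identical constant groups leave the tie-corrected H
    undefined; the result is flagged rather than raised.
    """
    if group_by not in ("unit", "level"):
        raise AnalysisError("group_by must be 'unit' or 'level'")
    vals = _values(matrix, measure)
    groups: dict[str, np.ndarray] = {}
    for name, grp in vals.groupby(group_by):
        v = grp["value"].to_numpy(dtype=float)
        if v.size >= 2:
            groups[str(name)] = v
    if len(groups) < 2:
        raise AnalysisError("need >= 2 groups with >= 2 observations each")
    n = sum(g.size for g in groups.values())
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        return TrendResult("kw_H", math.nan, n, math.nan, undefined=True,
                           note="all observations identical; tie correction degenerate")
    if p_method == "auto":
        p_method = "permutation" if n <= 500 else "chi2"

    ranks = sps.rankdata(pooled)
    sizes = np.array([g.size for g in groups.values()], dtype=float)
    onehot = np.zeros((n, len(groups)))
    pos = 0
    for j, g in enumerate(groups.values()):
        onehot[pos : pos + g.size, j] = 1.0
        pos += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_c = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    h_obs = float(_kw_h(ranks[None, :], onehot, sizes, tie_c)[0])

    if p_method == "chi2":
        p = float(sps.chi2.sf(h_obs, len(groups) - 1))
        note = f"df={len(groups) - 1}; chi2 approximation"
    elif p_method == "permutation":
        rng = np.random.default_rng(perm_seed)
        perms = rng.permuted(np.broadcast_to(ranks, (n_perm, n)), axis=1)
        h_perm = _kw_h(perms, onehot, sizes, tie_c)
        p = (1 + int((h_perm >= h_obs - 1e-12).sum())) / (n_perm + 1)
        note = f"df={len(groups) - 1}; group-label permutation p ({n_perm} shuffles)"
    else:
        raise AnalysisError(f"unknown p_method {p_method!r}")
    posthoc = _dunn_posthoc(groups, adjust)
    return TrendResult("kw_H", h_obs, n, p, posthoc=posthoc,
                       note=note + f"; Dunn adjusted by {adjust}")


# --- Mann-Whitney U -----------------------------------------------------------


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating rank assignments.

    Conditions on the observed (possibly tied) pooled ranks, so ties are
    handled exactly.  Returns (U of x, p).
    """
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    le = ge = total = 0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    p = min(1.0, 2.0 * min(le, ge) / total)
    return u_obs, p


def mann_whitney(x, y, exact_max_n: int = 10) -> TrendResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration (tie-aware) when both samples have <= ``exact_max_n``
    observations; otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise AnalysisError("both samples must be nonempty")
    if x.size <= exact_max_n and y.size <= exact_max_n:
        u, p = _exact_mwu_p(x, y)
        note = "exact enumeration"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
        note = "normal approximation with tie correction"
    return TrendResult("mwu_U", u, x.size + y.size, p, note=note)


def medial_lateral_test(matrix: pd.DataFrame, unit_pair: str = "ECs",
                        measure: str = "sq") -> TrendResult:
    """Lateral vs medial burden contrast for a bifurcated subfield (EI or ECs).

    Pools the per-case, per-level scores of the _Lat unit against the _Med
    unit and runs a two-sided Mann-Whitney U (lateral first, so U above its
    midpoint means heavier lateral burden).
    """
    if unit_pair not in ("EI", "ECs"):
        raise AnalysisError("unit_pair must be 'EI' or 'ECs'")
    vals = _values(matrix, measure)
    lat = vals.loc[vals["unit"] == f"{unit_pair}_Lat", "value"].to_numpy(dtype=float)
    med = vals.loc[vals["unit"] == f"{unit_pair}_Med", "value"].to_numpy(dtype=float)
    if lat.size == 0 or med.size == 0:
        raise AnalysisError(f"both {unit_pair}_Lat and {unit_pair}_Med need observations")
    res = mann_whitney(lat, med)
    return TrendResult(res.statistic_name, res.statistic, res.n, res.p_value,
                       note=f"{unit_pair}_Lat vs {unit_pair}_Med; {res.note}")


# --- wave classification and age ----------------------------------------------


def classify_wave(matrix: pd.DataFrame, case: CaseRecord,
                  cutoff: float = DEFAULT_WAVE_CUTOFF) -> WaveCall:
    """Call a case first- or second-wave from its anterior SQ burden.

    Anterior burden is the mean SQ over levels 1-4 (all units present),
    posterior over levels 5-8.  A case whose anterior mean reaches ``cutoff``
    carries pathology at both ends of the EC and is called second-wave.
    """
    vals = _values(matrix, "sq")
    vals = vals[vals["case_id"] == case.case_id]
    ant = vals.loc[vals["level"].isin(ANTERIOR_LEVELS), "value"].to_numpy(dtype=float)
    post = vals.loc[vals["level"].isin(POSTERIOR_LEVELS), "value"].to_numpy(dtype=float)
    if ant.size == 0:
        raise AnalysisError(f"case {case.case_id}: no anterior entries, unclassifiable")
    if post.size == 0:
        raise AnalysisError(f"case {case.case_id}: no posterior entries, unclassifiable")
    a, p = float(ant.mean()), float(post.mean())
    call = "second_wave" if a >= cutoff else "first_wave"
    return WaveCall(case.case_id, a, p, call, cutoff)


def age_anterior_correlation(matrix: pd.DataFrame, cases: list[CaseRecord],
                             level: int = 1) -> TrendResult:
    """Pearson correlation between age and mean SQ at the most anterior level.

    Cases with missing age are excluded (e.g. a hemisphere lacking
    demographics); at least 3 usable cases are required.  Constant burden
    leaves r undefined (flagged).
    """
    vals = _values(matrix, "sq")
    ages, burdens = [], []
    for case in cases:
        if case.age is None:
            continue
        v = vals.loc[(vals["case_id"] == case.case_id) & (vals["level"] == level),
                     "value"].to_numpy(dtype=float)
        if v.size == 0:
            continue
        ages.append(float(case.age))
        burdens.append(float(v.mean()))
    n = len(ages)
    if n < 3:
        raise AnalysisError(f"need >= 3 cases with known age, got {n}")
    ages_a, burd_a = np.array(ages), np.array(burdens)
    if np.ptp(burd_a) == 0 or np.ptp(ages_a) == 0:
        return TrendResult("pearson_r", math.nan, n, math.nan, undefined=True,
                           note="constant input")
    r, p = sps.pearsonr(ages_a, burd_a)
    return TrendResult("pearson_r", float(r), n, float(p))


# --- cohort summaries ----------------------------------------------------------


def _min_max_mean_sd(values: list[float]) -> dict[str, float]:
    v = np.asarray([x for x in values if x is not None], dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {"n": 0, "min": math.nan, "max": math.nan, "mean": math.nan, "sd": math.nan}
    return {
        "n": int(v.size),
        "min": float(v.min()),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=0)),  # population divisor
    }


def cohort_summary(cases: list[CaseRecord]) -> dict:
    """Demographic summary: age and brain weight (min/max/mean/population SD over
    non-missing values) and counts by sex, hemisphere and age group."""
    if not cases:
        raise AnalysisError("empty case list")

    def counts(getter):
        out: dict[str, int] = {}
        for c in cases:
            key = getter(c)
            key = "unknown" if key in (None, "") else str(key)
            out[key] = out.get(key, 0) + 1
        return out

    return {
        "n_cases": len(cases),
        "age": _min_max_mean_sd([c.age for c in cases]),
        "brain_weight_g": _min_max_mean_sd([c.brain_weight_g for c in cases]),
        "sex_counts": counts(lambda c: c.sex),
        "hemisphere_counts": counts(lambda c: c.hemisphere),
        "age_group_counts": counts(lambda c: c.age_group),
        "braak_counts": counts(lambda c: c.braak_stage),
    }
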