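"""End-to-end pipeline: simulate -> quantify -> score -> analyze -> thickness -> heatmap.

One :class:`RunConfig` (YAML-serializable) plus a single root seed drives every
stage; the root seed fans out to named child streams per stage so any stage is
reproducible in isolation.  A run writes tidy CSVs, NIfTI volumes, meshes and
renders under one output directory, together with a JSON statistics report, a
JSON-lines log, and a manifest of SHA-256 checksums for every artifact — two
runs with the same config and seed produce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gradient, heatmap3d, sq_scoring, synthetic, tau_quant, thickness

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Serializable description of one full run."""

    seed: int = 0
    n_slides: int = 4
    slide_tau_fractions: tuple = (0.02, 0.08, 0.15, 0.25)
    slide: dict = field(default_factory=dict)  # SlideSpec overrides
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    threshold_k: float = tau_quant.DEFAULT_K
    wave_cutoff: float = gradient.DEFAULT_WAVE_CUTOFF
    multiplicity: str = "bonferroni"
    voxel_size_mm: float = 0.5
    heatmap_cases: int = 1  # how many cases get meshes/renders

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise PipelineError(f"unknown config keys: {sorted(bad)}")
        if "slide_tau_fractions" in raw:
            raw["slide_tau_fractions"] = tuple(raw["slide_tau_fractions"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["slide_tau_fractions"] = list(d["slide_tau_fractions"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _trend_dict(res: gradient.TrendResult) -> dict:
    d = {
        "statistic_name": res.statistic_name,
        "statistic": None if res.undefined else res.statistic,
        "n": res.n,
        "p_value": None if res.undefined else res.p_value,
        "undefined": res.undefined,
        "note": res.note,
    }
    if res.posthoc is not None:
        d["posthoc"] = [
            {"pair": list(pair), "z": z, "p_adjusted": p} for pair, z, p in res.posthoc
        ]
    return d


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.t0 = time.monotonic()

    def write(self, **record):
        record.setdefault("elapsed_s", round(time.monotonic() - self.t0, 3))
        with open(self.path, "a") as fh:
            fh.write(json.dumps(record, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, outdir, force: bool = False) -> dict:
    """Execute all stages in order; returns the statistics report dict.

    Refuses to write into a non-empty output directory unless ``force`` is
    set.  Any stage failure is re-raised as :class:`PipelineError` naming the
    stage.  The manifest (``manifest.json``) lists every artifact with its
    SHA-256 checksum; the log and the manifest itself are not hashed.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise PipelineError(f"output directory {outdir} is not empty (use force=True)")
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log(outdir / "run_log.jsonl")
    if log.path.exists():
        log.path.unlink()

    streams = {
        name: rng
        for name, rng in zip(
            ("slides", "cohort"),
            np.random.SeedSequence(config.seed).spawn(2),
        )
    }
    artifacts: list[Path] = []
    report: dict = {"seed": config.seed}

    def stage(name):
        def deco(fn):
            try:
                t = time.monotonic()
                fn()
                log.write(stage=name, status="ok", seconds=round(time.monotonic() - t, 3))
            except Exception as exc:  # noqa: BLE001 - abort with stage context
                log.write(stage=name, status="error", error=str(exc))
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        cohort_seed = int(streams["cohort"].generate_state(1)[0] % (2**31))
        spec = synthetic.CohortSpec(**{**config.cohort, "seed": cohort_seed})
        data = synthetic.generate_cohort(spec)
        paths = synthetic.write_cohort_csvs(data, outdir / "cohort")
        artifacts.extend(Path(p) for p in paths.values())
        slide_seeds = streams["slides"].generate_state(config.n_slides) % (2**31)
        slides = []
        slide_dir = outdir / "slides"
        slide_dir.mkdir(exist_ok=True)
        for i in range(config.n_slides):
            frac = config.slide_tau_fractions[i % len(config.slide_tau_fractions)]
            sspec = synthetic.SlideSpec(
                **{**config.slide, "tau_fraction": frac, "seed": int(slide_seeds[i])}
            )
            res = synthetic.generate_slide(sspec)
            spaths = synthetic.write_slide(res, slide_dir / f"slide_{i:02d}")
            artifacts.extend(Path(p) for p in spaths.values())
            slides.append((sspec, res))
        state.update(cohort=data, slides=slides)

    @stage("quantify")
    def _quantify():
        rows = []
        for i, (sspec, res) in enumerate(state["slides"]):
            out = tau_quant.quantify_slide(
                res.image, res.wm_mask, {"GM": res.gm_mask}, res.exclusion_mask,
                tau_quant.ThresholdParams(config.threshold_k),
            )["GM"]
            true_frac = res.tau_mask.sum() / res.gm_mask.sum()
            rows.append(
                dict(slide=i, target_fraction=sspec.tau_fraction,
                     true_fraction=float(true_frac),
                     threshold=out.threshold_used, n_positive=out.n_positive,
                     n_negative=out.n_negative, tau_ratio=out.tau_ratio)
            )
        df = pd.DataFrame(rows)
        path = outdir / "quantification.csv"
        df.to_csv(path, index=False, float_format="%.6f")
        artifacts.append(path)
        state["quant"] = df

    @stage("score")
    def _score():
        rows = []
        for i, (_, res) in enumerate(state["slides"]):
            sc = sq_scoring.score_slide(
                res.image, res.gm_mask, res.wm_mask, res.exclusion_mask,
                k=config.threshold_k,
            )
            rows.append(dict(slide=i, sq=sc.value, nft_class=sc.nft_density_class,
                             nt_class=sc.nt_continuity_class, band=sc.laminar_band_flag))
        df = pd.DataFrame(rows)
        path = outdir / "slide_scores.csv"
        df.to_csv(path, index=False)
        artifacts.append(path)
        scores = state["cohort"].scores
        kap = sq_scoring.cohens_kappa(scores["sq"], scores["sq_rater_b"])
        report["inter_rater"] = {
            "kappa": kap.kappa, "ci95": list(kap.ci95), "n_items": kap.n_items,
            "undefined": kap.undefined,
        }

    @stage("analyze")
    def _analyze():
        data = state["cohort"]
        matrix = data.scores
        profile = gradient.level_profile(matrix, "sq")
        path = outdir / "level_profile.csv"
        profile.to_csv(path, index=False, float_format="%.6f")
        artifacts.append(path)
        report["level_trend"] = _trend_dict(gradient.level_trend_test(matrix, "sq"))
        report["subfield_effects"] = _trend_dict(
            gradient.subfield_effects(matrix, "sq", adjust=config.multiplicity)
        )
        report["level_effects"] = _trend_dict(
            gradient.subfield_effects(matrix, "sq", group_by="level",
                                      adjust=config.multiplicity)
        )
        for pair in ("ECs", "EI"):
            report[f"medial_lateral_{pair}"] = _trend_dict(
                gradient.medial_lateral_test(matrix, pair)
            )
        calls = []
        for case in data.cases:
            wc = gradient.classify_wave(matrix, case, config.wave_cutoff)
            calls.append(
                dict(case_id=wc.case_id, age=case.age,
                     anterior_burden=round(wc.anterior_burden, 4),
                     posterior_burden=round(wc.posterior_burden, 4), call=wc.call)
            )
        report["wave_calls"] = calls
        report["age_anterior"] = _trend_dict(
            gradient.age_anterior_correlation(matrix, data.cases)
        )
        report["cohort_summary"] = gradient.cohort_summary(data.cases)

    @stage("thickness")
    def _thickness():
        data = state["cohort"]
        unit_means = data.thickness.groupby("unit")["thickness_mm"].mean().to_dict()
        measured = []
        volumes = {}
        n_sites = 0
        for case in data.cases:
            cs = data.scores.loc[data.scores["case_id"] == case.case_id]
            vol = synthetic.generate_label_volume(
                cs, unit_means, voxel_size=config.voxel_size_mm
            )
            volumes[case.case_id] = vol
            tbl = thickness.measure_case(vol, case.case_id)
            plans = [
                thickness.plan_samples(vol, u)
                for u in thickness.THICKNESS_UNITS if vol.unit_mask(u).any()
            ]
            n_sites += thickness.count_planned_sites(plans)
            measured.append(tbl)
        measured_df = pd.concat(measured, ignore_index=True)
        path = outdir / "thickness_measured.csv"
        measured_df.to_csv(path, index=False, float_format="%.6f")
        artifacts.append(path)
        report["thickness"] = {
            "planned_sites": n_sites,
            "generated_corr": _trend_dict(
                thickness.thickness_tau_correlation(data.thickness, data.scores)
            ),
            "measured_corr": _trend_dict(
                thickness.thickness_tau_correlation(measured_df, data.scores)
            ),
        }
        state["volumes"] = volumes

    @stage("heatmap")
    def _heatmap():
        import imageio.v3 as iio

        data = state["cohort"]
        hdir = outdir / "heatmaps"
        hdir.mkdir(exist_ok=True)
        for case in data.cases[: config.heatmap_cases]:
            vol = state["volumes"][case.case_id]
            vol.hemisphere = case.hemisphere
            paths = heatmap3d.write_volume(vol, hdir / f"{case.case_id}_labels")
            artifacts.extend(Path(p) for p in paths.values())
            surfaces = heatmap3d.extract_isosurfaces(vol, min_score=1)
            for surf in surfaces:
                p = hdir / f"{case.case_id}_sq{surf.score}.ply"
                heatmap3d.write_surface_ply(surf, p)
                artifacts.append(p)
            mid = vol.data.shape[vol.ap_axis] // 2
            rgb = heatmap3d.render_slice(vol, mid)
            p = hdir / f"{case.case_id}_slice{mid:03d}.png"
            iio.imwrite(p, rgb)
            artifacts.append(p)
            report.setdefault("heatmap", {})[case.case_id] = {
                "n_surfaces": len(surfaces),
                "per_score_voxels": {
                    str(s): int((vol.score_field() == s).sum()) for s in range(5)
                },
            }

    @stage("report")
    def _report():
        lut = outdir / "score_colors_lut.txt"
        sq_scoring.write_color_lut(lut)
        artifacts.append(lut)
        cfg_path = outdir / "config.yaml"
        config.to_yaml(cfg_path)
        artifacts.append(cfg_path)
        rpath = outdir / "report.json"
        with open(rpath, "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        artifacts.append(rpath)
        manifest = {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(artifacts))
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    return report
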