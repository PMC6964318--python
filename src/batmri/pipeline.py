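"""End-to-end pipeline binding all stages on the synthetic cohort.

Stage order: simulate → reconstruct → transform → analyze-global →
mass-energy → analyze-local → report.  Each stage reads and writes
declared NIfTI/CSV/JSON artifacts under the run's output directory, so
stages can be rerun individually; a stage whose upstream artifact is
missing raises :class:`MissingArtifactError` naming the stage to rerun.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .config import ALL_STAGES, RunConfig
from .core import RoiMask, ThresholdRange
from .global_analysis import (SubjectData, binned_volume_change, depot_summary,
                              paired_stats, threshold_sweep, volume_histogram)
from .local_analysis import cluster_elbow, joint_histogram, voxel_deltas
from .mass_energy import depot_totals, energy_threshold_grid, mass_volume_r2
from .phantom import apply_cold_effect, generate_phantom, simulate_echo_series
from .recon import reconstruct_maps


class MissingArtifactError(FileNotFoundError):
    """An upstream stage's output is absent; the message names the stage."""


def _subject_seeds(config: RunConfig) -> np.ndarray:
    rng = np.random.default_rng(config.seed)
    return rng.integers(0, 2 ** 31 - 1, size=(config.n_subjects, 3))


def _sdir(out: Path, i: int) -> Path:
    return out / "subjects" / f"s{i:02d}"


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path}; rerun the '{stage}' stage first")
    return path


def stage_simulate(config: RunConfig, out: Path) -> None:
    seeds = _subject_seeds(config)
    for i, (s_ph, s_cold, s_acq) in enumerate(seeds):
        d = _sdir(out, i)
        d.mkdir(parents=True, exist_ok=True)
        pre = generate_phantom(config.shape, seed=int(s_ph),
                               voxel_volume=config.voxel_volume)
        post = apply_cold_effect(pre, config.cold_effect, seed=int(s_cold))
        for tp, truth in (("pre", pre), ("post", post)):
            io.save_volume(truth.ff_true, d / f"truth_{tp}_ff.nii.gz")
            io.save_volume(truth.t2s_true, d / f"truth_{tp}_t2star.nii.gz")
            io.save_volume(truth.fieldmap_true, d / f"truth_{tp}_fieldmap.nii.gz")
            echoes = simulate_echo_series(truth, config.acquisition,
                                          seed=int(s_acq) + (0 if tp == "pre" else 1))
            io.save_echo_series(echoes, d / f"echoes_{tp}.nii.gz", seed=int(s_acq))
        for name in ("roi", "sat_roi"):
            mask = RoiMask(values=getattr(pre, name).astype(float),
                           voxel_volume=config.voxel_volume,
                           label="supraclavicular" if name == "roi" else "deltoid SAT")
            io.save_mask(mask, d / f"{name}.nii.gz")


def stage_reconstruct(config: RunConfig, out: Path) -> None:
    for i in range(config.n_subjects):
        d = _sdir(out, i)
        for tp in ("pre", "post"):
            echoes = io.load_echo_series(_require(d / f"echoes_{tp}.nii.gz", "simulate"))
            maps = reconstruct_maps(echoes)
            io.save_maps(maps, d / f"recon_{tp}")


def stage_transform(config: RunConfig, out: Path) -> None:
    """Pull thermoneutral ROIs to post-cooling coordinates.

    The synthetic cohort shares one grid between time points, so the
    default registration is the identity; a user-supplied deformation
    field at ``subjects/sNN/deformation.nii.gz`` overrides it.
    """
    from .core import DeformationField
    from .roi_transform import transform_mask
    for i in range(config.n_subjects):
        d = _sdir(out, i)
        mask = io.load_mask(_require(d / "roi.nii.gz", "simulate"))
        field_path = d / "deformation.nii.gz"
        if field_path.exists():
            field = io.load_deformation_field(field_path)
        else:
            field = DeformationField(np.zeros((*mask.values.shape, 3)),
                                     affine=mask.affine.copy())
        io.save_mask(transform_mask(mask, field), d / "roi_transformed.nii.gz")


def _load_subject(config: RunConfig, out: Path, i: int,
                  which_roi: str = "roi") -> SubjectData:
    d = _sdir(out, i)
    roi_file = "roi_transformed.nii.gz" if which_roi == "roi" else "sat_roi.nii.gz"
    dep = "transform" if which_roi == "roi" else "simulate"
    roi = io.load_mask(_require(d / roi_file, dep))
    if config.map_source == "truth":
        ff_pre, _ = io.load_volume(_require(d / "truth_pre_ff.nii.gz", "simulate"))
        ff_post, _ = io.load_volume(d / "truth_post_ff.nii.gz")
        t2_pre, _ = io.load_volume(d / "truth_pre_t2star.nii.gz")
        t2_post, _ = io.load_volume(d / "truth_post_t2star.nii.gz")
    else:
        _require(d / "recon_pre" / "ff.nii.gz", "reconstruct")
        pre = io.load_maps(d / "recon_pre")
        post = io.load_maps(d / "recon_post")
        ff_pre, ff_post = np.nan_to_num(pre.ff), np.nan_to_num(post.ff)
        t2_pre, t2_post = np.nan_to_num(pre.t2star), np.nan_to_num(post.t2star)
    return SubjectData(ff_pre=np.asarray(ff_pre, float), ff_post=np.asarray(ff_post, float),
                       t2_pre=np.asarray(t2_pre, float), t2_post=np.asarray(t2_post, float),
                       roi_pre=roi, roi_post=roi)


def stage_analyze_global(config: RunConfig, out: Path) -> None:
    gdir = out / "global"
    gdir.mkdir(parents=True, exist_ok=True)
    subjects = [_load_subject(config, out, i) for i in range(config.n_subjects)]
    sat = [_load_subject(config, out, i, which_roi="sat_roi")
           for i in range(config.n_subjects)]

    rows = []
    for lo, up in config.threshold_ranges:
        rng = ThresholdRange(lo, up, min_lower=config.lower_min)
        for i, s in enumerate(subjects):
            for tp, ff, t2, roi in (("thermoneutral", s.ff_pre, s.t2_pre, s.roi_pre),
                                    ("post_cooling", s.ff_post, s.t2_post, s.roi_post)):
                summ = depot_summary(ff, t2, roi, rng, tp)
                rows.append({"subject": i, "range": f"{lo:g}-{up:g}", "timepoint": tp,
                             "vol_bat_ml": summ.vol_bat, "ff_glob_pct": summ.ff_glob,
                             "t2_glob_ms": summ.t2_glob, "n_voxels": summ.n_voxels})
    summaries = pd.DataFrame(rows)
    summaries.to_csv(gdir / "summaries.csv", index=False)

    # paired tests per range and quantity (need >= 2 subjects)
    if config.n_subjects >= 2:
        tests = []
        for lo, up in config.threshold_ranges:
            key = f"{lo:g}-{up:g}"
            sub = summaries[summaries["range"] == key]
            for qty in ("vol_bat_ml", "ff_glob_pct", "t2_glob_ms"):
                pre = sub[sub.timepoint == "thermoneutral"].sort_values("subject")[qty]
                post = sub[sub.timepoint == "post_cooling"].sort_values("subject")[qty]
                r = paired_stats(pre.to_numpy(), post.to_numpy())
                tests.append({"range": key, "quantity": qty, **r.__dict__})
        pd.DataFrame(tests).to_csv(gdir / "paired_tests.csv", index=False)

        # SAT control at its dedicated range
        sat_rng = ThresholdRange(*config.sat_range)
        pre = [depot_summary(s.ff_pre, s.t2_pre, s.roi_pre, sat_rng, "thermoneutral").ff_glob
               for s in sat]
        post = [depot_summary(s.ff_post, s.t2_post, s.roi_post, sat_rng, "post_cooling").ff_glob
                for s in sat]
        r = paired_stats(pre, post)
        (gdir / "ff_sat_test.json").write_text(json.dumps(r.__dict__, indent=2))

    # volume histograms (cohort mean) and per-bin volume change
    edges, _ = volume_histogram(subjects[0].ff_pre, subjects[0].roi_pre,
                                config.histogram_bin, (config.lower_min, 100.0))
    hp = np.mean([volume_histogram(s.ff_pre, s.roi_pre, config.histogram_bin,
                                   (config.lower_min, 100.0))[1] for s in subjects], axis=0)
    hq = np.mean([volume_histogram(s.ff_post, s.roi_post, config.histogram_bin,
                                   (config.lower_min, 100.0))[1] for s in subjects], axis=0)
    pd.DataFrame({"ff_lower": edges[:-1], "ff_upper": edges[1:],
                  "thermoneutral_ml": hp, "post_cooling_ml": hq}
                 ).to_csv(gdir / "volume_histogram.csv", index=False)
    binned_volume_change(subjects, config.volume_change_bin,
                         (config.lower_min, 100.0)).to_csv(
        gdir / "volume_change_bins.csv", index=False)

    for qty in ("volume", "ff", "t2star"):
        grid = threshold_sweep(subjects, qty, step=config.sweep_step,
                               lower_min=config.lower_min)
        grid.to_frame().to_csv(gdir / f"sweep_{qty}.csv")


def stage_mass_energy(config: RunConfig, out: Path) -> None:
    edir = out / "energy"
    edir.mkdir(parents=True, exist_ok=True)
    _require(out / "global" / "summaries.csv", "analyze-global")
    subjects = [_load_subject(config, out, i) for i in range(config.n_subjects)]
    rng = ThresholdRange(config.lower_min, 100.0)
    rows = []
    for i, s in enumerate(subjects):
        for tp, ff, roi in (("thermoneutral", s.ff_pre, s.roi_pre),
                            ("post_cooling", s.ff_post, s.roi_post)):
            tab = depot_totals(ff, roi, rng, config.constants, config.histogram_bin)
            tot = tab.loc["total"]
            rows.append({"subject": i, "timepoint": tp,
                         "fat_mass_g": tot.fat_mass_g, "lean_mass_g": tot.lean_mass_g,
                         "fat_volume_ul": tot.fat_volume_ul,
                         "lean_volume_ul": tot.lean_volume_ul,
                         "total_energy_kcal": tot.total_energy_kcal})
    totals = pd.DataFrame(rows)
    totals.to_csv(edir / "totals.csv", index=False)
    with open(edir / "constants.json", "w") as fh:
        json.dump(config.constants.to_dict(), fh, indent=2)

    pre = totals[totals.timepoint == "thermoneutral"].sort_values("subject")
    if config.n_subjects >= 3:
        vol_ml = (pre.fat_volume_ul + pre.lean_volume_ul) / 1000.0
        reg = {}
        for mass_col in ("fat_mass_g", "lean_mass_g"):
            slope, intercept, r2 = mass_volume_r2(vol_ml, pre[mass_col])
            reg[mass_col] = {"slope": slope, "intercept": intercept, "r_squared": r2}
        (edir / "mass_volume_regression.json").write_text(json.dumps(reg, indent=2))

    grid = energy_threshold_grid(subjects, step=config.sweep_step,
                                 lower_min=config.lower_min, constants=config.constants)
    grid.to_frame().to_csv(edir / "sweep_energy.csv")


def stage_analyze_local(config: RunConfig, out: Path) -> None:
    ldir = out / "local"
    ldir.mkdir(parents=True, exist_ok=True)
    tables = []
    for i in range(config.n_subjects):
        s = _load_subject(config, out, i)
        from .core import QuantitativeMaps
        blank = np.zeros_like(s.ff_pre)
        mp = QuantitativeMaps(water=blank, fat=blank, ff=s.ff_pre, t2star=s.t2_pre,
                              fieldmap=blank, fit_ok=np.ones_like(blank, bool))
        mq = QuantitativeMaps(water=blank, fat=blank, ff=s.ff_post, t2star=s.t2_post,
                              fieldmap=blank, fit_ok=np.ones_like(blank, bool))
        tab = voxel_deltas(mp, mq, s.roi_pre, smoothing_k=config.smoothing_k)
        tab.insert(0, "subject", i)
        tab.to_csv(ldir / f"voxel_table_s{i:02d}.csv", index=False)
        tables.append(tab)
    pooled = pd.concat(tables, ignore_index=True)

    counts, xe, ye = joint_histogram(pooled.ff_pre * 100.0, pooled.dff * 100.0,
                                     np.arange(0, 101, 1.0), np.arange(-25, 25.5, 1.0))
    hist = pd.DataFrame(counts, index=pd.Index(xe[:-1], name="ff_pre_pct"),
                        columns=ye[:-1])
    hist.to_csv(ldir / "joint_hist_ff_dff.csv")

    result = cluster_elbow(pooled, k_max=config.cluster_k_max,
                           variance_cutoff=config.cluster_cutoff,
                           seed=config.seed, n_restarts=config.cluster_restarts)
    report = {
        "k_selected": result.k_selected,
        "explained_variance_curve": list(map(float, result.explained_variance_curve)),
        "columns": result.columns,
        "clusters": result.summaries.to_dict(orient="records"),
    }
    (ldir / "clusters.json").write_text(json.dumps(report, indent=2))


def stage_report(config: RunConfig, out: Path) -> None:
    report = {"version": __version__, "python": platform.python_version(),
              "config": config.to_dict(), "artifacts": sorted(
                  str(p.relative_to(out)) for p in out.rglob("*") if p.is_file())}
    (out / "report.json").write_text(json.dumps(report, indent=2))


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "reconstruct": stage_reconstruct,
    "transform": stage_transform,
    "analyze-global": stage_analyze_global,
    "mass-energy": stage_mass_energy,
    "analyze-local": stage_analyze_local,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Execute the requested pipeline stages in canonical order.

    Returns a run report dict (also written to ``report.json`` when the
    ``report`` stage runs); records versions, seeds and per-stage timings.
    """
    stages = list(ALL_STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    timings = {}
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        _STAGE_FUNCS[stage](config, out)
        timings[stage] = time.perf_counter() - t0
    return {"outdir": str(out), "stages": stages, "timings_s": timings,
            "seed": config.seed, "version": __version__}
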