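"""Config-driven pipeline orchestration and cross-modality comparison.

Three branches produce alignment measures for the CE / ME / MC sampling
locations of a construct:

* **PRS** — preprocess polarized Raman spectra, project onto the master
  loading, fit the polarization sine per measurement point, summarize
  amplitude A and angle beta_PRS per location;
* **image** — discrete-fiber alignment index S and mean axis from
  CT-FIRE-style fiber tables (or synthetic wrapped-normal populations);
* **model** — FE contraction simulation fitted to the measured area
  shrinkage, then local alignment factor alpha, angle beta_model and the
  embedded-fiber equivalent S.

The modalities are bridged through the alignment aspect ratio
gamma = metric / metric_max (A for PRS, alpha for the model, S for
images), and angles are compared on the axial circle (differences are at
most 90 degrees).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fem, fiber_stats, kinematics, pca_alignment, preprocess, raman_io
from . import synthetic

LOCATIONS = ("CE", "ME", "MC")


class PipelineError(RuntimeError):
    pass


def axial_difference_deg(a: float, b: float) -> float:
    """Difference between two axial angles, in [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


# ---------------------------------------------------------------------------
# branch drivers
# ---------------------------------------------------------------------------

def prs_branch(sset: raman_io.SpectrumSet,
               reference: raman_io.SpectrumSet,
               cfg: preprocess.PreprocessConfig | None = None,
               pooled: bool = False) -> dict[str, pca_alignment.RegionAlignment]:
    """Preprocess, project and sine-fit one sample's PRS acquisitions.

    Default mode fits one sine per measurement point (roi, point) and
    summarizes per location; ``pooled=True`` fits all points of a location
    jointly instead.
    """
    cfg = cfg or preprocess.PreprocessConfig()
    ref_pp = preprocess.preprocess(
        reference, preprocess.PreprocessConfig(
            baseline_order=cfg.baseline_order, sg_polyorder=cfg.sg_polyorder,
            sg_window=cfg.sg_window, crop_lo=cfg.crop_lo, crop_hi=cfg.crop_hi,
            average_replicates=False))
    loading = pca_alignment.derive_loading(ref_pp)
    test_pp = preprocess.preprocess(sset, cfg)
    scores = pca_alignment.project_pc1(test_pp, loading)

    by_loc: dict[str, dict] = {}
    for meta, score in scores:
        point_key = (meta.roi, meta.point) if not pooled else ("all",)
        by_loc.setdefault(meta.location, {}) \
              .setdefault(point_key, {}) \
              .setdefault(meta.pol_angle_deg, []).append(score)

    summaries = {}
    for loc, points in by_loc.items():
        fits = [pca_alignment.fit_sine(angle_scores)
                for angle_scores in points.values()]
        summaries[loc] = pca_alignment.summarize_region(loc, fits)
    amps = {loc: s.amplitude_mean for loc, s in summaries.items()}
    gammas = pca_alignment.aspect_ratio(amps)
    for loc, s in summaries.items():
        s.gamma = gammas[loc]
    return summaries


def image_branch(fibers: dict[str, fiber_stats.FiberSet]
                 ) -> dict[str, fiber_stats.AlignmentResult]:
    """Discrete-fiber alignment statistics per location."""
    return {loc: fiber_stats.alignment_index(f) for loc, f in fibers.items()}


def model_branch(geometry: fem.Geometry, material: fem.Material,
                 target_area_shrinkage: float = 0.60,
                 sweep: np.ndarray | None = None,
                 n_fibers: int = kinematics.DEFAULT_N_FIBERS
                 ) -> tuple[fem.ShrinkageFit, kinematics.AlignmentMap]:
    """FE best-fit shrinkage run plus its alignment map."""
    mesh = fem.build_mesh(geometry)
    fit = fem.fit_shrinkage_strain(target_area_shrinkage, mesh, material,
                                   sweep=sweep)
    amap = kinematics.alignment_map(mesh, fit.field_best, n_fibers=n_fibers)
    return fit, amap


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def compare(prs: dict[str, pca_alignment.RegionAlignment] | None = None,
            image: dict[str, fiber_stats.AlignmentResult] | None = None,
            model: kinematics.AlignmentMap | None = None) -> pd.DataFrame:
    """Cross-modality table: per (location, modality) gamma, angle and metric.

    gamma normalizes each modality by its own within-sample maximum
    (A/A_max, alpha/alpha_max, S/S_max).  Requires at least two modalities
    with overlapping locations.
    """
    frames = []
    if prs:
        amax = max(s.amplitude_mean for s in prs.values())
        for loc, s in prs.items():
            frames.append({"location": loc, "modality": "PRS",
                           "gamma": s.amplitude_mean / amax,
                           "angle_deg": s.beta_prs_deg,
                           "metric_name": "A", "metric": s.amplitude_mean})
    if image:
        smax = max(r.S for r in image.values())
        for loc, r in image.items():
            frames.append({"location": loc, "modality": "image",
                           "gamma": r.S / smax if smax > 0 else float("nan"),
                           "angle_deg": r.mean_axis_deg,
                           "metric_name": "S", "metric": r.S, "S": r.S})
    if model:
        alpha_max = max(r.alpha for r in model.regions.values())
        for loc, r in model.regions.items():
            frames.append({"location": loc, "modality": "model",
                           "gamma": r.alpha / alpha_max,
                           "angle_deg": r.beta_model_deg,
                           "metric_name": "alpha", "metric": r.alpha,
                           "S": r.S})
    if not frames:
        raise PipelineError("no modality produced results")
    df = pd.DataFrame(frames)
    modalities = df["modality"].unique()
    if len(modalities) < 2:
        raise PipelineError("comparison needs at least two modalities")
    counts = df.groupby("location")["modality"].nunique()
    if not (counts >= 2).any():
        raise PipelineError("no overlapping locations across modalities")
    return df.sort_values(["location", "modality"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# config-driven run
# ---------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "seed": 0,
    "prs": {
        "synthetic": {
            "locations": {"CE": {"mod_depth": 0.55, "phase_deg": 75.0},
                          "ME": {"mod_depth": 0.25, "phase_deg": 45.0},
                          "MC": {"mod_depth": 0.27, "phase_deg": 75.0}},
            "noise_sd": 10.0,
        },
    },
    "image": {
        "synthetic": {
            "locations": {"CE": {"mean_deg": 129.1, "sd_deg": 25.0, "n": 150},
                          "ME": {"mean_deg": 89.2, "sd_deg": 38.0, "n": 150},
                          "MC": {"mean_deg": 96.8, "sd_deg": 37.8, "n": 150}},
        },
    },
    "fem": {
        "geometry": {}, "material": {},
        "target_area_shrinkage": 0.60,
        "sweep": {"lo": 0.0, "hi": 0.7, "step": 0.05},
    },
    "preprocess": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) \
            and isinstance(base.get(k), dict) else v
    return out


def run_pipeline(config_path, out_dir=None) -> Path:
    """Execute every configured branch and write all artifacts to a run dir.

    The run directory contains intermediate CSVs, the comparison tables
    (``comparison_gamma.csv``, ``comparison_angles.csv``,
    ``comparison_S.csv``), VTK fields for the model branch, polar-histogram
    PNGs, and ``run_log.json`` with the config hash and seeds.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        user_cfg = yaml.safe_load(fh) or {}
    cfg = _merge(_DEFAULT_CONFIG, user_cfg)
    seed = int(cfg.get("seed", 0))
    out_dir = Path(out_dir) if out_dir else config_path.parent / "run"
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]

    stage = "config"
    last_good: Path | None = None
    prs_res = image_res = amap = None
    fit = None
    try:
        if cfg.get("prs"):
            stage = "prs"
            prs_res = _run_prs_branch(cfg, seed, out_dir)
            last_good = out_dir / "prs_regions.csv"
        if cfg.get("image"):
            stage = "image"
            image_res = _run_image_branch(cfg, seed, out_dir)
            last_good = out_dir / "image_regions.csv"
        if cfg.get("fem"):
            stage = "model"
            fit, amap = _run_model_branch(cfg, out_dir)
            last_good = out_dir / "alignment_map.csv"
        stage = "compare"
        table = compare(prs=prs_res, image=image_res, model=amap)
        _write_comparisons(table, out_dir)
    except Exception as exc:
        raise PipelineError(
            f"pipeline failed at stage {stage!r} "
            f"(last good artifact: {last_good}): {exc}") from exc

    log = {"config_hash": cfg_hash, "seed": seed,
           "stages": [m for m, r in (("prs", prs_res), ("image", image_res),
                                     ("model", amap)) if r is not None]}
    if fit is not None:
        log["eps_best"] = fit.eps_best
        log["shrinkage_by_eps"] = {str(k): v
                                   for k, v in fit.shrinkage_by_eps.items()}
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return out_dir


def _run_prs_branch(cfg, seed, out_dir):
    pcfg = preprocess.PreprocessConfig(**cfg.get("preprocess", {}))
    prs_cfg = cfg["prs"]
    if "manifest" in prs_cfg:
        sset = raman_io.read_spectra(prs_cfg["manifest"],
                                     prs_cfg.get("data_dir"))
        reference = raman_io.read_spectra(prs_cfg["reference_manifest"],
                                          prs_cfg.get("reference_data_dir"))
    else:
        syn = prs_cfg["synthetic"]
        spectra = []
        for i, (loc, p) in enumerate(sorted(syn["locations"].items())):
            model = synthetic.SpectrumModel(
                bands=synthetic._default_bands(p["mod_depth"]),
                phase_deg=p["phase_deg"],
                noise_sd=syn.get("noise_sd", 10.0), seed=seed + 11 * (i + 1))
            spectra.extend(synthetic.gen_location_acquisitions(
                model, loc).spectra)
        sset = raman_io.SpectrumSet(spectra)
        reference = synthetic.gen_reference_set(
            synthetic.SpectrumModel(bands=synthetic._default_bands(0.8),
                                    phase_deg=0.0, noise_sd=8.0, seed=seed))
    res = prs_branch(sset, reference, pcfg)
    pd.DataFrame([asdict(s) for _, s in sorted(res.items())]) \
        .to_csv(out_dir / "prs_regions.csv", index=False)
    return res


def _run_image_branch(cfg, seed, out_dir):
    img_cfg = cfg["image"]
    fibers: dict[str, fiber_stats.FiberSet] = {}
    if "tables" in img_cfg:
        for loc, path in img_cfg["tables"].items():
            fibers[loc] = fiber_stats.read_fiber_table(path)
    else:
        for i, (loc, p) in enumerate(sorted(
                img_cfg["synthetic"]["locations"].items())):
            fibers[loc] = synthetic.gen_fiber_angles(synthetic.FiberModel(
                n=p.get("n", 150), mean_deg=p["mean_deg"],
                sd_deg=p["sd_deg"], seed=seed + 101 * (i + 1)))
    res = image_branch(fibers)
    pd.DataFrame([{"location": loc, **asdict(r)}
                  for loc, r in sorted(res.items())]) \
        .to_csv(out_dir / "image_regions.csv", index=False)
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        for loc, f in fibers.items():
            ax = fiber_stats.plot_polar_histogram(f, title=loc)
            ax.figure.savefig(out_dir / f"polar_{loc}.png", dpi=100)
            plt.close(ax.figure)
    except Exception:
        pass  # plotting is best-effort; metrics are already on disk
    return res


def _run_model_branch(cfg, out_dir):
    fem_cfg = cfg["fem"]
    geometry = fem.Geometry(**fem_cfg.get("geometry", {}))
    material = fem.Material(**fem_cfg.get("material", {}))
    sw = fem_cfg.get("sweep", {})
    sweep = np.round(np.arange(sw.get("lo", 0.0),
                               sw.get("hi", 0.7) + 1e-9,
                               sw.get("step", 0.05)), 10)
    mesh = fem.build_mesh(geometry)
    fit = fem.fit_shrinkage_strain(fem_cfg.get("target_area_shrinkage", 0.60),
                                   mesh, material, sweep=sweep)
    amap = kinematics.alignment_map(mesh, fit.field_best)
    amap.to_dataframe().to_csv(out_dir / "alignment_map.csv", index=False)
    cell = amap.element_ids
    beta_full = np.full(mesh.n_elements, np.nan)
    alpha_full = np.full(mesh.n_elements, np.nan)
    alpha_full[cell] = amap.alpha
    beta_full[cell] = amap.beta_model_deg
    fem.write_vtk(out_dir / "deformed.vtk", mesh,
                  point_data={"displacement": fit.field_best.u},
                  cell_data={"alpha": alpha_full, "beta_model": beta_full})
    return fit, amap


def _write_comparisons(table: pd.DataFrame, out_dir: Path) -> None:
    table.to_csv(out_dir / "comparison_full.csv", index=False)
    table.pivot(index="location", columns="modality", values="gamma") \
        .to_csv(out_dir / "comparison_gamma.csv")
    table.pivot(index="location", columns="modality", values="angle_deg") \
        .to_csv(out_dir / "comparison_angles.csv")
    if "S" in table.columns:
        # direct S comparison: image S vs model embedded-fiber equivalent S
        table.dropna(subset=["S"]) \
            .pivot(index="location", columns="modality", values="S") \
            .to_csv(out_dir / "comparison_S.csv")
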