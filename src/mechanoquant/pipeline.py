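"""Stage orchestration: run a configured pipeline stage end-to-end.

Every stage reads only its configured inputs, writes only under the
configured output directory, and drops a provenance JSON
(`<output>.provenance.json`) recording tool version, config hash, input
hashes and seed next to its primary output.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd
import tifffile

from . import afm_indentation as afm
from . import image_morphometry as morph
from . import pillar_tfm as tfm
from . import quant_stats as qs
from . import synthetic_data as synth
from .config import RunConfig
from .io_utils import ProvenanceRecord, validate_io

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def _write_provenance(out_path: str, config: RunConfig,
                      inputs: list[str]) -> None:
    rec = ProvenanceRecord.for_run(config.to_dict(), inputs, seed=config.seed)
    rec.to_json(out_path + ".provenance.json")


def _flags_from_mask(mask: np.ndarray | None,
                     positions: np.ndarray) -> np.ndarray | None:
    if mask is None:
        return None
    idx = np.round(positions).astype(int)
    h, w = mask.shape
    inside = ((idx[:, 0] >= 0) & (idx[:, 0] < w)
              & (idx[:, 1] >= 0) & (idx[:, 1] < h))
    flags = np.zeros(positions.shape[0], bool)
    flags[inside] = mask[idx[inside, 1], idx[inside, 0]] > 0
    return flags


def run_pipeline(config: RunConfig) -> dict:
    """Execute one configured stage; returns a dict of output paths and
    headline numbers."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    logging.basicConfig(level=config.log_level.replace("WARN", "WARNING"))
    stage = config.stage
    handler = _STAGES.get(stage)
    if handler is None:
        raise ValueError(f"unknown stage {stage!r}")
    return handler(config)


# ----------------------------------------------------------------- simulate

def _simulate_pillars(cfg: RunConfig) -> dict:
    scene = synth.make_pillar_scene(seed=cfg.seed, **cfg.params)
    out = os.path.join(cfg.out_dir, "pillars.tif")
    synth.gen_pillar_timelapse(scene, out_path=out)
    _write_provenance(out, cfg, [])
    return {"stack": out, "truth": out[:-4] + ".truth.json",
            "n_pillars": scene.n_pillars}


def _simulate_curve(cfg: RunConfig) -> dict:
    truth = synth.CurveTruth(seed=cfg.seed, **cfg.params)
    curve = synth.gen_force_curve(truth)
    out = os.path.join(cfg.out_dir, "curve.csv")
    curve.to_csv(out)
    truth.to_json(out[:-4] + ".truth.json")
    _write_provenance(out, cfg, [])
    return {"curve": out, "truth": out[:-4] + ".truth.json"}


def _simulate_blobs(cfg: RunConfig) -> dict:
    scene = synth.make_blob_scene(seed=cfg.seed, **cfg.params)
    img = synth.gen_blob_image(scene)
    out = os.path.join(cfg.out_dir, "blobs.tif")
    tifffile.imwrite(out, np.clip(np.rint(img), 0, 65535).astype(np.uint16))
    mask_out = os.path.join(cfg.out_dir, "cell_mask.tif")
    tifffile.imwrite(mask_out, scene.cell_mask.astype(np.uint16))
    scene.to_json(out[:-4] + ".truth.json")
    _write_provenance(out, cfg, [])
    return {"image": out, "mask": mask_out, "truth": out[:-4] + ".truth.json",
            "n_blobs": scene.n_blobs}


def _simulate_fibers(cfg: RunConfig) -> dict:
    img, record = synth.gen_fiber_image(seed=cfg.seed, **cfg.params)
    out = os.path.join(cfg.out_dir, "fibers.tif")
    tifffile.imwrite(out, np.clip(np.rint(img), 0, 65535).astype(np.uint16))
    record = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
              for k, v in record.items()}
    with open(out[:-4] + ".truth.json", "w") as fh:
        json.dump(record, fh, indent=1)
    _write_provenance(out, cfg, [])
    return {"image": out, "truth": out[:-4] + ".truth.json"}


def _simulate_groups(cfg: RunConfig) -> dict:
    params = dict(cfg.params)
    means = {}
    for key, mu in params.pop("means").items():
        parts = tuple(key.split(":"))
        means[parts if len(parts) > 1 else parts[0]] = float(mu)
    df = synth.gen_group_table(means, seed=cfg.seed, **params)
    out = os.path.join(cfg.out_dir, "groups.csv")
    df.to_csv(out, index=False)
    _write_provenance(out, cfg, [])
    return {"table": out, "n_rows": len(df)}


# ------------------------------------------------------------------ analyse

def _track_pillars(cfg: RunConfig) -> dict:
    stack = validate_io(cfg.inputs["stack"], "tiff_stack")
    ref_mask = (validate_io(cfg.inputs["ref_mask"], "mask_tiff")
                if "ref_mask" in cfg.inputs else None)
    cell_mask = (validate_io(cfg.inputs["cell_mask"], "mask_tiff")
                 if "cell_mask" in cfg.inputs else None)
    p = cfg.params
    spacing = float(p.get("spacing_hint_px", 12.0))
    rest = tfm.detect_pillars(stack[0], spacing)
    ref_flags = _flags_from_mask(ref_mask, rest)
    tracks = tfm.track_pillars(
        stack, rest, spacing_px=spacing,
        window_px=p.get("window_px"),
        reference_flags=ref_flags,
        pixel_size_um=cfg.pixel_size_um,
        frame_interval_s=float(p.get("frame_interval_s", 2.0)))
    drift = tfm.estimate_drift(tracks) if ref_flags is not None \
        and ref_flags.any() else None
    disp = tfm.compute_displacements(tracks, drift)
    cell_flags = _flags_from_mask(cell_mask, rest)
    if cell_flags is None and ref_flags is not None:
        cell_flags = ~ref_flags
    field = tfm.displacements_to_forces(
        disp, float(p["stiffness_nn_per_um"]), cell_flags=cell_flags)

    n, t = disp.shape[0], disp.shape[1]
    rows = pd.DataFrame({
        "pillar_id": np.repeat(np.arange(n), t),
        "frame": np.tile(np.arange(t), n),
        "x_px": tracks.positions[:, :, 0].ravel(),
        "y_px": tracks.positions[:, :, 1].ravel(),
        "ux_um": disp[:, :, 0].ravel(),
        "uy_um": disp[:, :, 1].ravel(),
        "fx_nN": field.forces_nn[:, :, 0].ravel(),
        "fy_nN": field.forces_nn[:, :, 1].ravel(),
        "fmag_nN": np.linalg.norm(field.forces_nn, axis=2).ravel(),
    })
    tracks_out = os.path.join(cfg.out_dir, "pillar_tracks.csv")
    rows.to_csv(tracks_out, index=False, float_format="%.6f")
    peaks_out = os.path.join(cfg.out_dir, "peak_forces.csv")
    pd.DataFrame({"pillar_id": np.arange(n),
                  "peak_force_nN": field.peak_forces_nn}).to_csv(
        peaks_out, index=False, float_format="%.6f")
    summary_out = os.path.join(cfg.out_dir, "cell_summary.json")
    with open(summary_out, "w") as fh:
        json.dump(field.cell_summary, fh, indent=1)
    if p.get("plot"):
        from .plotting import force_vector_map
        force_vector_map(rest, field,
                         os.path.join(cfg.out_dir, "force_map.png"))
    _write_provenance(tracks_out, cfg,
                      [cfg.inputs[k] for k in ("stack", "ref_mask", "cell_mask")
                       if k in cfg.inputs])
    return {"tracks": tracks_out, "peaks": peaks_out, "summary": summary_out,
            **field.cell_summary}


def _fit_afm(cfg: RunConfig) -> dict:
    curves_dir = cfg.inputs["curves"]
    p = cfg.params
    radius = float(p.get("radius_um", 17.5)) * 1e-6
    poisson = float(p.get("poisson", 0.5))
    k = float(p.get("spring_constant", 0.07))
    sens = p.get("sensitivity_m_per_v")
    paths = ([curves_dir] if os.path.isfile(curves_dir) else
             sorted(os.path.join(curves_dir, f)
                    for f in os.listdir(curves_dir) if f.endswith(".csv")
                    and not f.endswith(".truth.csv")))
    rows = []
    for path in paths:
        validate_io(path, "curve_csv")
        curve = afm.ForceCurve.from_csv(path, spring_constant_n_per_m=k)
        sep, force = afm.deflection_to_force(
            curve, sensitivity_m_per_v=sens, spring_constant_n_per_m=k)
        fit = afm.fit_hertz(sep, force, radius_m=radius, poisson=poisson)
        rows.append({"curve_id": os.path.splitext(os.path.basename(path))[0],
                     "E_Pa": fit.youngs_modulus_pa,
                     "contact_height_m": fit.contact_height_m,
                     "rms_residual_N": fit.rms_residual_n,
                     "converged": fit.converged})
    out = os.path.join(cfg.out_dir, "hertz_fits.csv")
    pd.DataFrame(rows).to_csv(out, index=False)
    _write_provenance(out, cfg, paths)
    return {"results": out, "n_curves": len(rows)}


def _quantify_blobs(cfg: RunConfig) -> dict:
    img = validate_io(cfg.inputs["image"], "tiff_stack")
    if img.ndim == 3:
        img = img[0]
    mask = validate_io(cfg.inputs["mask"], "mask_tiff")
    params = morph.SegmentationParams(**cfg.params) if cfg.params \
        else morph.SegmentationParams()
    stats = morph.segment_blobs(img, mask, cfg.pixel_size_um, params)
    out = os.path.join(cfg.out_dir, "blob_stats.json")
    with open(out, "w") as fh:
        json.dump({"count": stats.count,
                   "mean_area_um2": stats.mean_area_um2,
                   "areas_um2": stats.areas_um2.tolist(),
                   "cell_area_um2": morph.cell_area(mask, cfg.pixel_size_um)},
                  fh, indent=1)
    _write_provenance(out, cfg, [cfg.inputs["image"], cfg.inputs["mask"]])
    return {"results": out, "count": stats.count,
            "mean_area_um2": stats.mean_area_um2}


def _coherency(cfg: RunConfig) -> dict:
    img = validate_io(cfg.inputs["image"], "tiff_stack")
    if img.ndim == 3:
        img = img[0]
    mask = (validate_io(cfg.inputs["mask"], "mask_tiff")
            if "mask" in cfg.inputs else None)
    res = morph.coherency(img, mask, sigma=float(cfg.params.get("sigma", 1.0)),
                          rho=float(cfg.params.get("rho", 4.0)))
    out = os.path.join(cfg.out_dir, "coherency.json")
    with open(out, "w") as fh:
        json.dump({"coherency": res.coherency, "sigma_px": res.sigma_px,
                   "rho_px": res.rho_px,
                   "n_mask_pixels": res.n_mask_pixels}, fh, indent=1)
    _write_provenance(out, cfg, [cfg.inputs["image"]])
    return {"results": out, "coherency": res.coherency}


def _coloc(cfg: RunConfig) -> dict:
    img = validate_io(cfg.inputs["image"], "tiff_stack")
    if img.ndim != 3 or img.shape[0] < 2:
        raise ValueError("colocalization needs a 2-channel image stack")
    mask = (validate_io(cfg.inputs["mask"], "mask_tiff")
            if "mask" in cfg.inputs else None)
    res = morph.pearson_coloc(img[0], img[1], mask)
    out = os.path.join(cfg.out_dir, "coloc.json")
    with open(out, "w") as fh:
        json.dump({"pearson_r": res.pearson_r, "n_pixels": res.n_pixels},
                  fh, indent=1)
    _write_provenance(out, cfg, [cfg.inputs["image"]])
    return {"results": out, "pearson_r": res.pearson_r}


# ---------------------------------------------------------------- statistics

def _stats_ttest(cfg: RunConfig) -> dict:
    df = validate_io(cfg.inputs["table"], "group_csv")
    levels = sorted(df["factorA"].unique())
    if len(levels) != 2:
        raise ValueError("t-test needs exactly 2 levels of factorA")
    res = qs.two_sided_t_test(
        df.loc[df["factorA"] == levels[0], "value"],
        df.loc[df["factorA"] == levels[1], "value"],
        welch=bool(cfg.params.get("welch", False)),
        alpha=float(cfg.params.get("alpha", 0.05)))
    out = os.path.join(cfg.out_dir, "ttest.json")
    with open(out, "w") as fh:
        json.dump(res.to_dict(), fh, indent=1)
    _write_provenance(out, cfg, [cfg.inputs["table"]])
    return {"results": out, **res.p_value}


def _stats_anova2(cfg: RunConfig) -> dict:
    df = validate_io(cfg.inputs["table"], "group_csv")
    if "factorB" not in df.columns:
        raise ValueError("two-way ANOVA needs a factorB column")
    res = qs.two_way_anova_tukey(
        df, alpha=float(cfg.params.get("alpha", 0.05)),
        tukey_mode=cfg.params.get("tukey_mode", "cells"))
    out = os.path.join(cfg.out_dir, "anova2.json")
    with open(out, "w") as fh:
        json.dump(res.to_dict(), fh, indent=1)
    if res.post_hoc is not None:
        res.post_hoc.to_csv(os.path.join(cfg.out_dir, "tukey.csv"),
                            index=False)
    _write_provenance(out, cfg, [cfg.inputs["table"]])
    return {"results": out, **res.p_value}


def _stats_ddct(cfg: RunConfig) -> dict:
    df = validate_io(cfg.inputs["table"], "ct_csv")
    res = qs.ddct(df, reference_gene=cfg.params["reference_gene"],
                  calibrator=cfg.params["calibrator"])
    out = os.path.join(cfg.out_dir, "ddct.csv")
    res.to_csv(out, index=False)
    _write_provenance(out, cfg, [cfg.inputs["table"]])
    return {"results": out, "n_samples": len(res)}


_STAGES = {
    "simulate-pillars": _simulate_pillars,
    "simulate-curve": _simulate_curve,
    "simulate-blobs": _simulate_blobs,
    "simulate-fibers": _simulate_fibers,
    "simulate-groups": _simulate_groups,
    "track-pillars": _track_pillars,
    "fit-afm": _fit_afm,
    "quantify-blobs": _quantify_blobs,
    "coherency": _coherency,
    "coloc": _coloc,
    "stats-ttest": _stats_ttest,
    "stats-anova2": _stats_anova2,
    "stats-ddct": _stats_ddct,
}
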