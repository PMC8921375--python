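"""End-to-end orchestration: single-subject mapping and cohort model building.

``run_subject`` executes segmentation -> registration -> PRM -> cluster
extraction -> predictor assembly -> severity map for one inspiratory /
expiratory pair, writing masks, tables and the severity map plus a
machine-readable report.  ``run_cohort`` pools per-subject cluster tables,
fits the 10-scale models and the backward-selected airflow model, and
evaluates it by repeated five-fold cross-validation.  All randomness flows
from the config seed, and reports contain no wall-clock state, so identical
inputs and seeds reproduce outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from . import __version__
from . import io as vio
from .bprm import aggregate_grid, export_bprm, voxel_contribution
from .config import PipelineConfig
from .core import (
    EXPIRATORY,
    INSPIRATORY,
    ParameterError,
    SeedPointError,
    Volume3D,
)
from .densitometry import binarize, composite_lav, prm_classify
from .lac import (
    assign_regions,
    classify_predominance,
    erosion_depth_map,
    extract_lacs,
    lac_table,
    records_from_table,
)
from .registration import export_landmarks, register_pair
from .scaling_model import (
    AirflowModel,
    PREDICTOR_NAMES,
    ScaleModel,
    assemble_predictors,
    backward_select,
    cross_validate,
    fit_full_model,
    fit_scale_model,
)
from .segmentation import segment_subject, split_left_right, segment_airway, segment_lungs

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Model bundle (airflow model + scale models) serialization
# ---------------------------------------------------------------------------


@dataclass
class ModelBundle:
    airflow: AirflowModel
    scales: dict[str, ScaleModel]

    def to_json(self, path) -> None:
        d = {
            "airflow": self.airflow.to_dict(),
            "scales": {k: v.to_dict() for k, v in self.scales.items()},
            "format": "bprm-model-1",
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ModelBundle":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            airflow=AirflowModel.from_dict(d["airflow"]),
            scales={k: ScaleModel.from_dict(v) for k, v in d["scales"].items()},
        )


def scale_model_from_boundaries(boundaries, provenance="fixed") -> ScaleModel:
    """Build a ScaleModel from known cut points (centers set to bin midpoints)."""
    b = np.asarray(boundaries, dtype=float)
    lo = np.concatenate([[b[0] / 2], b])
    hi = np.concatenate([b, [b[-1] * 2]])
    return ScaleModel(k=b.size + 1, boundaries=b, centers=(lo + hi) / 2,
                      provenance=provenance)


# ---------------------------------------------------------------------------
# Single subject
# ---------------------------------------------------------------------------


def find_trachea_seed(vol: Volume3D, hu_max: float = -950.0) -> tuple[int, int, int]:
    """Locate a trachea voxel: an enclosed air region near the midline in the
    most superior slices."""
    nz, ny, nx = vol.shape
    for z in range(nz - 1, int(0.5 * nz), -1):
        sl = vol.values[z] < hu_max
        if not sl.any():
            continue
        lab, nlab = ndi.label(sl)
        border = np.unique(np.concatenate([
            lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
        best = None
        for lid in range(1, nlab + 1):
            if lid in border:
                continue  # open to the image edge: outside air
            m = lab == lid
            area = int(m.sum())
            if area < 3:
                continue
            cy, cx = ndi.center_of_mass(m)
            d = (cy - ny / 2) ** 2 + (cx - nx / 2) ** 2
            if best is None or d < best[0]:
                best = (d, int(round(cy)), int(round(cx)))
        if best is not None:
            return (z, best[1], best[2])
    raise SeedPointError("no enclosed air region found in the superior slices")


def _provenance(config: PipelineConfig, inputs: dict) -> dict:
    blob = json.dumps({"config": config.to_dict(), "inputs": inputs},
                      sort_keys=True, default=str)
    return {
        "config": config.to_dict(),
        "inputs": inputs,
        "package_version": __version__,
        "content_hash": hashlib.sha256(blob.encode()).hexdigest(),
    }


def run_subject(
    insp,
    exp,
    model: "ModelBundle | str | Path",
    config: PipelineConfig | None = None,
    outdir="bprm_subject",
    seed_point: tuple[int, int, int] | None = None,
    write_volumes: bool = True,
) -> dict:
    """Run the full single-subject pipeline; returns the report dict.

    ``insp``/``exp`` may be file paths or :class:`Volume3D`; ``model`` a
    :class:`ModelBundle` or a path to its JSON.  Stage outputs are written
    under ``outdir``; a cached report is reused when the stored provenance
    hash matches the current config and inputs.
    """
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs = {
        "insp": str(insp) if not isinstance(insp, Volume3D) else "<in-memory>",
        "exp": str(exp) if not isinstance(exp, Volume3D) else "<in-memory>",
        "model": str(model) if not isinstance(model, ModelBundle) else "<in-memory>",
    }
    prov = _provenance(cfg, inputs)
    report_path = outdir / "report.json"
    prov_path = outdir / "provenance.json"
    if report_path.exists() and prov_path.exists() and inputs["insp"] != "<in-memory>":
        try:
            with open(prov_path) as fh:
                if json.load(fh).get("content_hash") == prov["content_hash"]:
                    log.info("reusing cached outputs in %s", outdir)
                    with open(report_path) as fh:
                        return json.load(fh)
        except (json.JSONDecodeError, OSError):
            pass

    if not isinstance(insp, Volume3D):
        insp = vio.read_volume(insp, phase=INSPIRATORY)
    if not isinstance(exp, Volume3D):
        exp = vio.read_volume(exp, phase=EXPIRATORY)
    if not isinstance(model, ModelBundle):
        model = ModelBundle.from_json(model)

    # --- segmentation ------------------------------------------------------
    seed_i = seed_point or find_trachea_seed(insp)
    regions = segment_subject(insp, seed_i, cfg.segmentation)
    # the expiratory trachea sits elsewhere after lung contraction
    if seed_point is not None and exp.values[tuple(seed_point)] < -900:
        seed_e = seed_point
    else:
        seed_e = find_trachea_seed(exp)
    airway_e = segment_airway(exp, seed_e, hu_start=cfg.segmentation.airway_hu_start,
                              hu_stop=cfg.segmentation.airway_hu_stop,
                              hu_step=cfg.segmentation.airway_hu_step,
                              leak_factor=cfg.segmentation.airway_leak_factor,
                              connectivity=cfg.segmentation.connectivity)
    lung_e = segment_lungs(exp, airway_e,
                           upper_bound_hu=cfg.segmentation.lung_upper_bound_hu,
                           closing_radius=cfg.segmentation.closing_radius,
                           connectivity=cfg.segmentation.connectivity)
    side_e = split_left_right(lung_e, spacing=exp.spacing,
                              connectivity=cfg.segmentation.connectivity)
    side_e[airway_e] = 0

    mean_insp = float(insp.values[regions.parenchyma].mean())
    mean_exp = float(exp.values[(side_e > 0)].mean()) if (side_e > 0).any() else np.nan
    swap_suspect = bool(np.isfinite(mean_exp) and mean_exp < mean_insp)
    if swap_suspect:
        warnings.warn(
            "expiratory mean lung HU is below inspiratory; the inputs may be "
            "swapped", stacklevel=2)

    # --- registration ------------------------------------------------------
    side_i = np.where(regions.parenchyma, regions.side, 0)
    reg = register_pair(insp, exp, side_i, side_e,
                        pitch_mm=cfg.registration.pitch_mm,
                        beta=cfg.registration.beta_mm,
                        lam=cfg.registration.lam,
                        outlier_w=cfg.registration.outlier_w,
                        max_iter=cfg.registration.max_iter,
                        tol=cfg.registration.tol)
    coreg = reg.coreg

    # --- densitometry ------------------------------------------------------
    prm = prm_classify(insp, coreg, regions.parenchyma, cfg.thresholds,
                       valid=reg.valid)
    lav = composite_lav(insp, coreg, prm, regions, cfg.thresholds)

    # --- clusters ----------------------------------------------------------
    par_count = regions.parenchyma_count
    emph950 = binarize(insp, regions.parenchyma, cfg.thresholds.emph_severe)
    records_i, labels_i = [], np.zeros(insp.shape, dtype=np.int32)
    if emph950.any():
        depth_i = erosion_depth_map(emph950)
        records_i, labels_i = extract_lacs(
            emph950, depth_i, par_count,
            min_core_depth=cfg.lac.min_core_depth,
            connectivity=cfg.lac.connectivity,
            spacing=insp.spacing, origin=insp.origin,
            phase=INSPIRATORY, threshold=cfg.thresholds.emph_severe,
            min_voxels=cfg.lac.min_voxels)
        records_i = assign_regions(records_i, labels_i, regions)

    airt = binarize(coreg, regions.parenchyma & reg.valid, cfg.thresholds.air_trap)
    records_e, labels_e = [], np.zeros(insp.shape, dtype=np.int32)
    if airt.any():
        depth_e = erosion_depth_map(airt)
        records_e, labels_e = extract_lacs(
            airt, depth_e, par_count,
            min_core_depth=cfg.lac.min_core_depth,
            connectivity=cfg.lac.connectivity,
            spacing=insp.spacing, origin=insp.origin,
            phase=EXPIRATORY, threshold=cfg.thresholds.air_trap,
            min_voxels=cfg.lac.min_voxels)
        records_e = classify_predominance(records_e, labels_e, prm,
                                          ratio_cut=cfg.lac.ratio_cut)
        records_e = assign_regions(records_e, labels_e, regions)

    all_records = records_i + records_e
    predictors = assemble_predictors(all_records, model.scales)
    prediction = float(model.airflow.predict(predictors)[0])

    # --- severity map ------------------------------------------------------
    contributions = voxel_contribution(
        {"emph950": labels_i, "fsad": labels_e},
        {"emph950": records_i, "fsad": records_e},
        model.airflow, model.scales, par_count)
    grid = aggregate_grid(contributions, regions, prm, model.airflow.intercept,
                          cell_size_mm=cfg.grid_cell_mm)
    conservation_err = abs(grid.whole_lung_prediction - prediction) / max(
        abs(prediction), 1e-12)

    # --- outputs -----------------------------------------------------------
    lac_table(all_records).to_csv(outdir / "lacs.csv", index=False)
    lav.to_csv(outdir / "lav.csv", index=False)
    export_bprm(grid, insp, outdir / "bprm_severity.nii.gz",
                outdir / "bprm_cells.csv")
    export_landmarks(outdir / "landmarks.tsv", reg.landmarks_src,
                     reg.landmarks_dst)
    if write_volumes:
        vio.write_labels(prm.classes, insp, outdir / "prm.nii.gz",
                         {"0": "outside", "1": "normal", "2": "fSAD",
                          "3": "emphysema"})
        side_grp = (regions.side.astype(np.uint8) * 10
                    + regions.group.astype(np.uint8))
        vio.write_labels(side_grp, insp, outdir / "regions.nii.gz",
                         {"11": "left-upper", "12": "left-lower",
                          "21": "right-upper", "22": "right-lower"})
        vio.write_volume(coreg, outdir / "coreg_expiratory.nii.gz")

    def lav_row(group):
        sub = lav[(lav["side"] == "both") & (lav["group"] == group)]
        if sub.empty:
            return {}
        return {k: float(sub.iloc[0][k]) for k in sub.columns
                if k.startswith("LAV%")}

    whole = lav[(lav["side"] == "whole")].iloc[0]
    report = {
        "predicted_fev1_fvc": prediction,
        "whole_lung": {k: float(whole[k]) for k in lav.columns
                       if k.startswith("LAV%")},
        "upper": lav_row("upper"),
        "lower": lav_row("lower"),
        "n_parenchyma": par_count,
        "n_lacs_inspiratory": len(records_i),
        "n_lacs_expiratory": len(records_e),
        "n_invalid_warp": prm.n_invalid,
        "mean_lung_hu": {"inspiratory": mean_insp, "expiratory": mean_exp},
        "swap_suspect": swap_suspect,
        "bprm": {
            "cell_size_mm": list(grid.cell_size_mm),
            "n_cells": int(len(grid.cells)),
            "severity_total": float(grid.cells["severity"].sum()),
            "conservation_rel_err": conservation_err,
            "most_severe_cell": grid.cells.iloc[0][
                ["center_z_mm", "center_y_mm", "center_x_mm", "severity"]
            ].to_dict() if len(grid.cells) else None,
        },
    }
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(prov_path, "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def run_cohort(
    manifest,
    config: PipelineConfig | None = None,
    outdir="bprm_cohort",
    scale_models: dict[str, ScaleModel] | None = None,
) -> dict:
    """Fit scales + airflow model + CV report from a cohort manifest.

    ``manifest`` is a DataFrame (or CSV path) either listing per-subject
    cluster tables (columns ``subject_id``, ``lac_csv``, ``fev1_fvc``) or
    carrying the 40 predictor columns directly alongside ``fev1_fvc`` (in
    which case ``scale_models`` must be supplied for later subject
    prediction, e.g. from known boundaries).  Subjects with missing
    spirometry are skipped with a log entry.
    """
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)

    missing = manifest["fev1_fvc"].isna()
    if missing.any():
        for sid in manifest.loc[missing, "subject_id"]:
            log.warning("skipping subject %s: missing spirometry", sid)
        manifest = manifest[~missing].reset_index(drop=True)

    if set(PREDICTOR_NAMES) <= set(manifest.columns):
        X = manifest[PREDICTOR_NAMES].copy()
        if scale_models is None:
            raise ParameterError(
                "predictor-table manifests need scale_models (e.g. from known "
                "boundaries) for later subject prediction")
    else:
        pooled = {"emph950": [], "fsad": []}
        per_subject = []
        for _, row in manifest.iterrows():
            recs = records_from_table(pd.read_csv(row["lac_csv"]))
            per_subject.append(recs)
            for r in recs:
                if r.phase == INSPIRATORY:
                    pooled["emph950"].append(r.lad)
                elif r.lac_class == "fsad" and r.voxel_count > 0:
                    eff = r.lad * r.fsad_voxels / r.voxel_count
                    if eff > 0:
                        pooled["fsad"].append(eff)
        scale_models = {
            t: fit_scale_model(v, k=cfg.model.k_scales, provenance=t)
            for t, v in pooled.items()
        }
        X = pd.DataFrame(
            [assemble_predictors(recs, scale_models) for recs in per_subject])
    y = manifest["fev1_fvc"].to_numpy(dtype=float)

    full = fit_full_model(X, y)
    airflow = backward_select(full, alpha=cfg.model.alpha)
    cv = cross_validate(X, y, folds=cfg.model.folds, repeats=cfg.model.repeats,
                        seed=cfg.model.seed, alpha=cfg.model.alpha,
                        stratify=cfg.model.stratify,
                        reselect=cfg.model.reselect_per_fold)

    bundle = ModelBundle(airflow=airflow, scales=scale_models)
    bundle.to_json(outdir / "model.json")
    Xout = X.copy()
    Xout.insert(0, "subject_id", manifest["subject_id"].to_numpy())
    Xout["fev1_fvc"] = y
    Xout.to_csv(outdir / "predictors.csv", index=False)
    cv.records.to_csv(outdir / "cv.csv", index=False)
    prov = _provenance(cfg, {"n_subjects": int(len(manifest))})
    report = {
        "n_subjects": int(len(manifest)),
        "n_predictors_full": int(X.shape[1]),
        "n_terms_selected": len(airflow.terms),
        "selected_terms": sorted(airflow.term_names),
        "intercept": airflow.intercept,
        "cv_mean_r": cv.mean_r,
        "cv_sd_r": cv.sd_r,
        "cv_repeats": int(cfg.model.repeats),
        "cv_folds": int(cfg.model.folds),
        "seed": int(cfg.model.seed),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
    return report
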