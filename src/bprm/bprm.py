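"""The bullous parametric response map: voxel-wise and grid-wise severity.

Each lesion voxel inherits an equal share of its cluster's modeled
contribution to the predicted FEV1/FVC% deviation from the model intercept
(coefficient times the cluster's LAD%, for clusters whose (scale, group,
type) term survived backward selection).  Summing voxel contributions over a
cluster reproduces beta * LAD% exactly, and summing over the whole lung plus
the intercept reproduces the subject-level prediction — that conservation
identity is the normative definition of "severity" here.  An axis-aligned
grid anchored at the lung bounding box aggregates voxel contributions into
cells ranked most-negative-first (the BLVR target candidates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CatalogError, GridMismatchError, RegionMask, Volume3D
from .densitometry import PRM_EMPHYSEMA, PRM_FSAD, PRM_NORMAL, PRMMap
from .lac import LACRecord
from .scaling_model import AirflowModel, ScaleModel, predictor_name


def voxel_contribution(
    lac_labels: dict[str, np.ndarray],
    lac_catalog: dict[str, list[LACRecord]],
    model: AirflowModel,
    scales: dict[str, ScaleModel],
    parenchyma_count: int,
) -> np.ndarray:
    """Per-voxel severity (FEV1/FVC% units) on the reference grid.

    ``lac_labels``/``lac_catalog`` map lesion type (``"emph950"`` from the
    inspiratory mask, ``"fsad"`` from the co-registered expiratory mask) to a
    cluster label map and its records.  Every voxel of a cluster receives
    ``beta * 100 * lad_effective / voxel_count`` so the cluster total is
    ``beta * LAD%`` exactly; voxels of unselected terms and normal voxels
    contribute 0.
    """
    selected = {t.name: t.coefficient for t in model.terms}
    out = None
    for lesion_type, labels in lac_labels.items():
        if out is None:
            out = np.zeros(labels.shape, dtype=np.float64)
        per_cluster = np.zeros(int(labels.max()) + 1)
        for rec in lac_catalog[lesion_type]:
            if rec.group is None:
                raise CatalogError(f"LAC {rec.id} has no region assignment")
            if lesion_type == "fsad":
                if rec.lac_class == "emph_predominant":
                    continue
                lad_eff = rec.lad * rec.fsad_voxels / rec.voxel_count
            else:
                lad_eff = rec.lad
            if lad_eff <= 0:
                continue
            scale = int(scales[lesion_type].assign([lad_eff])[0])
            beta = selected.get(predictor_name(scale, rec.group, lesion_type))
            if beta is None:
                continue
            per_cluster[rec.id] = beta * 100.0 * lad_eff / rec.voxel_count
        out += per_cluster[labels]
    if out is None:
        raise CatalogError("no lesion label maps given")
    return out


@dataclass
class BPRMGrid:
    """Severity aggregated on an axis-aligned grid over the lung."""

    cell_size_mm: tuple[float, float, float]
    anchor_mm: tuple[float, float, float]  # lung bounding-box corner
    cells: pd.DataFrame  # one row per nonempty cell
    whole_lung_prediction: float
    intercept: float
    cell_index: np.ndarray  # per-voxel flat cell id (-1 outside lung)
    grid_shape: tuple[int, int, int]


def aggregate_grid(
    contributions: np.ndarray,
    regions: RegionMask,
    prm: PRMMap,
    model_intercept: float,
    cell_size_mm: float | tuple[float, float, float] = 20.0,
) -> BPRMGrid:
    """Sum voxel severities into grid cells anchored at the lung bounding box.

    Cells are ranked ascending by severity (most negative = most severe).
    Each cell also reports its parenchyma voxel count and the fractions of
    emphysema / fSAD / normal parenchyma it contains.
    """
    if np.isscalar(cell_size_mm):
        cell_size = (float(cell_size_mm),) * 3
    else:
        cell_size = tuple(float(c) for c in cell_size_mm)
    spacing = np.asarray(regions.spacing, dtype=float)
    if any(c < s for c, s in zip(cell_size, spacing)):
        raise GridMismatchError("cell size must be at least the voxel spacing")
    lung = regions.lung
    if contributions.shape != lung.shape:
        raise GridMismatchError("contribution map and regions disagree on grid")

    idx = np.argwhere(lung)
    coords = idx * spacing + np.asarray(regions.origin)
    anchor = coords.min(axis=0)
    cell = np.floor((coords - anchor) / np.asarray(cell_size)).astype(np.int64)
    grid_shape = tuple(int(c) for c in cell.max(axis=0) + 1)
    flat = np.ravel_multi_index(tuple(cell.T), grid_shape)

    cell_index = np.full(lung.shape, -1, dtype=np.int64)
    cell_index[tuple(idx.T)] = flat

    ncell = int(np.prod(grid_shape))
    sev = np.bincount(flat, weights=contributions[tuple(idx.T)], minlength=ncell)
    par = regions.parenchyma[tuple(idx.T)]
    n_par = np.bincount(flat[par], minlength=ncell)
    prm_at = prm.classes[tuple(idx.T)]
    comp = {}
    for code, cname in ((PRM_EMPHYSEMA, "emphysema"), (PRM_FSAD, "fSAD"),
                        (PRM_NORMAL, "normal")):
        comp[cname] = np.bincount(flat[par & (prm_at == code)], minlength=ncell)

    occupied = np.unique(flat)
    rows = []
    for f in occupied:
        zc, yc, xc = np.unravel_index(f, grid_shape)
        npar = int(n_par[f])
        row = {
            "cell_id": int(f),
            "iz": int(zc), "iy": int(yc), "ix": int(xc),
            "center_z_mm": anchor[0] + (zc + 0.5) * cell_size[0],
            "center_y_mm": anchor[1] + (yc + 0.5) * cell_size[1],
            "center_x_mm": anchor[2] + (xc + 0.5) * cell_size[2],
            "n_parenchyma": npar,
            "severity": float(sev[f]) if npar > 0 else 0.0,
        }
        for cname, counts in comp.items():
            row[f"frac_{cname}"] = counts[f] / npar if npar else 0.0
        rows.append(row)
    cells = pd.DataFrame(rows).sort_values(
        "severity", ascending=True, kind="stable").reset_index(drop=True)
    cells["rank"] = np.arange(1, len(cells) + 1)
    total = float(cells["severity"].sum())
    return BPRMGrid(
        cell_size_mm=cell_size,
        anchor_mm=tuple(anchor),
        cells=cells,
        whole_lung_prediction=model_intercept + total,
        intercept=model_intercept,
        cell_index=cell_index,
        grid_shape=grid_shape,
    )


def severity_volume(grid: BPRMGrid, geometry: Volume3D | RegionMask) -> np.ndarray:
    """Paint each lung voxel with its cell's severity (float32)."""
    shape = geometry.side.shape if isinstance(geometry, RegionMask) else geometry.shape
    if grid.cell_index.shape != tuple(shape):
        raise GridMismatchError("grid was built on a different voxel grid")
    lut = np.zeros(int(np.prod(grid.grid_shape)) + 1, dtype=np.float32)
    for _, row in grid.cells.iterrows():
        lut[int(row["cell_id"])] = row["severity"]
    out = np.zeros(shape, dtype=np.float32)
    inside = grid.cell_index >= 0
    out[inside] = lut[grid.cell_index[inside]]
    return out


def export_bprm(grid: BPRMGrid, geometry: Volume3D, nifti_path, csv_path) -> None:
    """Write the severity NIfTI and the ranked-cell CSV (most severe first)."""
    from . import io as vio

    vol = Volume3D(severity_volume(grid, geometry), geometry.spacing,
                   geometry.origin, phase=geometry.phase)
    vio.write_volume(vol, nifti_path, dtype=np.float32)
    grid.cells.to_csv(csv_path, index=False)


def plot_severity_montage(grid: BPRMGrid, geometry: Volume3D, png_path,
                          n_slices: int = 6) -> None:
    """Optional axial montage with a diverging colormap (most severe = blue)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sev = severity_volume(grid, geometry)
    vmax = max(float(np.abs(sev).max()), 1e-9)
    zs = np.linspace(0, sev.shape[0] - 1, n_slices + 2).astype(int)[1:-1]
    fig, axes = plt.subplots(1, len(zs), figsize=(3 * len(zs), 3))
    for ax, z in zip(np.atleast_1d(axes), zs):
        ax.imshow(sev[z], cmap="RdBu", vmin=-vmax, vmax=vmax, origin="lower")
        ax.set_title(f"z={z}")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(png_path, dpi=100)
    plt.close(fig)
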