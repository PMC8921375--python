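"""Low attenuation clusters: erosion-depth splitting, LAD and classification.

A connected low-attenuation component can merge several bullae through thin
necks.  Iterative erosion assigns each voxel the number of erosion rounds it
survives; plateaus of locally maximal depth (at least ``min_core_depth``
deep) are bulla cores, and every lesion voxel is attributed to exactly one
core by descending-depth region growth (marker-based watershed on the
negated depth).  Components without a qualifying core stay whole.  Each
cluster's low attenuation density (LAD) is its voxel count over the
parenchyma count, so the LADs of one mask sum exactly to LAV%/100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.segmentation import watershed

from .core import (
    GROUP_NAMES,
    SIDE_NAMES,
    EXPIRATORY,
    ParameterError,
    PhaseError,
    RegionMask,
)
from .densitometry import PRM_EMPHYSEMA, PRM_FSAD, PRMMap

_STRUCT3 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class LACRecord:
    """One low attenuation cluster and its derived measures."""

    id: int
    phase: str  # inspiratory | expiratory
    threshold: float
    voxel_count: int
    lad: float  # fraction of parenchyma, 0 < lad <= 1
    max_erosion_depth: int
    centroid_mm: tuple[float, float, float]
    side: str | None = None  # left | right
    group: str | None = None  # upper | lower
    lac_class: str = "plain"  # plain | emph_predominant | fsad
    fsad_voxels: int = 0
    small: bool = False  # below the configured minimum size (kept, flagged)


def erosion_depth_map(lesion: np.ndarray) -> np.ndarray:
    """Erosion survival depth per voxel (3x3x3 structuring element).

    Boundary voxels have depth 0; iteration stops when the mask is empty.
    """
    lesion = np.asarray(lesion, dtype=bool)
    if not np.any(lesion):
        raise ParameterError("lesion mask is empty")
    depth = np.zeros(lesion.shape, dtype=np.int32)
    current = lesion
    while True:
        current = ndi.binary_erosion(current, structure=_STRUCT3)
        if not np.any(current):
            break
        depth[current] += 1
    return depth


def _cores(depth: np.ndarray, lesion: np.ndarray, min_core_depth,
           struct: np.ndarray) -> np.ndarray:
    """Connected components of local-maximum depth plateaus (bool mask)."""
    if np.isinf(min_core_depth):
        return np.zeros(lesion.shape, dtype=bool)
    local_max = depth >= ndi.grey_dilation(depth, footprint=struct)
    return lesion & local_max & (depth >= min_core_depth)


def extract_lacs(
    lesion: np.ndarray,
    depth: np.ndarray,
    parenchyma_count: int,
    min_core_depth: float = 2,
    connectivity: int = 26,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    phase: str = "inspiratory",
    threshold: float = -950.0,
    min_voxels: int = 8,
) -> tuple[list[LACRecord], np.ndarray]:
    """Split a lesion mask into low attenuation clusters.

    Returns ``(records, label_map)`` where ``label_map`` assigns every lesion
    voxel to exactly one cluster id (1-based).  ``min_core_depth = inf``
    degenerates to plain connected-component labeling.
    """
    lesion = np.asarray(lesion, dtype=bool)
    if connectivity == 26:
        struct = _STRUCT3
    elif connectivity == 6:
        struct = ndi.generate_binary_structure(3, 1)
    else:
        raise ParameterError("connectivity must be 6 or 26")
    if parenchyma_count <= 0:
        raise ParameterError("parenchyma_count must be positive")

    comp, ncomp = ndi.label(lesion, structure=struct)
    if ncomp == 0:
        return [], np.zeros(lesion.shape, dtype=np.int32)

    core_mask = _cores(depth, lesion, min_core_depth, struct)
    markers, nmark = ndi.label(core_mask, structure=struct)

    # components without any qualifying core stay whole: one marker each
    comp_ids_with_core = np.unique(comp[core_mask])
    next_id = nmark + 1
    coreless = np.setdiff1d(np.arange(1, ncomp + 1), comp_ids_with_core)
    if coreless.size:
        coreless_mask = np.isin(comp, coreless)
        markers = markers.copy()
        markers[coreless_mask] = comp[coreless_mask] + nmark
        next_id = nmark + ncomp + 1

    conn = 3 if connectivity == 26 else 1
    labels = watershed(-depth, markers=markers, mask=lesion, connectivity=conn)

    ids = np.unique(labels[lesion])
    records: list[LACRecord] = []
    label_map = np.zeros(lesion.shape, dtype=np.int32)
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    for new_id, old in enumerate(ids, start=1):
        m = labels == old
        label_map[m] = new_id
        count = int(m.sum())
        com = ndi.center_of_mass(m)
        records.append(LACRecord(
            id=new_id,
            phase=phase,
            threshold=float(threshold),
            voxel_count=count,
            lad=count / parenchyma_count,
            max_erosion_depth=int(depth[m].max()),
            centroid_mm=tuple(np.asarray(com) * spacing + origin),
            small=count < min_voxels,
        ))
    return records, label_map


def classify_predominance(
    records: list[LACRecord],
    label_map: np.ndarray,
    prm: PRMMap,
    ratio_cut: float = 0.5,
) -> list[LACRecord]:
    """Classify expiratory air-trapping clusters by emphysema predominance.

    A cluster whose PRM-emphysema voxel fraction exceeds ``ratio_cut`` is
    ``emph_predominant`` (excluded from the fSAD predictors); otherwise it is
    ``fsad`` and its effective density uses only its PRM fSAD voxels.
    """
    if any(r.phase != EXPIRATORY for r in records):
        raise PhaseError("predominance classification applies to expiratory "
                         "air-trapping clusters only")
    nmax = int(label_map.max())
    emph_counts = np.bincount(
        label_map[(prm.classes == PRM_EMPHYSEMA) & (label_map > 0)],
        minlength=nmax + 1)
    fsad_counts = np.bincount(
        label_map[(prm.classes == PRM_FSAD) & (label_map > 0)],
        minlength=nmax + 1)
    for r in records:
        emph_frac = emph_counts[r.id] / r.voxel_count
        if emph_frac > ratio_cut:
            r.lac_class = "emph_predominant"
            r.fsad_voxels = 0
        else:
            r.lac_class = "fsad"
            r.fsad_voxels = int(fsad_counts[r.id])
    return records


def assign_regions(
    records: list[LACRecord],
    label_map: np.ndarray,
    regions: RegionMask,
) -> list[LACRecord]:
    """Assign each cluster the (side, group) of the majority of its voxels.

    Exact ties break toward the lower group and, for side, toward left.
    """
    nmax = int(label_map.max())
    in_cluster = label_map > 0

    def count_where(cond):
        return np.bincount(label_map[in_cluster & cond], minlength=nmax + 1)

    side_counts = {name: count_where(regions.side == code)
                   for code, name in SIDE_NAMES.items()}
    group_counts = {name: count_where(regions.group == code)
                    for code, name in GROUP_NAMES.items()}
    for r in records:
        r.side = "left" if side_counts["left"][r.id] >= side_counts["right"][r.id] \
            else "right"
        r.group = "upper" if group_counts["upper"][r.id] > group_counts["lower"][r.id] \
            else "lower"
    return records


def lac_table(records: list[LACRecord]) -> pd.DataFrame:
    """One row per cluster, suitable for CSV export."""
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "phase": r.phase, "threshold": r.threshold,
            "side": r.side, "group": r.group, "lac_class": r.lac_class,
            "voxel_count": r.voxel_count, "lad": r.lad,
            "fsad_voxels": r.fsad_voxels,
            "max_erosion_depth": r.max_erosion_depth,
            "centroid_z_mm": r.centroid_mm[0],
            "centroid_y_mm": r.centroid_mm[1],
            "centroid_x_mm": r.centroid_mm[2],
            "small": r.small,
        })
    return pd.DataFrame(rows)


def records_from_table(df: pd.DataFrame) -> list[LACRecord]:
    """Inverse of :func:`lac_table` (centroids optional)."""
    records = []
    for _, row in df.iterrows():
        records.append(LACRecord(
            id=int(row["id"]), phase=str(row["phase"]),
            threshold=float(row.get("threshold", np.nan)),
            voxel_count=int(row["voxel_count"]), lad=float(row["lad"]),
            max_erosion_depth=int(row.get("max_erosion_depth", 0)),
            centroid_mm=(float(row.get("centroid_z_mm", 0.0)),
                         float(row.get("centroid_y_mm", 0.0)),
                         float(row.get("centroid_x_mm", 0.0))),
            side=row.get("side"), group=row.get("group"),
            lac_class=str(row.get("lac_class", "plain")),
            fsad_voxels=int(row.get("fsad_voxels", 0)),
            small=bool(row.get("small", False)),
        ))
    return records
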