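"""Lung, airway and lobe-group segmentation.

The lung mask is grown from the airway under an HU upper bound, vessels are
re-included by morphological closing and hole filling, and the airway itself
is subtracted so that the remaining parenchyma is the denominator of every
density measure.  Left and right lungs are separated by erosion (to detach
the anterior junction) followed by geodesic reassignment, and each lung is
partitioned into upper/lower lobe groups by a thin-plate-spline surface
fitted through fissure points found with a Hessian plate filter.  The right
middle lobe is counted with the lower group, so a single surface per lung
suffices.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.ndimage as ndi
from scipy.interpolate import RBFInterpolator
from skimage.feature import hessian_matrix

from .core import (
    LEFT,
    LOWER,
    RIGHT,
    UPPER,
    LeakError,
    ParameterError,
    RegionMask,
    SeedPointError,
    SplitError,
    Volume3D,
)

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndi.generate_binary_structure(3, 1)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return _STRUCT26
    if connectivity == 6:
        return _STRUCT6
    raise ParameterError("connectivity must be 6 or 26")


def segment_airway(
    vol: Volume3D,
    seed_point: tuple[int, int, int],
    hu_start: float = -960.0,
    hu_stop: float = -800.0,
    hu_step: float = 20.0,
    leak_factor: float = 2.0,
    connectivity: int = 26,
) -> np.ndarray:
    """Leak-guarded threshold-stepping region growing of the airway lumen.

    Starting from a strict air threshold, the threshold is raised in steps;
    at each step the connected component containing the seed is taken.  A
    step whose component volume jumps by more than ``leak_factor`` relative
    to the previous step indicates a leak into the parenchyma and is
    rejected, keeping the last good mask.
    """
    seed_point = tuple(int(i) for i in seed_point)
    if vol.values[seed_point] >= -900.0:
        raise SeedPointError(
            f"seed HU {vol.values[seed_point]:.0f} is not air-dense (< -900 required)"
        )
    struct = _structure(connectivity)
    mask = None
    prev_size = 0
    th = hu_start
    while th <= hu_stop + 1e-9:
        cand = vol.values < th
        if cand[seed_point]:
            lab, _ = ndi.label(cand, structure=struct)
            comp = lab == lab[seed_point]
            size = int(comp.sum())
            if mask is not None and size > leak_factor * prev_size + 100:
                log.debug("airway growth leak at %.0f HU (%d -> %d voxels)",
                          th, prev_size, size)
                break
            mask = comp
            prev_size = size
        th += hu_step
    if mask is None:
        raise SeedPointError("no air-dense region found at the seed")
    return mask


def segment_lungs(
    vol: Volume3D,
    airway: np.ndarray,
    upper_bound_hu: float = -200.0,
    closing_radius: int = 2,
    connectivity: int = 26,
    border_leak_fraction: float = 0.5,
) -> np.ndarray:
    """Grow the lung mask from airway-adjacent voxels under an HU bound.

    All components of ``HU < upper_bound_hu`` touching the (dilated) airway
    are taken; enclosed vessels are re-included by morphological closing and
    hole filling; the airway is subtracted afterwards.  If the grown region
    covers more than ``border_leak_fraction`` of the image border the
    threshold leaked out of the body and a :class:`LeakError` is raised.
    """
    if not np.any(airway):
        raise ParameterError("airway mask is empty")
    struct = _structure(connectivity)
    cand = vol.values < upper_bound_hu
    if not np.any(cand):
        return np.zeros(vol.shape, dtype=bool)
    lab, nlab = ndi.label(cand, structure=struct)
    touch = np.unique(lab[ndi.binary_dilation(airway, structure=struct)])
    touch = touch[touch != 0]
    grown = np.isin(lab, touch)
    if not np.any(grown):
        return np.zeros(vol.shape, dtype=bool)

    border = np.zeros(vol.shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        for end in (0, -1):
            sl[ax] = end
            border[tuple(sl)] = True
    if grown[border].sum() >= border_leak_fraction * border.sum():
        raise LeakError("lung growth reached most of the image border; "
                        "upper bound too permissive")

    if closing_radius > 0:
        ball = _ball(closing_radius, vol.spacing)
        grown = ndi.binary_closing(grown, structure=ball)
        grown = ndi.binary_fill_holes(grown)
    return grown & ~np.asarray(airway, dtype=bool)


def _ball(radius_vox: int, spacing=None) -> np.ndarray:
    r = int(radius_vox)
    zz, yy, xx = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1]
    return (zz**2 + yy**2 + xx**2) <= r**2 + 1e-9


def _geodesic_assign(mask: np.ndarray, seeds: np.ndarray,
                     struct: np.ndarray) -> np.ndarray:
    """Assign every mask voxel to the nearest seed label by geodesic BFS.

    Simultaneous frontier growth; a voxel reached by two labels in the same
    round goes to the smaller label (deterministic).
    """
    labels = np.where(mask, seeds, 0).astype(np.int32)
    while True:
        unassigned = mask & (labels == 0)
        if not np.any(unassigned):
            break
        newly = np.zeros_like(labels)
        changed = False
        for lbl in (1, 2):
            grown = ndi.binary_dilation(labels == lbl, structure=struct)
            claim = grown & unassigned & (newly == 0)
            if np.any(claim):
                newly[claim] = lbl
                changed = True
        if not changed:
            # disconnected leftovers: assign by Euclidean nearest seed label
            dist1 = ndi.distance_transform_edt(labels != 1)
            dist2 = ndi.distance_transform_edt(labels != 2)
            labels[unassigned] = np.where(dist1 <= dist2, 1, 2)[unassigned]
            break
        labels[newly > 0] = newly[newly > 0]
    return labels


def split_left_right(
    lung: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    connectivity: int = 26,
    min_seed_fraction: float = 0.05,
    max_erosions: int = 50,
) -> np.ndarray:
    """Label lung voxels LEFT/RIGHT.

    The mask is eroded until it falls apart into at least two sizeable
    components; the two largest become seeds and every original lung voxel
    is reassigned to the nearest seed by geodesic distance inside the mask.
    Left/right is decided by the seed centroids' physical x coordinate
    (patient left = smaller x in RAS).
    """
    lung = np.asarray(lung, dtype=bool)
    if not np.any(lung):
        raise ParameterError("lung mask is empty")
    struct = _structure(connectivity)
    total = int(lung.sum())
    eroded = lung
    n_erosions = 0
    while True:
        lab, nlab = ndi.label(eroded, structure=struct)
        if nlab >= 2:
            sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, nlab + 1))
            order = np.argsort(sizes)[::-1]
            if nlab >= 2 and sizes[order[1]] >= min_seed_fraction * sizes[order[0]]:
                big1, big2 = order[0] + 1, order[1] + 1
                break
        eroded = ndi.binary_erosion(eroded, structure=struct)
        n_erosions += 1
        if not np.any(eroded) or n_erosions > max_erosions:
            raise SplitError("erosion exhausted the mask before it split")

    c1 = ndi.center_of_mass(lab == big1)
    c2 = ndi.center_of_mass(lab == big2)
    # smaller physical x -> LEFT
    if c1[2] * spacing[2] <= c2[2] * spacing[2]:
        left_lab, right_lab = big1, big2
    else:
        left_lab, right_lab = big2, big1
    seeds = np.zeros(lung.shape, dtype=np.int32)
    seeds[lab == left_lab] = LEFT
    seeds[lab == right_lab] = RIGHT
    side = _geodesic_assign(lung, seeds, struct)
    return side.astype(np.uint8)


# ---------------------------------------------------------------------------
# Fissure detection and lobe-group partition
# ---------------------------------------------------------------------------


def plateness(vol: Volume3D, sigma_mm: float = 2.0):
    """Bright-plate Hessian score per voxel.

    With eigenvalues sorted |l1| >= |l2| >= |l3|, the score is
    ``S = |l1| * (1 - |l2|/|l1|)`` where a bright plate requires ``l1 < 0``;
    elsewhere the score is 0.  Returns ``(S, e1)`` with ``e1`` the unit
    eigenvector of l1 (the plate normal) in (z, y, x) voxel steps.
    """
    sigma_vox = [sigma_mm / s for s in vol.spacing]
    helems = hessian_matrix(vol.values.astype(np.float64), sigma=sigma_vox,
                            use_gaussian_derivatives=True, order="rc")
    nz, ny, nx = vol.shape
    H = np.empty((nz, ny, nx, 3, 3))
    iu = np.triu_indices(3)
    for k, (i, j) in enumerate(zip(*iu)):
        H[..., i, j] = helems[k]
        H[..., j, i] = helems[k]
    evals, evecs = np.linalg.eigh(H)
    order = np.argsort(-np.abs(evals), axis=-1)
    evals = np.take_along_axis(evals, order, axis=-1)
    l1, l2 = evals[..., 0], evals[..., 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.abs(l1) * (1.0 - np.abs(l2) / np.abs(l1))
    score = np.where((l1 < 0) & np.isfinite(score), score, 0.0)
    e1 = np.take_along_axis(
        evecs, order[..., None, :], axis=-1)[..., 0]
    return score, e1


def detect_fissure_points(
    vol: Volume3D,
    side_mask: np.ndarray,
    sigma_mm: float = 2.0,
    threshold: float = 10.0,
    margin_vox: int = 2,
    max_points: int = 5000,
) -> np.ndarray:
    """Fissure candidate points (physical mm) from the Hessian plate filter.

    Voxels inside the (eroded) side mask whose plateness exceeds
    ``threshold`` and survive non-maximum suppression along the plate normal
    are returned, strongest first, capped at ``max_points``.  May be empty;
    the caller falls back to a plane.
    """
    score, e1 = plateness(vol, sigma_mm=sigma_mm)
    interior = ndi.binary_erosion(np.asarray(side_mask, dtype=bool),
                                  iterations=max(margin_vox, 1))
    cand = (score > threshold) & interior
    idx = np.argwhere(cand)
    if idx.size == 0:
        return np.empty((0, 3))
    step = np.rint(e1[cand]).astype(int)
    step[np.all(step == 0, axis=1)] = (1, 0, 0)
    shape = np.asarray(vol.shape)
    keep = np.ones(len(idx), dtype=bool)
    for sgn in (+1, -1):
        nb = np.clip(idx + sgn * step, 0, shape - 1)
        keep &= score[cand] >= score[nb[:, 0], nb[:, 1], nb[:, 2]]
    idx = idx[keep]
    if idx.shape[0] > max_points:
        s = score[idx[:, 0], idx[:, 1], idx[:, 2]]
        idx = idx[np.argsort(-s, kind="stable")[:max_points]]
    return idx * np.asarray(vol.spacing) + np.asarray(vol.origin)


def fit_lobe_surface(
    points_mm: np.ndarray,
    side_mask: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    smoothing: float = 1.0,
    fallback_fraction: float = 0.55,
) -> np.ndarray:
    """Partition a lung into upper/lower groups by a fissure surface.

    A regularized thin plate spline z = f(x, y) is fitted through the
    control points; voxels above the surface are labeled UPPER, at or below
    LOWER.  With fewer than 6 non-collinear points a horizontal plane at
    ``fallback_fraction`` of the cranio-caudal lung extent is used instead
    (logged as a warning).
    """
    side_mask = np.asarray(side_mask, dtype=bool)
    if not np.any(side_mask):
        return np.zeros(side_mask.shape, dtype=np.uint8)
    points_mm = np.atleast_2d(np.asarray(points_mm, dtype=float))
    idx = np.argwhere(side_mask)
    zc = idx[:, 0] * spacing[0] + origin[0]

    surface = None
    if points_mm.shape[0] >= 6 and not _collinear_yx(points_mm):
        try:
            rbf = RBFInterpolator(points_mm[:, 1:3], points_mm[:, 0],
                                  kernel="thin_plate_spline",
                                  smoothing=smoothing, degree=1)
            yx = idx[:, 1:3] * np.asarray(spacing[1:]) + np.asarray(origin[1:])
            surface = rbf(yx)
        except np.linalg.LinAlgError:  # degenerate point layout
            surface = None
    if surface is None:
        log.warning("too few/degenerate fissure points (%d); "
                    "falling back to a horizontal plane", points_mm.shape[0])
        zmin, zmax = zc.min(), zc.max()
        surface = np.full(idx.shape[0], zmin + fallback_fraction * (zmax - zmin))

    group = np.zeros(side_mask.shape, dtype=np.uint8)
    above = zc > surface + 1e-6  # voxels on the surface itself go LOWER
    group[tuple(idx[above].T)] = UPPER
    group[tuple(idx[~above].T)] = LOWER
    return group


def _collinear_yx(points_mm: np.ndarray) -> bool:
    yx = points_mm[:, 1:3]
    M = np.column_stack([yx - yx.mean(axis=0)])
    return np.linalg.matrix_rank(M, tol=1e-8) < 2


def build_region_mask(
    lung: np.ndarray,
    airway: np.ndarray,
    side: np.ndarray,
    group: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
) -> RegionMask:
    """Assemble a RegionMask; airway voxels carry no side/group label."""
    lung = np.asarray(lung, dtype=bool)
    side = np.where(lung, side, 0).astype(np.uint8)
    group = np.where(lung, group, 0).astype(np.uint8)
    return RegionMask(side=side, group=group, airway=np.asarray(airway, bool),
                      spacing=tuple(spacing), origin=tuple(origin))


def segment_subject(vol: Volume3D, seed_point, config=None) -> RegionMask:
    """Full segmentation of one phase: airway, lungs, sides, lobe groups."""
    from .config import SegmentationConfig

    cfg = config or SegmentationConfig()
    airway = segment_airway(vol, seed_point, hu_start=cfg.airway_hu_start,
                            hu_stop=cfg.airway_hu_stop, hu_step=cfg.airway_hu_step,
                            leak_factor=cfg.airway_leak_factor,
                            connectivity=cfg.connectivity)
    lung = segment_lungs(vol, airway, upper_bound_hu=cfg.lung_upper_bound_hu,
                         closing_radius=cfg.closing_radius,
                         connectivity=cfg.connectivity)
    side = split_left_right(lung, spacing=vol.spacing,
                            connectivity=cfg.connectivity)
    group = np.zeros(lung.shape, dtype=np.uint8)
    for code in (LEFT, RIGHT):
        m = side == code
        if not np.any(m):
            continue
        pts = detect_fissure_points(vol, m, sigma_mm=cfg.fissure_sigma_mm,
                                    threshold=cfg.fissure_threshold)
        g = fit_lobe_surface(pts, m, spacing=vol.spacing, origin=vol.origin,
                             smoothing=cfg.tps_smoothing,
                             fallback_fraction=cfg.fallback_fraction)
        group[m] = g[m]
    return build_region_mask(lung, airway, side, group,
                             spacing=vol.spacing, origin=vol.origin)
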