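"""Non-rigid alignment of the expiratory lung onto the inspiratory lung.

Sparse points are sampled from each lung mask on a deterministic physical
grid, matched by coherent point drift (CPD: an isotropic Gaussian-mixture EM
with motion-coherence regularization on a Gaussian kernel), and the
transformed interior points serve as landmarks for a scattered-interpolation
warp of the expiratory HU volume onto the inspiratory grid.  Left and right
lungs are registered independently and their landmark sets pooled for a
single dense warp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError
from scipy.spatial.distance import cdist

from .core import (
    HU_MIN,
    DegenerateGeometryError,
    ParameterError,
    PointSet,
    Volume3D,
)

log = logging.getLogger(__name__)


def sample_points(
    mask: np.ndarray,
    spacing,
    target_spacing: float,
    role: str = "surface",
    origin=(0.0, 0.0, 0.0),
    side: str | None = None,
) -> PointSet:
    """Evenly distributed sparse points of a mask on a physical grid.

    The mask's candidate voxels (boundary voxels for ``surface``, all voxels
    for ``interior``) are binned into cubic cells of pitch ``target_spacing``
    anchored at the mask's bounding-box corner; the candidate closest to each
    cell center is returned.  Deterministic: no randomness, stable tie-breaks.
    """
    mask = np.asarray(mask, dtype=bool)
    spacing = np.asarray(spacing, dtype=float)
    if not np.any(mask):
        raise ParameterError("mask is empty")
    if target_spacing < spacing.max():
        raise ParameterError(
            f"target_spacing {target_spacing} mm below voxel spacing {tuple(spacing)}"
        )
    if role == "surface":
        cand = mask & ~ndi.binary_erosion(mask)
    elif role == "interior":
        cand = mask
    else:
        raise ParameterError("role must be 'surface' or 'interior'")
    idx = np.argwhere(cand)
    coords = idx * spacing + np.asarray(origin, dtype=float)
    anchor = coords.min(axis=0)
    cell = np.floor((coords - anchor) / target_spacing).astype(np.int64)
    cell_id = (cell[:, 0], cell[:, 1], cell[:, 2])
    # representative per cell: nearest to the cell center, stable on ties
    centers = anchor + (cell + 0.5) * target_spacing
    d2 = ((coords - centers) ** 2).sum(axis=1)
    order = np.lexsort((np.arange(len(idx)), d2,
                        cell[:, 2], cell[:, 1], cell[:, 0]))
    cells_sorted = cell[order]
    first = np.ones(len(order), dtype=bool)
    first[1:] = np.any(np.diff(cells_sorted, axis=0) != 0, axis=1)
    chosen = order[first]
    chosen.sort()
    return PointSet(coords=coords[chosen], role=role, side=side)


@dataclass
class CPDResult:
    """State of a converged (or stopped) non-rigid CPD registration.

    The EM runs on points normalized to zero mean and unit RMS scale (the
    Gaussian-mixture outlier balance assumes roughly unit-scale data);
    ``W`` and ``sigma2_trace`` live in that normalized frame, ``mu``/``scale``
    map back to mm.
    """

    beta: float  # kernel width in mm (as requested)
    lam: float
    W: np.ndarray  # (M, 3) kernel weights, normalized frame
    floating: np.ndarray  # (M, 3) original floating points, mm
    moved_points: np.ndarray  # (M, 3) transformed floating points, mm
    sigma2_trace: np.ndarray  # normalized-frame mixture variance
    converged: bool
    mu: np.ndarray = None  # type: ignore[assignment]
    scale: float = 1.0

    def transform(self, points_mm: np.ndarray) -> np.ndarray:
        """Apply the learned displacement field to arbitrary points (mm)."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        pn = (pts - self.mu) / self.scale
        yn = (self.floating - self.mu) / self.scale
        G = _gauss_gram(pn, yn, self.beta / self.scale)
        return (pn + G @ self.W) * self.scale + self.mu


def _gauss_gram(a: np.ndarray, b: np.ndarray, beta: float) -> np.ndarray:
    return np.exp(-cdist(a, b, "sqeuclidean") / (2.0 * beta * beta))


def cpd_nonrigid(
    floating: PointSet | np.ndarray,
    reference: PointSet | np.ndarray,
    beta: float = 30.0,
    lam: float = 2.0,
    outlier_w: float = 0.1,
    max_iter: int = 300,
    tol: float = 1e-7,
    sigma2_min_mm: float = 0.0,
) -> CPDResult:
    """Coherent point drift, non-rigid variant.

    E-step: posterior correspondence probabilities under an isotropic
    Gaussian mixture centered on the moved floating points, with uniform
    outlier mass ``outlier_w``.  M-step: solve
    ``(G + lam * sigma^2 * diag(1/P1)) W = diag(1/P1) P X - Y`` for the
    kernel weights and update the mixture variance.  Stops when the relative
    change of sigma^2 drops below ``tol`` or after ``max_iter`` iterations.

    ``sigma2_min_mm`` (mm) floors the mixture standard deviation; when the
    point sets are sparse surface samples, flooring at about half the
    sampling pitch keeps the posteriors soft across neighboring samples and
    prevents overfitting the sampling quantization.
    """
    Y = np.asarray(floating.coords if isinstance(floating, PointSet) else floating,
                   dtype=float)
    X = np.asarray(reference.coords if isinstance(reference, PointSet) else reference,
                   dtype=float)
    if Y.size == 0 or X.size == 0:
        raise ParameterError("point sets must be nonempty")
    if beta <= 0 or lam <= 0:
        raise ParameterError("beta and lambda must be positive")
    if not 0 <= outlier_w < 1:
        raise ParameterError("outlier_w must be in [0, 1)")
    M, N, D = Y.shape[0], X.shape[0], 3

    Y_mm, X_mm = Y, X
    mu = np.vstack([X, Y]).mean(axis=0)
    scale = float(np.sqrt(((np.vstack([X, Y]) - mu) ** 2).sum(axis=1).mean()))
    scale = max(scale, np.finfo(float).tiny)
    Y = (Y - mu) / scale
    X = (X - mu) / scale
    beta_n = beta / scale

    sigma2_floor = max((sigma2_min_mm / scale) ** 2, 1e-12)

    G = _gauss_gram(Y, Y, beta_n)
    W = np.zeros((M, D))
    T = Y.copy()
    sigma2 = cdist(X, Y, "sqeuclidean").sum() / (D * M * N)
    trace = [sigma2]
    converged = False
    for _ in range(max_iter):
        # E-step
        d2 = cdist(T, X, "sqeuclidean")
        P = np.exp(-d2 / (2.0 * sigma2))
        c = ((2.0 * np.pi * sigma2) ** (D / 2.0)
             * outlier_w / max(1.0 - outlier_w, 1e-12) * M / N)
        den = P.sum(axis=0) + c
        den[den == 0] = np.finfo(float).tiny
        P /= den
        P1 = P.sum(axis=1)
        Pt1 = P.sum(axis=0)
        Np = P1.sum()
        if Np < np.finfo(float).tiny:
            break
        PX = P @ X
        # M-step
        P1s = np.maximum(P1, 1e-12)
        A = G + lam * sigma2 * np.diag(1.0 / P1s)
        rhs = PX / P1s[:, None] - Y
        try:
            W = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            try:
                W = np.linalg.solve(A + 1e-6 * np.eye(M), rhs)
            except np.linalg.LinAlgError as err:
                raise DegenerateGeometryError(
                    "CPD system singular even after regularization bump") from err
        T = Y + G @ W
        xPx = (Pt1 * (X * X).sum(axis=1)).sum()
        yPy = (P1 * (T * T).sum(axis=1)).sum()
        trPXT = (PX * T).sum()
        sigma2_new = max((xPx - 2.0 * trPXT + yPy) / (Np * D), sigma2_floor)
        rel = abs(sigma2 - sigma2_new) / max(sigma2, np.finfo(float).tiny)
        sigma2 = sigma2_new
        trace.append(sigma2)
        if rel < tol:
            converged = True
            break
    return CPDResult(beta=beta, lam=lam, W=W, floating=Y_mm,
                     moved_points=T * scale + mu,
                     sigma2_trace=np.asarray(trace), converged=converged,
                     mu=mu, scale=scale)


def warp_volume(
    expiratory: Volume3D,
    landmarks_src: np.ndarray,
    landmarks_dst: np.ndarray,
    out_grid: Volume3D,
) -> tuple[Volume3D, np.ndarray]:
    """Resample the expiratory volume onto the reference grid via landmarks.

    ``landmarks_src`` are points in the expiratory volume, ``landmarks_dst``
    their registered positions in the reference (inspiratory) space.  A dense
    displacement field on ``out_grid`` is built by scattered linear
    interpolation of ``src - dst`` at the dst positions (nearest-landmark
    extension outside their convex hull), then HU are pulled from the
    expiratory volume by trilinear interpolation.  Voxels mapping outside
    the expiratory field of view are set to -1024 and flagged invalid in the
    returned validity mask.
    """
    src = np.atleast_2d(np.asarray(landmarks_src, dtype=float))
    dst = np.atleast_2d(np.asarray(landmarks_dst, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 4:
        raise ParameterError("need matching landmark sets of length >= 4")
    disp = src - dst
    try:
        lin = LinearNDInterpolator(dst, disp)
    except QhullError as err:
        raise DegenerateGeometryError(f"degenerate landmark geometry: {err}") from err
    near = NearestNDInterpolator(dst, disp)

    axes = [out_grid.origin[i] + np.arange(out_grid.shape[i]) * out_grid.spacing[i]
            for i in range(3)]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([Z, Y, X], axis=-1).reshape(-1, 3)
    d = lin(pts)
    outside = np.isnan(d[:, 0])
    if np.any(outside):
        d[outside] = near(pts[outside])
    sample = pts + d

    # physical -> expiratory voxel index
    idx = (sample - np.asarray(expiratory.origin)) / np.asarray(expiratory.spacing)
    shape = np.asarray(expiratory.shape)
    valid = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
    hu = ndi.map_coordinates(expiratory.values.astype(np.float64), idx.T,
                             order=1, mode="constant", cval=HU_MIN)
    hu[~valid] = HU_MIN
    out = Volume3D(hu.reshape(out_grid.shape).astype(np.float32),
                   out_grid.spacing, out_grid.origin, phase=expiratory.phase)
    return out, valid.reshape(out_grid.shape)


@dataclass
class RegistrationResult:
    coreg: Volume3D
    valid: np.ndarray
    landmarks_src: np.ndarray
    landmarks_dst: np.ndarray
    cpd: dict = field(default_factory=dict)  # side -> CPDResult


def _mask_moments_affine(m_ref: np.ndarray, m_flt: np.ndarray,
                         spacing_ref, spacing_flt,
                         origin_ref, origin_flt):
    """Axis-aligned affine (scale a, shift t) aligning floating mask moments
    to the reference mask: p -> a * p + t."""
    vr = np.argwhere(m_ref) * np.asarray(spacing_ref) + np.asarray(origin_ref)
    vf = np.argwhere(m_flt) * np.asarray(spacing_flt) + np.asarray(origin_flt)
    a = vr.std(axis=0) / np.maximum(vf.std(axis=0), 1e-9)
    t = vr.mean(axis=0) - a * vf.mean(axis=0)
    return a, t


def register_pair(
    insp: Volume3D,
    exp: Volume3D,
    insp_side: np.ndarray,
    exp_side: np.ndarray,
    pitch_mm: float = 6.0,
    beta: float = 45.0,
    lam: float = 8.0,
    outlier_w: float = 0.1,
    max_iter: int = 300,
    tol: float = 1e-7,
    sigma2_min_mm: float | None = None,
) -> RegistrationResult:
    """Register the expiratory phase onto the inspiratory grid, per lung.

    For each side present in both masks, a moment-based axis-aligned affine
    (centroid + per-axis scale of the full masks) pre-aligns the expiratory
    lung, then CPD on the surface point samples refines the residual
    deformation (floating = expiratory, reference = inspiratory).  The
    expiratory interior points pushed through affine + CPD become landmarks
    and both sides' landmarks feed one dense warp.  The side masks must
    exclude the airway (sampled points represent parenchyma).
    """
    if sigma2_min_mm is None:
        sigma2_min_mm = 0.5 * pitch_mm  # soften posteriors across sample pitch
    srcs, dsts, cpds = [], [], {}
    for code, name in ((1, "left"), (2, "right")):
        m_ref = insp_side == code
        m_flt = exp_side == code
        if not (np.any(m_ref) and np.any(m_flt)):
            continue
        a, t = _mask_moments_affine(m_ref, m_flt, insp.spacing, exp.spacing,
                                    insp.origin, exp.origin)
        ref_pts = sample_points(m_ref, insp.spacing, pitch_mm, "surface",
                                insp.origin).coords
        flt_pts = sample_points(m_flt, exp.spacing, pitch_mm, "surface",
                                exp.origin).coords
        res = cpd_nonrigid(flt_pts * a + t, ref_pts, beta=beta, lam=lam,
                           outlier_w=outlier_w, max_iter=max_iter, tol=tol,
                           sigma2_min_mm=sigma2_min_mm)
        interior = sample_points(m_flt, exp.spacing, pitch_mm, "interior",
                                 exp.origin).coords
        moved = res.transform(interior * a + t)
        srcs.append(interior)
        dsts.append(moved)
        cpds[name] = res
        log.info("CPD %s: %d->%d pts, sigma2 %.3g, converged=%s", name,
                 len(flt_pts), len(ref_pts), res.sigma2_trace[-1], res.converged)
    if not srcs:
        raise ParameterError("no common lung side between the two phases")
    src = np.vstack(srcs)
    dst = np.vstack(dsts)
    coreg, valid = warp_volume(exp, src, dst, insp)
    return RegistrationResult(coreg=coreg, valid=valid, landmarks_src=src,
                              landmarks_dst=dst, cpd=cpds)


def export_landmarks(path, src: np.ndarray, dst: np.ndarray) -> None:
    """Write landmarks as TSV: x, y, z, dx, dy, dz (mm, RAS)."""
    src = np.atleast_2d(src)[:, ::-1]  # (z,y,x) -> (x,y,z)
    dst = np.atleast_2d(dst)[:, ::-1]
    d = dst - src
    arr = np.hstack([src, d])
    header = "x\ty\tz\tdx\tdy\tdz"
    np.savetxt(path, arr, delimiter="\t", header=header, comments="")
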