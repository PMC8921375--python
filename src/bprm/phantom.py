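"""Synthetic paired-CT phantoms and synthetic cohorts with known ground truth.

The imaging phantom emulates the quantities the pipeline measures: two
ellipsoidal lungs inside a soft-tissue body, an enclosed airway tree reaching
both lungs, spherical emphysema bullae (about -980 HU in both phases),
air-trapping regions (about -900 HU in both phases, i.e. above the -950
emphysema threshold on inspiration but below the -856 air-trapping threshold
on expiration), and an oblique fissure plane per lung separating the
upper/lower lobe groups.  The expiratory volume is the inspiratory geometry
pushed through a known smooth contraction-toward-hilum map plus a
low-frequency sinusoidal perturbation, so registration accuracy can be
scored against an analytic displacement field.

Default HU means/SDs are fixed so the -950/-920/-856 thresholds separate the
classes by at least three standard deviations.  A single integer seed drives
all draws through independent child streams (one per tissue class and phase),
so adding lesions never perturbs the parenchyma noise.

The cohort generator emulates the statistical layer only: per subject it
draws cluster LADs from a log-normal size law, bins them into 10 scales at
the law's decile boundaries, sums per (scale, lobe group, lesion type) into
the 40 predictors, and produces FEV1/FVC% from a known linear law plus
Gaussian noise (clipped to [10, 95]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats

from .core import INSPIRATORY, EXPIRATORY, ParameterError, SizingError, Volume3D
from .scaling_model import PREDICTOR_NAMES, predictor_name

# ---------------------------------------------------------------------------
# Imaging phantom
# ---------------------------------------------------------------------------

#: mean HU per tissue class, by phase
DEFAULT_HU_MEAN = {
    "background": (-1000.0, -1000.0),
    "body": (40.0, 40.0),
    "parenchyma": (-850.0, -760.0),
    "airway": (-1000.0, -1000.0),
    "bulla": (-980.0, -980.0),
    "trap": (-900.0, -900.0),
    "fissure": (-700.0, -610.0),  # parenchyma + 150 HU bright plate
}
#: HU standard deviation per tissue class (same both phases)
DEFAULT_HU_SD = {
    "background": 2.0,
    "body": 10.0,
    "parenchyma": 30.0,
    "airway": 5.0,
    "bulla": 10.0,
    "trap": 15.0,
    "fissure": 30.0,
}

_BACKGROUND, _BODY, _PARENCHYMA, _AIRWAY, _BULLA, _TRAP, _FISSURE = range(7)

LESION_NORMAL, LESION_EMPHYSEMA, LESION_AIR_TRAP = 0, 1, 2


@dataclass
class Bulla:
    center_mm: tuple[float, float, float]  # (z, y, x)
    radius_mm: float
    kind: str  # "emphysema" | "air_trap"


@dataclass
class PhantomTruth:
    """Ground truth recorded alongside a phantom pair.

    ``deformation`` is the dense displacement field (mm) on the inspiratory
    grid: a material point at inspiratory position ``p`` sits at
    ``p + deformation`` in the expiratory volume.  ``lesion_labels`` live on
    the inspiratory grid (0 normal, 1 emphysema, 2 air trap).
    """

    deformation: np.ndarray  # (3, nz, ny, nx) float32, (dz, dy, dx) mm
    lesion_labels: np.ndarray  # uint8 on the inspiratory grid
    bulla_catalog: list[Bulla]
    lung_truth: dict[str, np.ndarray]  # phase -> bool mask
    airway_truth: dict[str, np.ndarray]  # phase -> bool mask
    side_truth: np.ndarray  # uint8 on the inspiratory grid (0/1/2)
    group_truth: np.ndarray  # uint8 on the inspiratory grid (0/1/2)
    hilum_mm: tuple[float, float, float]
    contraction: float
    sin_amp_mm: float

    def forward_map(self, points_mm: np.ndarray) -> np.ndarray:
        """Map inspiratory physical points to their expiratory positions."""
        return _expiration_map(np.atleast_2d(points_mm), self.hilum_mm,
                               self.contraction, self.sin_amp_mm,
                               self._periods)

    def inverse_map(self, points_mm: np.ndarray) -> np.ndarray:
        """Map expiratory physical points back to inspiratory positions."""
        return _expiration_map_inverse(np.atleast_2d(points_mm), self.hilum_mm,
                                       self.contraction, self.sin_amp_mm,
                                       self._periods)

    _periods: tuple[float, float, float] = (100.0, 100.0, 100.0)


def _sin_displacement(p: np.ndarray, amp: float, periods) -> np.ndarray:
    """Low-frequency sinusoidal perturbation (mm); p is (..., 3) in mm."""
    out = np.empty_like(p)
    ph = (0.7, 1.9, 0.4)
    for i in range(3):
        j = (i + 1) % 3
        out[..., i] = amp * np.sin(2.0 * np.pi * p[..., j] / periods[i] + ph[i])
    return out


def _expiration_map(p, hilum, contraction, amp, periods):
    h = np.asarray(hilum)
    return h + (1.0 - contraction) * (p - h) + _sin_displacement(p, amp, periods)


def _expiration_map_inverse(q, hilum, contraction, amp, periods, iters: int = 12):
    h = np.asarray(hilum)
    s = 1.0 - contraction
    x = h + (q - h) / s
    for _ in range(iters):
        x = h + (q - h - _sin_displacement(x, amp, periods)) / s
    return x


def _point_segment_dist(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(p - (a + t[..., None] * ab), axis=-1)


@dataclass
class _Geometry:
    """Analytic phantom geometry in physical mm (derived from the extent)."""

    extent: np.ndarray  # (Lz, Ly, Lx)
    body_center: np.ndarray = field(init=False)
    body_semi: np.ndarray = field(init=False)
    lung_centers: dict = field(init=False)
    lung_semi: np.ndarray = field(init=False)
    airway_segments: list = field(init=False)
    hilum: np.ndarray = field(init=False)
    fissure_slope: float = 0.35
    fissure_frac: float = 0.55

    def __post_init__(self) -> None:
        L = self.extent
        self.body_center = 0.5 * L
        self.body_semi = np.array([0.48, 0.44, 0.46]) * L
        self.lung_semi = np.array([0.34, 0.26, 0.15]) * L
        self.lung_centers = {
            "left": np.array([0.50, 0.50, 0.30]) * L,
            "right": np.array([0.50, 0.50, 0.70]) * L,
        }
        r_trachea = max(2.5, 0.022 * float(L.min()))
        r_bronchus = max(2.0, 0.018 * float(L.min()))
        carina = np.array([0.55, 0.50, 0.50]) * L
        top = np.array([0.80, 0.50, 0.50]) * L
        self.hilum = carina
        self.airway_segments = [
            (top, carina, r_trachea),
            (carina, self.lung_centers["left"], r_bronchus),
            (carina, self.lung_centers["right"], r_bronchus),
        ]

    def in_body(self, p):
        return (((p - self.body_center) / self.body_semi) ** 2).sum(-1) <= 1.0

    def in_lung(self, p, side):
        c = self.lung_centers[side]
        return (((p - c) / self.lung_semi) ** 2).sum(-1) <= 1.0

    def airway_dist(self, p):
        d = np.full(p.shape[:-1], np.inf)
        for a, b, r in self.airway_segments:
            d = np.minimum(d, _point_segment_dist(p, a, b) - r)
        return d

    def in_airway(self, p):
        return self.airway_dist(p) <= 0.0

    def fissure_offset(self, p, side):
        """Signed distance (mm, along z) above the oblique fissure plane."""
        c = self.lung_centers[side]
        z0 = c[0] + (self.fissure_frac - 0.5) * 2.0 * self.lung_semi[0]
        return p[..., 0] - (z0 + self.fissure_slope * (p[..., 1] - c[1]))


def _class_labels(points: np.ndarray, geom: _Geometry, bullae: list[Bulla],
                  fissure_halfwidth: float, include_fissure: bool) -> np.ndarray:
    """Tissue class per point (flattened), by priority airway > lesion > fissure
    > parenchyma > body > background."""
    labels = np.zeros(points.shape[0], dtype=np.uint8)
    labels[geom.in_body(points)] = _BODY
    lung_l = geom.in_lung(points, "left")
    lung_r = geom.in_lung(points, "right")
    lung = lung_l | lung_r
    labels[lung] = _PARENCHYMA
    if include_fissure:
        for side, m in (("left", lung_l), ("right", lung_r)):
            off = geom.fissure_offset(points[m], side)
            sub = np.flatnonzero(m)[np.abs(off) <= fissure_halfwidth]
            labels[sub] = _FISSURE
    for b in bullae:
        inside = np.linalg.norm(points - np.asarray(b.center_mm), axis=-1) <= b.radius_mm
        inside &= lung
        labels[inside] = _BULLA if b.kind == "emphysema" else _TRAP
    labels[geom.in_airway(points)] = _AIRWAY
    return labels


def _place_lesions(geom: _Geometry, n_bullae: int, n_traps: int,
                   bulla_radius: float, trap_radius: float,
                   rng: np.random.Generator) -> list[Bulla]:
    specs = [("emphysema", bulla_radius)] * n_bullae + [("air_trap", trap_radius)] * n_traps
    placed: list[Bulla] = []
    for kind, radius in specs:
        ok = False
        for _ in range(4000):
            side = "left" if rng.random() < 0.5 else "right"
            c = geom.lung_centers[side]
            margin = geom.lung_semi - (radius + 1.0)
            if np.any(margin <= 0):
                raise SizingError(
                    f"lung too small for a lesion of radius {radius} mm")
            u = rng.uniform(-1.0, 1.0, size=3)
            p = c + u * margin
            if (((p - c) / margin) ** 2).sum() > 1.0:
                continue
            if geom.airway_dist(p[None, :])[0] < radius + 2.0:
                continue
            if any(np.linalg.norm(p - np.asarray(q.center_mm))
                   < radius + q.radius_mm + 2.0 for q in placed):
                continue
            placed.append(Bulla(tuple(p), radius, kind))
            ok = True
            break
        if not ok:
            raise SizingError("could not place all lesions; volume too small")
    return placed


def make_phantom_pair(
    shape=(96, 96, 96),
    spacing=(1.5, 1.5, 1.5),
    n_bullae: int = 6,
    n_traps: int = 4,
    seed: int = 0,
    bulla_radius_mm: float = 6.0,
    trap_radius_mm: float = 8.0,
    contraction: float = 0.08,
    sin_amp_mm: float = 2.0,
    include_fissure: bool = True,
    hu_mean: dict = DEFAULT_HU_MEAN,
    hu_sd: dict = DEFAULT_HU_SD,
) -> tuple[Volume3D, Volume3D, PhantomTruth]:
    """Generate a paired inspiratory/expiratory phantom with ground truth.

    Returns ``(inspiratory, expiratory, truth)``.  Same inputs give
    bit-identical outputs.
    """
    shape = tuple(int(s) for s in shape)
    spacing = tuple(float(s) for s in spacing)
    if min(shape) < 32:
        raise SizingError("phantom needs shape >= 32 voxels per axis")
    if n_bullae < 0 or n_traps < 0:
        raise ParameterError("lesion counts must be non-negative")

    extent = np.asarray(shape) * np.asarray(spacing)
    geom = _Geometry(extent=extent)
    periods = tuple(0.9 * float(e) for e in extent)

    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(4)
    rng_place = np.random.default_rng(kids[0])
    bullae = _place_lesions(geom, n_bullae, n_traps, bulla_radius_mm,
                            trap_radius_mm, rng_place)

    axes = [np.arange(shape[i]) * spacing[i] for i in range(3)]
    Z, Y, X = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([Z, Y, X], axis=-1).reshape(-1, 3)

    fw = 0.7 * max(spacing)
    labels_insp = _class_labels(pts, geom, bullae, fw, include_fissure)
    pts_exp_src = _expiration_map_inverse(pts, geom.hilum, contraction,
                                          sin_amp_mm, periods)
    labels_exp = _class_labels(pts_exp_src, geom, bullae, fw, include_fissure)

    def render(labels: np.ndarray, phase_idx: int, noise_seed) -> np.ndarray:
        rng = np.random.default_rng(noise_seed)
        # one unit-normal field for tissue classes, one for lesions: lesion
        # placement cannot perturb the parenchyma noise
        tissue_field = rng.standard_normal(labels.shape, dtype=np.float32)
        lesion_field = rng.standard_normal(labels.shape, dtype=np.float32)
        class_names = ["background", "body", "parenchyma", "airway", "bulla",
                       "trap", "fissure"]
        hu = np.empty(labels.shape, dtype=np.float32)
        for code, name in enumerate(class_names):
            m = labels == code
            fieldv = lesion_field if code in (_BULLA, _TRAP, _AIRWAY) else tissue_field
            hu[m] = hu_mean[name][phase_idx] + hu_sd[name] * fieldv[m]
        return hu

    hu_insp = render(labels_insp, 0, kids[1]).reshape(shape)
    hu_exp = render(labels_exp, 1, kids[2]).reshape(shape)

    insp = Volume3D(hu_insp, spacing, phase=INSPIRATORY)
    exp = Volume3D(hu_exp, spacing, phase=EXPIRATORY)

    deformation = (_expiration_map(pts, geom.hilum, contraction, sin_amp_mm,
                                   periods) - pts).astype(np.float32)
    deformation = np.moveaxis(deformation.reshape(*shape, 3), -1, 0)

    lesion = np.zeros(shape, dtype=np.uint8).reshape(-1)
    lesion[labels_insp == _BULLA] = LESION_EMPHYSEMA
    lesion[labels_insp == _TRAP] = LESION_AIR_TRAP
    lesion = lesion.reshape(shape)

    def lung_mask(lbl):
        return np.isin(lbl, [_PARENCHYMA, _BULLA, _TRAP, _FISSURE]).reshape(shape)

    lung_truth = {INSPIRATORY: lung_mask(labels_insp),
                  EXPIRATORY: lung_mask(labels_exp)}
    airway_truth = {INSPIRATORY: (labels_insp == _AIRWAY).reshape(shape),
                    EXPIRATORY: (labels_exp == _AIRWAY).reshape(shape)}

    side = np.zeros(pts.shape[0], dtype=np.uint8)
    side[geom.in_lung(pts, "left") & lung_truth[INSPIRATORY].reshape(-1)] = 1
    side[geom.in_lung(pts, "right") & lung_truth[INSPIRATORY].reshape(-1)] = 2
    group = np.zeros(pts.shape[0], dtype=np.uint8)
    for code, sname in ((1, "left"), (2, "right")):
        m = side == code
        off = geom.fissure_offset(pts[m], sname)
        g = np.where(off > 0, 1, 2).astype(np.uint8)  # above plane -> upper
        group[m] = g

    truth = PhantomTruth(
        deformation=deformation,
        lesion_labels=lesion,
        bulla_catalog=bullae,
        lung_truth=lung_truth,
        airway_truth=airway_truth,
        side_truth=side.reshape(shape),
        group_truth=group.reshape(shape),
        hilum_mm=tuple(geom.hilum),
        contraction=contraction,
        sin_amp_mm=sin_amp_mm,
        _periods=periods,
    )
    return insp, exp, truth


def airway_seed_index(truth: PhantomTruth) -> tuple[int, int, int]:
    """A voxel index inside the trachea, for seeding airway segmentation."""
    idx = np.argwhere(truth.airway_truth[INSPIRATORY])
    # highest airway voxel nearest the volume midline: trachea interior
    top = idx[idx[:, 0] == idx[:, 0].max()]
    mid = top[np.argsort(np.abs(top[:, 2] - np.median(top[:, 2])))[0]]
    return tuple(int(v) for v in mid)


def save_phantom_pair(outdir, insp: Volume3D, exp: Volume3D,
                      truth: PhantomTruth) -> dict:
    """Write a phantom pair and its truth as NIfTI + a JSON catalog."""
    from pathlib import Path

    from . import io as vio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "inspiratory": outdir / "inspiratory.nii.gz",
        "expiratory": outdir / "expiratory.nii.gz",
        "lesion_labels": outdir / "lesion_labels.nii.gz",
        "catalog": outdir / "truth_catalog.json",
    }
    vio.write_volume(insp, paths["inspiratory"])
    vio.write_volume(exp, paths["expiratory"])
    vio.write_labels(truth.lesion_labels, insp, paths["lesion_labels"],
                     {"0": "normal", "1": "emphysema", "2": "air_trap"})
    catalog = {
        "bullae": [
            {"center_mm": list(b.center_mm), "radius_mm": b.radius_mm,
             "kind": b.kind}
            for b in truth.bulla_catalog
        ],
        "hilum_mm": list(truth.hilum_mm),
        "contraction": truth.contraction,
        "sin_amp_mm": truth.sin_amp_mm,
    }
    with open(paths["catalog"], "w") as fh:
        json.dump(catalog, fh, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------


def default_scale_boundaries(lad_mu: float, lad_sigma: float) -> np.ndarray:
    """Decile boundaries of the log-normal LAD size law (9 ascending cuts)."""
    q = np.arange(1, 10) / 10.0
    return np.exp(lad_mu + lad_sigma * scipy.stats.norm.ppf(q))


@dataclass
class CohortTruth:
    """Known linear LAD -> FEV1/FVC law behind a synthetic cohort.

    ``beta_true`` is indexed by :data:`bprm.scaling_model.PREDICTOR_NAMES`
    (FEV1/FVC% per LAD%); exactly the declared nonzero entries are nonzero.
    """

    beta_true: np.ndarray  # (40,)
    intercept_true: float = 88.0
    noise_sd: float = 3.0
    seed: int = 0
    mean_clusters: float = 150.0
    lad_mu: float = float(np.log(5e-4))
    lad_sigma: float = 1.3
    severity_sigma: float = 0.0  # optional shared per-subject severity factor
    clip: tuple[float, float] = (10.0, 95.0)

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        if self.beta_true.shape != (len(PREDICTOR_NAMES),):
            raise ParameterError("beta_true must have one entry per predictor")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")

    @property
    def scale_boundaries(self) -> np.ndarray:
        return default_scale_boundaries(self.lad_mu, self.lad_sigma)

    @property
    def beta_series(self) -> pd.Series:
        return pd.Series(self.beta_true, index=PREDICTOR_NAMES)


def default_cohort_truth(noise_sd: float = 3.0, seed: int = 0) -> CohortTruth:
    """16 true nonzero terms: scales 6-9 in every (type, group) combination.

    Medium-to-large clusters carry the functional deficit while the giant
    scale-10 bullae do not, mirroring the observation that medium bullae
    impair airflow more than giant ones.  Each coefficient is inversely
    proportional to its bin's natural variability under the default
    log-normal size law (sd of the per-subject LAD% sum, estimated once from
    a large probe cohort and frozen), so every true term contributes an
    equal share of the signal variance; with ``noise_sd = 3`` the population
    R^2 is ~0.67.
    """
    beta = pd.Series(0.0, index=PREDICTOR_NAMES)
    strengths = {
        ("emph950", "upper"): [-9.08, -6.67, -4.55, -2.74],
        ("emph950", "lower"): [-9.39, -6.53, -4.43, -2.76],
        ("fsad", "upper"): [-9.23, -6.52, -4.52, -2.71],
        ("fsad", "lower"): [-9.32, -6.62, -4.47, -2.79],
    }
    for (t, g), vals in strengths.items():
        for scale, b in zip(range(6, 10), vals):
            beta[predictor_name(scale, g, t)] = b
    return CohortTruth(beta_true=beta.to_numpy(), noise_sd=noise_sd, seed=seed)


def _subject_predictors(rng: np.random.Generator, truth: CohortTruth) -> np.ndarray:
    rate = truth.mean_clusters
    if truth.severity_sigma > 0:
        rate *= rng.lognormal(0.0, truth.severity_sigma)
    n = rng.poisson(rate)
    x = np.zeros(len(PREDICTOR_NAMES))
    if n == 0:
        return x
    lads = rng.lognormal(truth.lad_mu, truth.lad_sigma, size=n)
    scales = np.searchsorted(truth.scale_boundaries, lads, side="left")  # 0..9
    groups = rng.integers(0, 2, size=n)  # 0 upper, 1 lower
    types = rng.integers(0, 2, size=n)  # 0 emph950, 1 fsad
    flat = (types * 2 + groups) * 10 + scales
    np.add.at(x, flat, 100.0 * lads)
    return x


def make_cohort(n_subjects: int, truth: CohortTruth) -> pd.DataFrame:
    """Synthesize a cohort table: subject id, 40 LAD% predictors, FEV1/FVC%.

    The response is ``intercept + X beta + N(0, noise_sd)``, clipped to the
    physiological range.  Deterministic given ``truth.seed``.
    """
    if n_subjects < 10:
        raise ParameterError("need at least 10 subjects")
    if truth.noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    ss = np.random.SeedSequence(truth.seed)
    kid_x, kid_eps = ss.spawn(2)
    rng_x = np.random.default_rng(kid_x)
    rng_eps = np.random.default_rng(kid_eps)
    X = np.stack([_subject_predictors(rng_x, truth) for _ in range(n_subjects)])
    y = truth.intercept_true + X @ truth.beta_true
    if truth.noise_sd > 0:
        y = y + rng_eps.normal(0.0, truth.noise_sd, size=n_subjects)
    y = np.clip(y, *truth.clip)
    df = pd.DataFrame(X, columns=PREDICTOR_NAMES)
    df.insert(0, "subject_id", [f"S{i:04d}" for i in range(n_subjects)])
    df["fev1_fvc"] = y
    return df


def tune_noise_for_r2(truth: CohortTruth, target_r2: float,
                      n_probe: int = 4000, probe_seed: int = 987654) -> CohortTruth:
    """Return a copy of ``truth`` with noise_sd set for a population R^2.

    The signal variance var(X beta) is estimated on a large noiseless probe
    cohort, then ``noise_sd = sqrt(var_signal * (1 - R2) / R2)``.
    """
    if not 0 < target_r2 < 1:
        raise ParameterError("target R^2 must be in (0, 1)")
    probe = replace(truth, noise_sd=0.0, seed=probe_seed)
    df = make_cohort(n_probe, probe)
    signal = df[PREDICTOR_NAMES].to_numpy() @ truth.beta_true
    var_sig = float(np.var(signal))
    return replace(truth, noise_sd=float(np.sqrt(var_sig * (1 - target_r2) / target_r2)))
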