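"""Threshold densitometry and parametric response mapping.

Lesion masks are strict-inequality thresholdings (HU < threshold) of one
phase; LAV% is the lesion fraction of the parenchyma.  The PRM classifies
each parenchyma voxel of the co-registered pair as normal, fSAD
(air-trapping on expiration without emphysematous destruction) or emphysema.
Two emphysema rules are provided:

* ``strict_both`` (default): emphysema iff HU < -950 on *both* the
  inspiratory and the co-registered expiratory volume; fSAD iff expiratory
  HU < -856 and not emphysema.
* ``classic``: emphysema iff inspiratory HU < -950 and expiratory HU < -856;
  fSAD iff inspiratory HU >= -950 and expiratory HU < -856.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ParameterError, RegionMask, Volume3D, require_same_grid

PRM_OUTSIDE, PRM_NORMAL, PRM_FSAD, PRM_EMPHYSEMA = 0, 1, 2, 3
PRM_CLASS_NAMES = {PRM_NORMAL: "normal", PRM_FSAD: "fSAD",
                   PRM_EMPHYSEMA: "emphysema"}

EMPH_RULES = ("strict_both", "classic")


@dataclass
class Thresholds:
    """HU thresholds for the four lesion types.

    ``emph_mild`` defaults to -920 (the tabulated convention); -930 is a
    documented alternative.  All comparisons are strict (HU < threshold).
    """

    emph_mild: float = -920.0
    emph_severe: float = -950.0
    air_trap: float = -856.0
    emph_rule: str = "strict_both"

    def __post_init__(self) -> None:
        if not (self.emph_severe < self.emph_mild < self.air_trap < 0):
            raise ParameterError(
                "thresholds must satisfy emph_severe < emph_mild < air_trap < 0")
        if self.emph_rule not in EMPH_RULES:
            raise ParameterError(f"emph_rule must be one of {EMPH_RULES}")


def binarize(vol: Volume3D, parenchyma: np.ndarray, threshold: float) -> np.ndarray:
    """Strict-threshold lesion mask: voxel in parenchyma AND HU < threshold."""
    if not -1024 <= threshold <= 3071:
        raise ParameterError("threshold outside the HU range")
    return np.asarray(parenchyma, dtype=bool) & (vol.values < threshold)


def lav_percent(lesion: np.ndarray, parenchyma: np.ndarray) -> float:
    """100 * |lesion intersect parenchyma| / |parenchyma|."""
    parenchyma = np.asarray(parenchyma, dtype=bool)
    denom = int(parenchyma.sum())
    if denom == 0:
        raise ZeroDivisionError("empty parenchyma")
    return 100.0 * int((np.asarray(lesion, bool) & parenchyma).sum()) / denom


def lav_percent_by_region(lesion: np.ndarray, regions: RegionMask) -> pd.Series:
    """LAV% for the whole lung and per lobe group (upper/lower)."""
    out = {"whole": lav_percent(lesion, regions.parenchyma)}
    for gname, gmask in regions.group_masks().items():
        out[gname] = lav_percent(lesion, gmask) if gmask.any() else np.nan
    return pd.Series(out)


@dataclass
class PRMMap:
    """Per-voxel PRM classes on the inspiratory grid.

    Classes are mutually exclusive and cover the *valid* parenchyma exactly;
    parenchyma voxels warped from outside the expiratory field of view are
    left as ``PRM_OUTSIDE`` and counted in ``n_invalid``.
    """

    classes: np.ndarray  # uint8
    thresholds: Thresholds
    n_invalid: int = 0

    def counts(self, regions: RegionMask) -> pd.DataFrame:
        """Voxel counts per (side, group) region and PRM class."""
        rows = []
        masks = dict(regions.region_masks())
        masks[("whole", "whole")] = regions.parenchyma
        for (sname, gname), m in masks.items():
            row = {"side": sname, "group": gname}
            for code, cname in PRM_CLASS_NAMES.items():
                row[cname] = int(np.count_nonzero(m & (self.classes == code)))
            row["invalid"] = int(np.count_nonzero(m & (self.classes == PRM_OUTSIDE)))
            rows.append(row)
        return pd.DataFrame(rows)


def prm_classify(
    insp: Volume3D,
    coreg_exp: Volume3D,
    parenchyma: np.ndarray,
    th: Thresholds = Thresholds(),
    valid: np.ndarray | None = None,
) -> PRMMap:
    """Classify each valid parenchyma voxel as normal / fSAD / emphysema."""
    require_same_grid(insp, coreg_exp)
    par = np.asarray(parenchyma, dtype=bool)
    if valid is None:
        valid = np.ones(par.shape, dtype=bool)
    dom = par & np.asarray(valid, dtype=bool)

    i = insp.values
    e = coreg_exp.values
    if th.emph_rule == "strict_both":
        emph = (i < th.emph_severe) & (e < th.emph_severe)
        fsad = (e < th.air_trap) & ~emph
    else:  # classic
        emph = (i < th.emph_severe) & (e < th.air_trap)
        fsad = (i >= th.emph_severe) & (e < th.air_trap)

    classes = np.zeros(par.shape, dtype=np.uint8)
    classes[dom] = PRM_NORMAL
    classes[dom & fsad] = PRM_FSAD
    classes[dom & emph] = PRM_EMPHYSEMA
    return PRMMap(classes=classes, thresholds=th,
                  n_invalid=int(np.count_nonzero(par & ~np.asarray(valid, bool))))


def composite_lav(
    insp: Volume3D,
    coreg_exp: Volume3D,
    prm: PRMMap,
    regions: RegionMask,
    th: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """LAV% table per region: Emph920, Emph950, AirT, fSAD and the composites.

    ``Emph950+fSAD`` is a plain sum of disjoint classes (guaranteed by the
    PRM); ``Emph920+AirT`` is the simple addition of the two single-phase
    measures.
    """
    emph920 = binarize(insp, regions.parenchyma, th.emph_mild)
    emph950 = binarize(insp, regions.parenchyma, th.emph_severe)
    airt = binarize(coreg_exp, regions.parenchyma, th.air_trap)
    fsad = prm.classes == PRM_FSAD
    prm_emph = prm.classes == PRM_EMPHYSEMA

    masks = dict(regions.region_masks())
    masks[("whole", "whole")] = regions.parenchyma
    by_group = regions.group_masks()
    for gname, gmask in by_group.items():
        masks[("both", gname)] = gmask

    rows = []
    for (sname, gname), m in masks.items():
        denom = int(m.sum())
        if denom == 0:
            continue

        def pct(lesion):
            return 100.0 * int(np.count_nonzero(lesion & m)) / denom

        rows.append({
            "side": sname,
            "group": gname,
            "LAV%_Emph920": pct(emph920),
            "LAV%_Emph950": pct(emph950),
            "LAV%_AirT": pct(airt),
            "LAV%_fSAD": pct(fsad),
            "LAV%_PRM_Emph": pct(prm_emph),
            "LAV%_Emph920+AirT": pct(emph920) + pct(airt),
            "LAV%_Emph950+fSAD": pct(emph950) + pct(fsad),
        })
    return pd.DataFrame(rows)
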