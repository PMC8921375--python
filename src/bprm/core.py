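"""Core containers and errors shared across the pipeline.

Conventions
-----------
* Arrays are indexed ``(z, y, x)`` with ``z`` superior, ``y`` anterior and
  ``x`` pointing to the patient's right (RAS physical axes, reversed index
  order).  A voxel's physical coordinate is ``origin + index * spacing`` (mm),
  evaluated per axis in the same ``(z, y, x)`` order.
* HU values are clamped to the scanner range [-1024, 3071].
* ``side`` labels: 0 outside, 1 left, 2 right.  ``group`` labels: 0 none,
  1 upper, 2 lower.  The patient's left is at *smaller* physical x in RAS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HU_MIN = -1024.0
HU_MAX = 3071.0

OUTSIDE, LEFT, RIGHT = 0, 1, 2
NONE, UPPER, LOWER = 0, 1, 2

SIDE_NAMES = {LEFT: "left", RIGHT: "right"}
GROUP_NAMES = {UPPER: "upper", LOWER: "lower"}


class BPRMError(Exception):
    """Base class for pipeline errors."""


class SizingError(BPRMError, ValueError):
    """Requested geometry does not fit the volume."""


class ParameterError(BPRMError, ValueError):
    """A parameter is outside its valid range."""


class SeedPointError(BPRMError, ValueError):
    """Region-growing seed does not satisfy its precondition."""


class LeakError(BPRMError, RuntimeError):
    """Region growing escaped the intended anatomy."""


class SplitError(BPRMError, RuntimeError):
    """Left/right separation failed (erosion exhausted the mask)."""


class GridMismatchError(BPRMError, ValueError):
    """Two volumes that must share a grid do not."""


class DegenerateGeometryError(BPRMError, ValueError):
    """Landmarks or points are geometrically degenerate."""


class PhaseError(BPRMError, ValueError):
    """An operation received data from the wrong respiratory phase."""


class FormatError(BPRMError, ValueError):
    """A file could not be parsed as the expected image format."""


class DegenerateScaleError(BPRMError, ValueError):
    """Too few distinct values to fit the requested number of scales."""


class UndefinedCorrelationError(BPRMError, ValueError):
    """Correlation undefined (zero variance or too few samples)."""


class FitError(BPRMError, ValueError):
    """Linear model cannot be fitted on the given data."""


class CatalogError(BPRMError, ValueError):
    """A cluster record is missing required annotations."""


INSPIRATORY = "inspiratory"
EXPIRATORY = "expiratory"


@dataclass
class Volume3D:
    """A 3-D HU image with physical spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        HU values, float.
    spacing : tuple of float
        Voxel size in mm, ``(dz, dy, dx)``; strictly positive.
    origin : tuple of float
        Physical coordinate (mm) of voxel (0, 0, 0), ``(z, y, x)`` order.
    phase : str
        ``"inspiratory"`` or ``"expiratory"``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase: str = INSPIRATORY

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ParameterError("Volume3D expects a 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ParameterError("spacing must be strictly positive")
        if self.phase not in (INSPIRATORY, EXPIRATORY):
            raise ParameterError(f"unknown phase {self.phase!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.values.shape)  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def grid_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical (z, y, x) coordinate arrays of every voxel (broadcastable)."""
        axes = [
            (self.origin[i] + np.arange(self.shape[i]) * self.spacing[i])
            for i in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))  # type: ignore[return-value]

    def index_coords(self, indices: np.ndarray) -> np.ndarray:
        """Physical coordinates (mm) of integer voxel indices, (N, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def same_grid(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


def require_same_grid(a: Volume3D, b: Volume3D) -> None:
    if not a.same_grid(b):
        raise GridMismatchError("volumes are not on the same grid")


@dataclass
class RegionMask:
    """Voxel labels for lung side, lobe group and airway membership.

    ``group != NONE`` implies ``side != OUTSIDE``; airway voxels are excluded
    from the parenchyma, which is the denominator of every density measure.
    """

    side: np.ndarray  # uint8: OUTSIDE / LEFT / RIGHT
    group: np.ndarray  # uint8: NONE / UPPER / LOWER
    airway: np.ndarray  # bool
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.side = np.asarray(self.side, dtype=np.uint8)
        self.group = np.asarray(self.group, dtype=np.uint8)
        self.airway = np.asarray(self.airway, dtype=bool)
        if not (self.side.shape == self.group.shape == self.airway.shape):
            raise GridMismatchError("side/group/airway shapes differ")
        if np.any((self.group != NONE) & (self.side == OUTSIDE)):
            raise ParameterError("group label outside the lung mask")

    @property
    def lung(self) -> np.ndarray:
        return self.side != OUTSIDE

    @property
    def parenchyma(self) -> np.ndarray:
        """Lung voxels with the airway removed."""
        return self.lung & ~self.airway

    @property
    def parenchyma_count(self) -> int:
        return int(np.count_nonzero(self.parenchyma))

    def region_masks(self) -> dict[tuple[str, str], np.ndarray]:
        """Parenchyma masks per (side, group) region."""
        par = self.parenchyma
        out: dict[tuple[str, str], np.ndarray] = {}
        for s, sname in SIDE_NAMES.items():
            for g, gname in GROUP_NAMES.items():
                out[(sname, gname)] = par & (self.side == s) & (self.group == g)
        return out

    def group_masks(self) -> dict[str, np.ndarray]:
        """Parenchyma masks per lobe group (upper/lower, both sides)."""
        par = self.parenchyma
        return {g: par & (self.group == code) for code, g in GROUP_NAMES.items()}


@dataclass
class PointSet:
    """Sparse physical points (mm) sampled from a mask."""

    coords: np.ndarray  # (N, 3) physical mm, (z, y, x)
    role: str = "surface"  # surface | interior
    side: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[1] != 3:
            raise ParameterError("PointSet coords must be (N, 3)")

    def __len__(self) -> int:
        return self.coords.shape[0]
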