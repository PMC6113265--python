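"""Core raster containers, land-use class codes and alignment checks.

All layers in one run live on a single planar grid (row-major numpy arrays,
square pixels in metres).  Areas are pixel_count x pixel_size**2 throughout;
no geodesic correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Canonical land-use class codes (uint8 rasters).
CLASS_CODES = {
    "cropland": 1,
    "forest": 2,
    "grassland": 3,
    "water": 4,
    "built-up": 5,
    "bare": 6,
}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}

# Physiographic zones of a mountain-oasis-desert (MODS) landscape.
ZONE_CODES = {"mountain": 1, "oasis": 2, "desert": 3}
ZONE_NAMES = {v: k for k, v in ZONE_CODES.items()}


class ConfigurationError(ValueError):
    """Invalid configuration (proportions, grid size, factor counts...)."""


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class AlignmentError(ValueError):
    """Two layers do not share the run grid."""


@dataclass(frozen=True)
class RasterGrid:
    """Shared grid of one run: shape, square pixel size in metres, origin, nodata."""

    shape: tuple[int, int]
    pixel_size: float = 100.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = float("nan")

    @property
    def pixel_area_m2(self) -> float:
        return self.pixel_size ** 2

    @property
    def pixel_area_km2(self) -> float:
        return self.pixel_area_m2 / 1e6

    @property
    def n_pixels(self) -> int:
        return int(self.shape[0]) * int(self.shape[1])

    def matches(self, other: "RasterGrid") -> bool:
        return (
            tuple(self.shape) == tuple(other.shape)
            and np.isclose(self.pixel_size, other.pixel_size)
            and np.allclose(self.origin, other.origin)
        )

    def require_match(self, other: "RasterGrid", what: str = "layer") -> None:
        if not self.matches(other):
            raise AlignmentError(
                f"{what} grid {other.shape}@{other.pixel_size} m does not match "
                f"run grid {self.shape}@{self.pixel_size} m"
            )


@dataclass
class LandUseMap:
    """Categorical land-use raster over the codes in :data:`CLASS_CODES`."""

    classes: np.ndarray  # uint8, codes 1..6
    grid: RasterGrid
    zones: np.ndarray | None = None  # optional categorical zone raster

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.shape != tuple(self.grid.shape):
            raise AlignmentError(
                f"land-use array shape {self.classes.shape} != grid {self.grid.shape}"
            )
        valid = set(CLASS_CODES.values()) | {0}  # 0 = nodata
        present = set(np.unique(self.classes).tolist())
        if not present <= valid:
            raise ValidationError(f"unknown class codes: {sorted(present - valid)}")

    def class_counts(self) -> dict[int, int]:
        counts = np.bincount(self.classes.ravel(), minlength=7)
        return {code: int(counts[code]) for code in CLASS_CODES.values()}

    def class_areas_km2(self) -> dict[int, float]:
        a = self.grid.pixel_area_km2
        return {c: n * a for c, n in self.class_counts().items()}

    def proportions(self) -> dict[int, float]:
        n = self.classes.size
        return {c: cnt / n for c, cnt in self.class_counts().items()}

    def copy(self) -> "LandUseMap":
        return LandUseMap(self.classes.copy(), self.grid,
                          None if self.zones is None else self.zones.copy())


def require_aligned(grid: RasterGrid, *arrays: np.ndarray, what: str = "raster") -> None:
    """Raise :class:`AlignmentError` unless every array has the grid's shape."""
    for a in arrays:
        if np.asarray(a).shape != tuple(grid.shape):
            raise AlignmentError(
                f"{what} shape {np.asarray(a).shape} does not match grid {grid.shape}"
            )
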