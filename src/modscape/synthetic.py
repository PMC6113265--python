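"""Seed-reproducible synthetic mountain-oasis-desert (MODS) landscapes.

The generator emulates the structure of an arid mountain-oasis-desert
prefecture without any real geodata: elevation descends from north to south,
precipitation increases with altitude, a riverine oasis corridor crosses the
low ground, and the land-use composition matches a requested mix (the shipped
default is 34.9% grassland, 7.3% forest, 3.6% cropland, 52.3% bare land and
1.9% water/built-up).  Everything downstream — transition-matrix estimation,
ANN-CA allocation, the six ES models and the interaction coding — is testable
on these bundles with known statistical structure.

All randomness flows through one ``numpy.random.Generator`` seeded per call;
identical config + seed gives bit-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import (
    CLASS_CODES,
    ZONE_CODES,
    ConfigurationError,
    LandUseMap,
    RasterGrid,
    ValidationError,
)
from .landuse import TransitionMatrix

#: land-use mix of the emulated prefecture in the base year (fractions of area)
DEFAULT_PROPORTIONS = {
    "cropland": 0.036,
    "forest": 0.073,
    "grassland": 0.349,
    "water": 0.012,
    "built-up": 0.007,
    "bare": 0.523,
}


@dataclass
class SyntheticConfig:
    """Configuration of one synthetic landscape draw.

    Proportions must sum to 1 (tolerance 1e-9); the seed is mandatory so that
    every bundle is reproducible.
    """

    shape: tuple[int, int] = (100, 100)
    pixel_size: float = 100.0
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    elevation_range: tuple[float, float] = (500.0, 3500.0)
    precip_base: float = 140.0        # mm/a on the valley floor
    precip_lapse: float = 0.045       # mm/a per m of elevation
    temperature_sea_level: float = 18.0   # deg C extrapolated to 0 m
    temperature_lapse: float = 0.0065     # deg C per m
    oasis_buffer_px: int = 6          # half-width of the riverine oasis corridor
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.proportions) - set(CLASS_CODES)
        if unknown:
            raise ConfigurationError(f"unknown classes in proportions: {sorted(unknown)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"proportions must sum to 1, got {total}")
        if any(p < 0 for p in self.proportions.values()):
            raise ConfigurationError("proportions must be non-negative")
        if self.shape[0] < 20 or self.shape[1] < 20:
            raise ConfigurationError(f"grid must be at least 20x20, got {self.shape}")


@dataclass
class LandscapeBundle:
    """A synthetic landscape: land use, terrain, climate, soil, wind, zones."""

    landuse_t0: LandUseMap
    dem: np.ndarray                 # m
    precipitation: np.ndarray       # mm/a
    temperature: np.ndarray         # deg C
    et0: np.ndarray                 # mm/a reference evapotranspiration
    soil_stack: dict[str, np.ndarray]   # sand/silt/clay fractions, organic matter %
    wind_stack: dict[str, np.ndarray]   # RWEQ weather/erodibility/crust/roughness
    zones: np.ndarray               # ZONE_CODES raster
    grid: RasterGrid
    config: SyntheticConfig


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Spatially correlated unit-variance noise (Gaussian filter on white noise)."""
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=sigma, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _target_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n pixels to the requested proportions."""
    raw = {c: p * n for c, p in proportions.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:short]:
        counts[c] += 1
    return counts


def generate_landscape(config: SyntheticConfig) -> LandscapeBundle:
    """Draw one synthetic MODS landscape.

    Elevation falls from the northern edge (row 0) southwards with correlated
    relief; precipitation is base + lapse x elevation plus correlated noise,
    so it increases with altitude by construction.  A meandering river runs
    north-south; zones are mountain (top elevation tercile), oasis (lower
    ground within ``oasis_buffer_px`` of the river) and desert (the rest).
    Land-use classes are placed by zone-conditional priors (cropland and
    built-up hug the river inside the oasis, forest sits high and wet,
    bare land fills the desert) and an exact-count fill, so realized
    composition matches the request to within rounding.
    """
    rows, cols = config.shape
    rng = np.random.default_rng(config.seed)
    grid = RasterGrid(shape=(rows, cols), pixel_size=config.pixel_size)

    # --- terrain: north-to-south descent + correlated relief
    lo, hi = config.elevation_range
    gradient = np.linspace(1.0, 0.0, rows)[:, None] * np.ones((1, cols))
    relief = _smooth_noise(rng, (rows, cols), sigma=max(rows, cols) / 12)
    dem = lo + (hi - lo) * np.clip(gradient + 0.18 * relief, 0.0, 1.0)

    # --- river: meandering north-south line on the low ground
    t = np.arange(rows)
    meander = _smooth_noise(rng, (rows, 1), sigma=rows / 8).ravel()
    river_col = np.clip(
        cols / 2 + 0.15 * cols * meander, 1, cols - 2).astype(int)
    river = np.zeros((rows, cols), dtype=bool)
    river[t, river_col] = True
    dist_river = ndimage.distance_transform_edt(~river)

    # --- climate
    precip_noise = _smooth_noise(rng, (rows, cols), sigma=max(rows, cols) / 10)
    precipitation = (
        config.precip_base
        + config.precip_lapse * (dem - lo)
        + 6.0 * precip_noise
    )
    precipitation = np.clip(precipitation, 5.0, None)
    temperature = (
        config.temperature_sea_level
        - config.temperature_lapse * dem
        + 0.4 * _smooth_noise(rng, (rows, cols), sigma=max(rows, cols) / 10)
    )
    # reference ET: high on the hot dry valley floor, low in the cold mountains
    et0 = np.clip(900.0 + 45.0 * temperature
                  + 25.0 * _smooth_noise(rng, (rows, cols), sigma=max(rows, cols) / 10),
                  200.0, None)

    # --- zones: elevation terciles + river buffer
    q_hi = np.quantile(dem, 2.0 / 3.0)
    q_lo = np.quantile(dem, 1.0 / 3.0)
    zones = np.full((rows, cols), ZONE_CODES["desert"], dtype=np.uint8)
    zones[dem >= q_hi] = ZONE_CODES["mountain"]
    oasis = (dem < q_hi) & (dist_river <= config.oasis_buffer_px)
    zones[oasis] = ZONE_CODES["oasis"]

    # --- land-use placement: per-class affinity scores, exact-count greedy fill
    mountain = zones == ZONE_CODES["mountain"]
    desert = zones == ZONE_CODES["desert"]
    nz = lambda: 0.3 * _smooth_noise(rng, (rows, cols), sigma=3.0)
    near_river = np.exp(-dist_river / max(config.oasis_buffer_px, 1))
    elev_norm = (dem - dem.min()) / max(dem.max() - dem.min(), 1e-9)
    scores = {
        "water": 3.0 * river.astype(float) + 0.5 * near_river + nz(),
        "cropland": 2.0 * oasis + 1.2 * near_river - 1.0 * mountain + nz(),
        "built-up": 1.8 * oasis + 1.5 * near_river - 1.0 * mountain + nz(),
        "forest": 2.0 * mountain + 1.5 * elev_norm + nz(),
        "grassland": 1.2 * mountain + 0.8 * (1 - np.abs(elev_norm - 0.55) * 2) + nz(),
        "bare": 2.0 * desert + 1.0 * (1 - elev_norm) + nz(),
    }
    counts = _target_counts(config.proportions, rows * cols)
    landuse = np.zeros((rows, cols), dtype=np.uint8)
    unassigned = np.ones(rows * cols, dtype=bool)
    # rarest classes pick first so their best habitat is still free
    for cls in sorted(counts, key=counts.get):
        need = counts[cls]
        if need == 0:
            continue
        s = scores[cls].ravel().copy()
        s[~unassigned] = -np.inf
        pick = np.argpartition(-s, need - 1)[:need]
        landuse.ravel()[pick] = CLASS_CODES[cls]
        unassigned[pick] = False

    # --- soil: texture fractions and organic matter, zone-trended
    sand = np.clip(0.35 + 0.35 * desert - 0.15 * mountain
                   + 0.08 * _smooth_noise(rng, (rows, cols), 5.0), 0.05, 0.95)
    clay = np.clip(0.20 + 0.10 * oasis + 0.05 * _smooth_noise(rng, (rows, cols), 5.0),
                   0.02, 0.6)
    clay = np.minimum(clay, 0.95 - sand)
    silt = np.clip(1.0 - sand - clay, 0.02, None)
    om = np.clip(1.2 + 1.8 * mountain + 0.8 * oasis
                 + 0.3 * _smooth_noise(rng, (rows, cols), 5.0), 0.1, 6.0)
    soil_stack = {"sand": sand, "silt": silt, "clay": clay, "organic_matter": om}

    # --- wind factors (RWEQ inputs): strongest over the open desert floor
    wf = np.clip(40.0 + 35.0 * desert - 20.0 * mountain
                 + 6.0 * _smooth_noise(rng, (rows, cols), 6.0), 1.0, None)
    ef = np.clip(0.35 + 0.15 * sand + 0.04 * _smooth_noise(rng, (rows, cols), 6.0),
                 0.05, 0.9)
    scf = np.clip(0.6 + 0.2 * _smooth_noise(rng, (rows, cols), 6.0), 0.1, 1.0)
    ka = np.clip(0.8 + 0.1 * _smooth_noise(rng, (rows, cols), 6.0), 0.3, 1.0)
    wind_stack = {"WF": wf, "EF": ef, "SCF": scf, "Ka": ka}

    lu_map = LandUseMap(landuse, grid, zones)
    return LandscapeBundle(
        landuse_t0=lu_map, dem=dem, precipitation=precipitation,
        temperature=temperature, et0=et0, soil_stack=soil_stack,
        wind_stack=wind_stack, zones=zones, grid=grid, config=config,
    )


def generate_markov_pair(
    matrix: TransitionMatrix,
    n_pixels: int,
    seed: int,
    initial_probs: np.ndarray | None = None,
) -> tuple[LandUseMap, LandUseMap]:
    """Draw an i.i.d. (t0, t1) map pair whose transitions follow ``matrix``.

    Each pixel's t0 class is drawn from ``initial_probs`` (uniform over the
    matrix classes by default) and its t1 class independently from the t0
    class's row of the matrix.  The maps come back as n x 1 rasters — a
    fixture for transition-matrix estimation, with no spatial structure.
    """
    matrix.validate()
    k = len(matrix.classes)
    codes = np.array([CLASS_CODES[c] for c in matrix.classes], dtype=np.uint8)
    rng = np.random.default_rng(seed)
    grid = RasterGrid(shape=(int(n_pixels), 1), pixel_size=100.0)
    if n_pixels == 0:
        empty = np.zeros((0, 1), dtype=np.uint8)
        return LandUseMap(empty, grid), LandUseMap(empty.copy(), grid)
    p0 = np.full(k, 1.0 / k) if initial_probs is None else np.asarray(initial_probs, float)
    idx0 = rng.choice(k, size=n_pixels, p=p0 / p0.sum())
    # vectorized row-conditional draw via inverse CDF
    cum = np.cumsum(matrix.probs, axis=1)
    u = rng.random(n_pixels)
    idx1 = (u[:, None] > cum[idx0]).sum(axis=1).clip(max=k - 1)
    t0 = codes[idx0].reshape(-1, 1)
    t1 = codes[idx1].reshape(-1, 1)
    return LandUseMap(t0, grid), LandUseMap(t1, grid)


def generate_driving_factors(
    bundle: LandscapeBundle, n_factors: int = 16, seed: int = 0
) -> np.ndarray:
    """Stack of continuous driving factors for suitability training.

    The first factors are physically meaningful — slope from the DEM,
    Euclidean pixel distance to water and to built-up, elevation,
    precipitation, temperature, reference ET and distance to the nearest
    river-corridor pixel — and the remainder are spatially correlated noise
    fields standing in for unavailable socioeconomic layers.  All factors are
    finite everywhere and aligned with the bundle grid.
    """
    if n_factors < 3:
        raise ConfigurationError("need at least 3 driving factors")
    rng = np.random.default_rng(seed)
    dem = bundle.dem
    gy, gx = np.gradient(dem, bundle.grid.pixel_size)
    slope = np.degrees(np.arctan(np.hypot(gy, gx)))

    def dist_to(code: int) -> np.ndarray:
        mask = bundle.landuse_t0.classes == code
        if not mask.any():
            return np.zeros_like(dem)
        return ndimage.distance_transform_edt(~mask)

    base = [
        slope,
        dist_to(CLASS_CODES["water"]),
        dist_to(CLASS_CODES["built-up"]),
        dem,
        bundle.precipitation,
        bundle.temperature,
        bundle.et0,
        dist_to(CLASS_CODES["cropland"]),
    ]
    factors = base[:n_factors]
    while len(factors) < n_factors:
        factors.append(_smooth_noise(rng, dem.shape, sigma=4.0))
    stack = np.stack(factors)
    if not np.all(np.isfinite(stack)):
        raise ValidationError("driving factors must be finite everywhere")
    return stack
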