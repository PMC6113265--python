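"""Per-pixel quantification of the six ecosystem services.

* Water yield (WY, mm/a): annual water balance, Y = (1 - AET/P) x P, with
  actual evapotranspiration from a Budyko-Zhang curve of the aridity index
  Kc x ET0 / P and a per-class plant-available-water coefficient w.
* Crop production (CP, index): Miami-type climatic productivity (minimum of
  a temperature- and a precipitation-limited term) scaled by a land-use level
  index on cropland pixels, zero elsewhere.
* Soil conservation (SC, t km-2 a-1): USLE — potential erosion R K L S minus
  actual erosion R K L S C P.
* Sand fixation (SF, t km-2 a-1): RWEQ — potential wind-driven sand transport
  with bare ground minus transport under the class's vegetation cover factor.
* Carbon sequestration (CS, mass per area): sum of the four carbon pools of a
  pixel's class; regional total CT = sum over classes of density x area.
* Aesthetic value (AV, survey score 0-5): per-class mean questionnaire score,
  with subtype scores combined by area weights.

Every operation is deterministic and pixelwise (no RNG, no neighbourhood
coupling), hence invariant to raster tiling and traversal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import (
    CLASS_CODES,
    ZONE_NAMES,
    LandUseMap,
    RasterGrid,
    ValidationError,
    require_aligned,
)

#: canonical ES keys in this package
ES_KEYS = ("WY", "CP", "SC", "SF", "CS", "AV")


@dataclass
class ESLayer:
    """One continuous ecosystem-service raster with units and a year tag."""

    name: str
    values: np.ndarray
    units: str
    grid: RasterGrid
    year: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        require_aligned(self.grid, self.values, what=f"ES layer {self.name}")


# ---------------------------------------------------------------------------
# Water yield
# ---------------------------------------------------------------------------

@dataclass
class WaterYieldInputs:
    """Inputs of the annual water-balance model.

    ``kc`` scales reference ET into potential ET per land-use class
    (crop/vegetation coefficient); ``w`` is the Budyko-Zhang plant-available
    water coefficient per class (larger w -> vegetation evaporates a larger
    share of supply at a given aridity).
    """

    precipitation: np.ndarray       # mm/a, >= 0
    et0: np.ndarray                 # mm/a reference ET
    kc: dict[str, float] = field(default_factory=lambda: {
        "cropland": 0.95, "forest": 1.0, "grassland": 0.65,
        "water": 1.1, "built-up": 0.3, "bare": 0.2,
    })
    w: dict[str, float] = field(default_factory=lambda: {
        "cropland": 1.5, "forest": 2.0, "grassland": 1.0,
        "water": 2.0, "built-up": 0.5, "bare": 0.5,
    })


def budyko_aet_ratio(aridity: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Budyko-Zhang evaporative index AET/P as a function of aridity ET0'/P.

    ``AET/P = (1 + w phi) / (1 + w phi + 1/phi)`` with phi the aridity index.
    Bounded in [0, 1]; -> 0 as phi -> 0 (energy limit) and -> 1 as
    phi -> inf (water limit).
    """
    phi = np.asarray(aridity, dtype=float)
    out = np.zeros_like(phi)
    pos = phi > 0
    out[pos] = (1 + w[pos] * phi[pos]) / (1 + w[pos] * phi[pos] + 1.0 / phi[pos])
    return np.clip(out, 0.0, 1.0)


def water_yield(inputs: WaterYieldInputs, landuse: LandUseMap,
                year: int | None = None, aet_model=None) -> ESLayer:
    """Annual water yield Y = (1 - AET/P) x P per pixel, in mm/a.

    By default AET comes from the Budyko-Zhang curve of Kc x ET0 / P with
    the pixel class's coefficients, so 0 <= Y <= P everywhere.  The water
    balance itself is model-agnostic: ``aet_model(aridity, w) -> AET/P``
    swaps in any evaporative-index curve bounded in [0, 1].  Pixels with
    P = 0 get Y = 0 and are counted in ``meta['zero_precip_pixels']``.
    """
    if aet_model is None:
        aet_model = budyko_aet_ratio
    p = np.asarray(inputs.precipitation, dtype=float)
    et0 = np.asarray(inputs.et0, dtype=float)
    require_aligned(landuse.grid, p, et0, what="water-yield input")
    if np.any(p < 0):
        raise ValidationError("precipitation must be non-negative")
    kc = np.zeros_like(p)
    w = np.ones_like(p)
    for cls, code in CLASS_CODES.items():
        mask = landuse.classes == code
        kc[mask] = inputs.kc[cls]
        w[mask] = inputs.w[cls]
    y = np.zeros_like(p)
    pos = p > 0
    aridity = np.zeros_like(p)
    aridity[pos] = kc[pos] * et0[pos] / p[pos]
    ratio = np.clip(aet_model(aridity, w), 0.0, 1.0)
    y[pos] = (1.0 - ratio[pos]) * p[pos]
    return ESLayer("WY", y, "mm/a", landuse.grid, year,
                   meta={"zero_precip_pixels": int((~pos).sum())})


# ---------------------------------------------------------------------------
# Crop production
# ---------------------------------------------------------------------------

@dataclass
class CropParams:
    """Miami-model coefficients and the land-use level index raster.

    ``npp_max`` is the asymptotic climatic productivity; the temperature term
    is ``npp_max / (1 + exp(t_a - t_b T))`` and the precipitation term
    ``npp_max (1 - exp(-p_k P))``; P_v is their minimum (Liebig).  ``i_zrd``
    in [0, 1] grades cropland quality.
    """

    i_zrd: np.ndarray
    npp_max: float = 3000.0
    t_a: float = 1.315
    t_b: float = 0.119
    p_k: float = 0.000664


def miami_temperature_term(temperature: np.ndarray, params: CropParams) -> np.ndarray:
    t = np.asarray(temperature, dtype=float)
    return params.npp_max / (1.0 + np.exp(params.t_a - params.t_b * t))


def miami_precipitation_term(precipitation: np.ndarray, params: CropParams) -> np.ndarray:
    p = np.asarray(precipitation, dtype=float)
    return params.npp_max * (1.0 - np.exp(-params.p_k * p))


def crop_production(params: CropParams, temperature: np.ndarray,
                    precipitation: np.ndarray, landuse: LandUseMap,
                    year: int | None = None) -> ESLayer:
    """CP = P_v x I_zrd on cropland pixels, 0 elsewhere (mass index units)."""
    i_zrd = np.asarray(params.i_zrd, dtype=float)
    require_aligned(landuse.grid, i_zrd, temperature, precipitation,
                    what="crop-production input")
    crop = landuse.classes == CLASS_CODES["cropland"]
    if crop.any() and not np.all(np.isfinite(i_zrd[crop])):
        raise ValidationError("I_zrd missing (non-finite) on cropland pixels")
    if np.any((i_zrd < 0) | (i_zrd > 1)):
        raise ValidationError("I_zrd must lie in [0, 1]")
    pv = np.minimum(miami_temperature_term(temperature, params),
                    miami_precipitation_term(precipitation, params))
    cp = np.where(crop, pv * i_zrd, 0.0)
    return ESLayer("CP", cp, "index", landuse.grid, year)


# ---------------------------------------------------------------------------
# Soil conservation (USLE)
# ---------------------------------------------------------------------------

@dataclass
class USLEFactorStack:
    """USLE factor rasters and per-class cover / support-practice tables.

    R (rainfall erosivity), K (soil erodibility) and LS (combined slope
    length-steepness) are rasters; C (cover) and P (support practice) are
    per-class scalars in [0, 1].
    """

    r: np.ndarray
    k: np.ndarray
    ls: np.ndarray
    c_cover: dict[str, float] = field(default_factory=lambda: {
        "cropland": 0.22, "forest": 0.006, "grassland": 0.04,
        "water": 0.0, "built-up": 0.0, "bare": 1.0,
    })
    p_support: dict[str, float] = field(default_factory=lambda: {
        "cropland": 0.35, "forest": 1.0, "grassland": 1.0,
        "water": 0.0, "built-up": 0.0, "bare": 1.0,
    })

    def __post_init__(self) -> None:
        for name, arr in (("R", self.r), ("K", self.k), ("LS", self.ls)):
            if np.any(np.asarray(arr) < 0):
                raise ValidationError(f"USLE factor {name} must be non-negative")
        for table in (self.c_cover, self.p_support):
            for cls, v in table.items():
                if not 0 <= v <= 1:
                    raise ValidationError(f"USLE per-class factor for {cls} outside [0,1]")


def rainfall_erosivity(precipitation: np.ndarray) -> np.ndarray:
    """Annual-precipitation erosivity proxy R = 0.0483 P^1.61 (Wischmeier-type)."""
    return 0.0483 * np.asarray(precipitation, dtype=float) ** 1.61


def soil_erodibility_epic(sand: np.ndarray, silt: np.ndarray, clay: np.ndarray,
                          organic_matter: np.ndarray) -> np.ndarray:
    """EPIC erodibility K from texture fractions (0-1) and organic matter (%)."""
    sa, si, cl = (100 * np.asarray(a, float) for a in (sand, silt, clay))
    om = np.asarray(organic_matter, dtype=float)
    sn = 1.0 - sa / 100.0
    k = (0.2 + 0.3 * np.exp(-0.0256 * sa * (1 - si / 100.0))) \
        * (si / np.clip(cl + si, 1e-6, None)) ** 0.3 \
        * (1.0 - 0.25 * om / np.clip(om + np.exp(3.72 - 2.95 * om), 1e-6, None)) \
        * (1.0 - 0.7 * sn / np.clip(sn + np.exp(-5.51 + 22.9 * sn), 1e-6, None))
    return np.clip(k, 0.0, None)


def slope_length_steepness(dem: np.ndarray, pixel_size: float) -> np.ndarray:
    """Standard LS from DEM slope: L = (lambda/22.13)^m with lambda = pixel size,
    S piecewise in slope (McCool); returns the L x S product raster."""
    gy, gx = np.gradient(np.asarray(dem, float), pixel_size)
    slope_rad = np.arctan(np.hypot(gy, gx))
    beta = (np.sin(slope_rad) / 0.0896) / (3.0 * np.sin(slope_rad) ** 0.8 + 0.56)
    m = beta / (1 + beta)
    l = (pixel_size / 22.13) ** m
    s = np.where(np.tan(slope_rad) < 0.09,
                 10.8 * np.sin(slope_rad) + 0.03,
                 16.8 * np.sin(slope_rad) - 0.5)
    return l * np.clip(s, 0.0, None)


def usle_soil_conservation(stack: USLEFactorStack, landuse: LandUseMap,
                           year: int | None = None) -> ESLayer:
    """Soil conservation A_c = A_r - A with A = R K L S C P and A_r = R K L S.

    Since C x P <= 1 per class, A_c >= 0 everywhere; the actual- and
    potential-erosion rasters ride along in ``meta``.  Units t km-2 a-1
    under the shipped R/K conventions.
    """
    require_aligned(landuse.grid, stack.r, stack.k, stack.ls, what="USLE factor")
    c = np.zeros_like(np.asarray(stack.r, float))
    p = np.zeros_like(c)
    for cls, code in CLASS_CODES.items():
        mask = landuse.classes == code
        c[mask] = stack.c_cover[cls]
        p[mask] = stack.p_support[cls]
    a_r = np.asarray(stack.r, float) * stack.k * stack.ls
    a = a_r * c * p
    a_c = a_r - a
    return ESLayer("SC", a_c, "t/km2/a", landuse.grid, year,
                   meta={"actual_erosion": a, "potential_erosion": a_r})


# ---------------------------------------------------------------------------
# Sand fixation (RWEQ)
# ---------------------------------------------------------------------------

@dataclass
class RWEQFactorStack:
    """RWEQ factor rasters, per-class vegetation-cover factors, field length.

    WF weather factor, EF soil erodibility, SCF soil crust, Ka roughness;
    C_veg in (0, 1] per class (1 = bare ground); field_length_x is the
    downwind distance (m) at which transport is evaluated.
    """

    wf: np.ndarray
    ef: np.ndarray
    scf: np.ndarray
    ka: np.ndarray
    c_veg: dict[str, float] = field(default_factory=lambda: {
        "cropland": 0.25, "forest": 0.05, "grassland": 0.15,
        "water": 0.005, "built-up": 0.1, "bare": 1.0,
    })
    field_length_x: float = 50.0

    def __post_init__(self) -> None:
        for name, arr in (("WF", self.wf), ("EF", self.ef),
                          ("SCF", self.scf), ("Ka", self.ka)):
            if np.any(np.asarray(arr) < 0):
                raise ValidationError(f"RWEQ factor {name} must be non-negative")
        for cls, v in self.c_veg.items():
            if not 0 < v <= 1:
                raise ValidationError(f"C_veg for {cls} must lie in (0, 1]")


def rweq_transport(combined_factor: np.ndarray, x: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RWEQ transport at downwind distance x from the combined factor product.

    With Pi = WF x EF x SCF x Ka x C:
    ``Qmax = 109.8 Pi`` (maximum transportable sand mass),
    ``S = 105.71 Pi^-0.3711`` (critical field length), and
    ``Q(x) = (2 x / S^2) Qmax exp(-(x/S)^2)`` taking the transport equation's
    height symbol as the same downwind distance x.  Where Pi = 0, Qmax and
    Q(x) are 0 and S is NaN (flagged undefined).
    """
    pi = np.asarray(combined_factor, dtype=float)
    if np.any(pi < 0):
        raise ValidationError("combined RWEQ factor product must be non-negative")
    qmax = 109.8 * pi
    s = np.full_like(pi, np.nan)
    pos = pi > 0
    s[pos] = 105.71 * pi[pos] ** (-0.3711)
    q = np.zeros_like(pi)
    q[pos] = (2.0 * x / s[pos] ** 2) * qmax[pos] * np.exp(-((x / s[pos]) ** 2))
    return qmax, s, q


def rweq_sand_fixation(stack: RWEQFactorStack, landuse: LandUseMap,
                       year: int | None = None) -> ESLayer:
    """Sand fixation dQ = Q0 - Qv in t km-2 a-1.

    Q0 is potential transport with bare ground (vegetation factor forced to
    1; crust and roughness keep their mapped values), Qv actual transport
    with the class's vegetation factor.  dQ >= 0 since C_veg <= 1.
    """
    require_aligned(landuse.grid, stack.wf, stack.ef, stack.scf, stack.ka,
                    what="RWEQ factor")
    base = (np.asarray(stack.wf, float) * stack.ef * stack.scf * stack.ka)
    c_map = np.ones_like(base)
    for cls, code in CLASS_CODES.items():
        c_map[landuse.classes == code] = stack.c_veg[cls]
    x = stack.field_length_x
    _, _, q0 = rweq_transport(base, x)             # bare potential: C_veg = 1
    _, _, qv = rweq_transport(base * c_map, x)     # with vegetation
    dq = q0 - qv
    return ESLayer("SF", dq, "t/km2/a", landuse.grid, year,
                   meta={"undefined_pixels": int((base == 0).sum())})


# ---------------------------------------------------------------------------
# Carbon sequestration
# ---------------------------------------------------------------------------

@dataclass
class CarbonDensityTable:
    """Per-class densities of the four carbon pools (mass per area).

    Pools: aboveground biomass, belowground biomass, soil organic carbon,
    dead organic matter.  Units are whatever the table is given in (the
    shipped defaults are kg m-2); the regional total CT inherits
    mass = density x m^2.
    """

    pools: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "cropland": (0.6, 0.2, 8.0, 0.1),
            "forest": (6.0, 1.5, 12.0, 0.8),
            "grassland": (0.5, 1.0, 9.0, 0.2),
            "water": (0.0, 0.0, 0.0, 0.0),
            "built-up": (0.1, 0.0, 4.0, 0.0),
            "bare": (0.05, 0.05, 2.0, 0.0),
        })

    def __post_init__(self) -> None:
        for cls, pools in self.pools.items():
            if any(v < 0 for v in pools):
                raise ValidationError(f"carbon densities for {cls} must be >= 0")

    def total_density(self, cls: str) -> float:
        return float(sum(self.pools[cls]))


def carbon_sequestration(table: CarbonDensityTable, landuse: LandUseMap,
                         year: int | None = None) -> tuple[ESLayer, float]:
    """Per-pixel carbon density (sum of the four pools) and regional total CT.

    CT = sum over classes of total density x class area (pixel count x pixel
    area in m^2).  Raises naming the class if a mapped class is missing from
    the table.
    """
    density = np.zeros(landuse.classes.shape, dtype=float)
    present = set(np.unique(landuse.classes).tolist()) - {0}
    for code in present:
        cls = {v: k for k, v in CLASS_CODES.items()}[code]
        if cls not in table.pools:
            raise ValidationError(f"class {cls!r} missing from the carbon density table")
        density[landuse.classes == code] = table.total_density(cls)
    ct = float(density.sum() * landuse.grid.pixel_area_m2)
    return ESLayer("CS", density, "mass/m2", landuse.grid, year,
                   meta={"CT": ct}), ct


# ---------------------------------------------------------------------------
# Aesthetic value
# ---------------------------------------------------------------------------

@dataclass
class AVScoreTable:
    """Mean survey scores (0-5) per land-use class, optionally from subtypes.

    ``subtypes`` maps a class to ``[(score, area_weight), ...]``; the class
    score is then the area-weighted mean of its subtype scores.
    """

    scores: dict[str, float] = field(default_factory=lambda: {
        "cropland": 3.8, "forest": 4.6, "grassland": 2.5,
        "water": 4.2, "built-up": 2.2, "bare": 0.8,
    })
    subtypes: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, sub in self.subtypes.items():
            wsum = sum(w for _, w in sub)
            if abs(wsum - 1.0) > 1e-9:
                raise ValidationError(f"subtype weights for {cls} must sum to 1")
            self.scores[cls] = sum(s * w for s, w in sub)
        for cls, s in self.scores.items():
            if not 0 <= s <= 5:
                raise ValidationError(f"AV score for {cls} outside [0, 5]: {s}")

    def score(self, cls: str) -> float:
        if cls not in self.scores:
            raise ValidationError(f"class {cls!r} has no aesthetic score")
        return self.scores[cls]


def aesthetic_value(table: AVScoreTable, landuse: LandUseMap,
                    year: int | None = None) -> ESLayer:
    """Per-pixel aesthetic value = the survey score of the pixel's class."""
    av = np.zeros(landuse.classes.shape, dtype=float)
    present = set(np.unique(landuse.classes).tolist()) - {0}
    for code in present:
        cls = {v: k for k, v in CLASS_CODES.items()}[code]
        av[landuse.classes == code] = table.score(cls)
    return ESLayer("AV", av, "score", landuse.grid, year)


# ---------------------------------------------------------------------------
# Zonal statistics
# ---------------------------------------------------------------------------

def zonal_totals(layer: ESLayer, zones: np.ndarray) -> pd.DataFrame:
    """Per-zone and whole-area sum and mean of one ES layer.

    The whole-area row is the sum/pooled mean over all zone rows.  Totals are
    plain pixel-value sums; multiply by pixel area externally if the layer is
    a per-area density.
    """
    require_aligned(layer.grid, zones, what="zone raster")
    z = np.asarray(zones).ravel()
    v = layer.values.ravel()
    rows = []
    for code in np.unique(z):
        mask = z == code
        name = ZONE_NAMES.get(int(code), str(int(code)))
        rows.append({"zone": name, "n_pixels": int(mask.sum()),
                     "total": float(v[mask].sum()),
                     "mean": float(v[mask].mean()) if mask.any() else 0.0})
    whole = {"zone": "all", "n_pixels": int(v.size),
             "total": float(v.sum()),
             "mean": float(v.mean()) if v.size else 0.0}
    return pd.DataFrame(rows + [whole])
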