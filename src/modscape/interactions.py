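"""Multi-ES trade-off and synergy identification.

Two scales:

* regional — whole-area ES totals per year are min-max normalized (the data
  behind flower diagrams) and classified into increasing / decreasing /
  unchanged trends, from which every ES pair is labelled synergy (both move
  the same way), trade-off (opposite ways) or neutral (one unchanged);
* grid — per-pixel change of each ES between two years is reclassified to a
  digit (1 increase, 2 decrease, 3 unchanged), the six digits are
  concatenated in the fixed order (WY, CP, SC, SF, CS, AV) into a six-digit
  code, codes covering less than a minimum summed area are pooled as "other
  interactions", and the surviving interaction classes are cross-tabulated
  against land-use transitions to attribute their causes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .grids import CLASS_NAMES, AlignmentError, RasterGrid, ValidationError
from .es import ESLayer

#: fixed digit order of the six services in every code
ES_ORDER = ("WY", "CP", "SC", "SF", "CS", "AV")
#: presentation order used in human-readable labels
LABEL_ORDER = ("SC", "CP", "CS", "AV", "WY", "SF")

INCREASE, DECREASE, UNCHANGED = 1, 2, 3
OTHER_LABEL = "other interactions"
_MINUS = "−"  # typographic minus used in labels


@dataclass
class InteractionCodeRaster:
    """Per-pixel six-digit interaction codes over :data:`ES_ORDER`.

    Codes are stored as integers (e.g. 111122); 0 marks pixels pooled into
    "other interactions" by the area filter.  ``legend`` lists retained codes
    with their labels and areas, sorted by area descending.
    """

    codes: np.ndarray
    grid: RasterGrid
    legend: list[dict] = field(default_factory=list)
    es_order: tuple[str, ...] = ES_ORDER

    def code_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.codes, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Min-max normalize a series to [0, 1]; a constant series maps to all 0."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("series must have length >= 2")
    if not np.all(np.isfinite(v)):
        raise ValidationError("series contains non-finite values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


@dataclass
class TrendClassification:
    """Per-ES trend labels and pairwise interaction labels."""

    per_es: dict[str, str]                      # increase / decrease / unchanged / mixed
    pairs: dict[tuple[str, str], str]           # synergy / trade-off / neutral

    def pair(self, a: str, b: str) -> str:
        return self.pairs[tuple(sorted((a, b)))]


def classify_regional_trends(
    series: dict[str, np.ndarray],
    unchanged_threshold: float = 0.01,
) -> TrendClassification:
    """Label each ES series and every ES pair from whole-area annual totals.

    An ES increases (decreases) if its total relative change over the series
    exceeds ``unchanged_threshold`` in magnitude and the year-to-year steps
    never contradict the overall sign by more than the threshold; below the
    threshold it is unchanged.  Series with large swings in both directions
    are labelled "mixed", excluded from pairing, and warned about.  Pairs:
    two increasing or two decreasing ES are a synergy, opposite signs a
    trade-off, any unchanged member neutral.
    """
    lengths = {len(np.asarray(v)) for v in series.values()}
    if len(lengths) > 1:
        raise ValidationError("all ES series must share the same years")
    per_es: dict[str, str] = {}
    for name, v in series.items():
        v = np.asarray(v, dtype=float)
        scale = max(abs(v[0]), abs(v).max(), 1e-12)
        rel_total = (v[-1] - v[0]) / scale
        diffs = np.diff(v) / scale
        if abs(rel_total) <= unchanged_threshold:
            per_es[name] = "unchanged"
        elif rel_total > 0 and np.all(diffs >= -unchanged_threshold):
            per_es[name] = "increase"
        elif rel_total < 0 and np.all(diffs <= unchanged_threshold):
            per_es[name] = "decrease"
        else:
            per_es[name] = "mixed"
            warnings.warn(f"ES {name}: non-monotone series with large swings, "
                          "excluded from pairwise labels")
    pairs: dict[tuple[str, str], str] = {}
    for a, b in combinations(sorted(series), 2):
        ta, tb = per_es[a], per_es[b]
        if "mixed" in (ta, tb):
            continue
        if "unchanged" in (ta, tb):
            pairs[(a, b)] = "neutral"
        elif ta == tb:
            pairs[(a, b)] = "synergy"
        else:
            pairs[(a, b)] = "trade-off"
    return TrendClassification(per_es, pairs)


def reclass_change(es_t0: ESLayer, es_t1: ESLayer, epsilon: float = 0.0) -> np.ndarray:
    """Reclassify the per-pixel change t1 - t0 of one ES to a digit raster.

    Digit 1 where the change exceeds ``epsilon``, 2 where it falls below
    ``-epsilon``, 3 otherwise (unchanged).
    """
    if es_t0.units != es_t1.units:
        raise ValidationError(
            f"unit mismatch: {es_t0.name} in {es_t0.units!r} vs {es_t1.units!r}")
    if es_t0.values.shape != es_t1.values.shape:
        raise AlignmentError("ES layers are misaligned")
    delta = es_t1.values - es_t0.values
    digits = np.full(delta.shape, UNCHANGED, dtype=np.uint8)
    digits[delta > epsilon] = INCREASE
    digits[delta < -epsilon] = DECREASE
    return digits


def encode_overlay(digit_rasters: dict[str, np.ndarray],
                   grid: RasterGrid,
                   order: tuple[str, ...] = ES_ORDER) -> InteractionCodeRaster:
    """Concatenate six aligned digit rasters into per-pixel six-digit codes.

    The concatenation follows ``order`` (most significant digit first) and is
    bijective with the digit tuple.
    """
    missing = set(order) - set(digit_rasters)
    if missing:
        raise ValidationError(f"missing digit rasters for: {sorted(missing)}")
    codes = np.zeros(tuple(grid.shape), dtype=np.int32)
    for name in order:
        d = np.asarray(digit_rasters[name])
        if d.shape != tuple(grid.shape):
            raise AlignmentError(f"digit raster {name} misaligned")
        if not np.isin(d, (1, 2, 3)).all():
            raise ValidationError(f"digit raster {name} has digits outside {{1,2,3}}")
        codes = codes * 10 + d.astype(np.int32)
    return InteractionCodeRaster(codes, grid)


def code_to_digits(code: int | str,
                   order: tuple[str, ...] = ES_ORDER) -> dict[str, int]:
    """Split a six-digit code back into its per-ES digits."""
    s = str(code)
    if len(s) != len(order) or any(ch not in "123" for ch in s):
        raise ValidationError(f"malformed interaction code: {code!r}")
    return {name: int(ch) for name, ch in zip(order, s)}


def decode_code(code: int | str, order: tuple[str, ...] = ES_ORDER) -> str:
    """Human-readable label of one code: increased ES with '+', decreased
    with a minus sign, unchanged omitted; all-unchanged reads "no change".

    Services are listed in the fixed presentation order, increasing group
    first.  Two or more services moving together form a synergy; any
    increasing vs decreasing pair is a trade-off (conveyed by the grouping).
    """
    digits = code_to_digits(code, order)
    inc = [es for es in LABEL_ORDER if digits.get(es) == INCREASE]
    dec = [es for es in LABEL_ORDER if digits.get(es) == DECREASE]
    if not inc and not dec:
        return "no change"
    parts = []
    if inc:
        parts.append(" ".join(f"{es}+" for es in inc))
    if dec:
        parts.append(" ".join(f"{es}{_MINUS}" for es in dec))
    return ", ".join(parts)


def filter_codes_by_area(codes: InteractionCodeRaster,
                         min_area_km2: float = 40.0) -> InteractionCodeRaster:
    """Pool codes whose summed area does not exceed ``min_area_km2``.

    Retention is strict: a code is kept only if pixel count x pixel area is
    strictly greater than the threshold.  Pooled pixels get code 0 and the
    label "other interactions"; the legend lists retained codes by area
    descending.  Total pixel count is conserved.
    """
    if min_area_km2 <= 0:
        raise ValidationError("min_area_km2 must be positive")
    area = codes.grid.pixel_area_km2
    counts = codes.code_counts()
    out = codes.codes.copy()
    legend = []
    for code, n in counts.items():
        if code == 0:
            continue
        if n * area > min_area_km2:
            legend.append({"code": code, "label": decode_code(code),
                           "n_pixels": n, "area_km2": n * area})
        else:
            out[codes.codes == code] = 0
    legend.sort(key=lambda e: e["area_km2"], reverse=True)
    n_other = int((out == 0).sum())
    if n_other:
        legend.append({"code": 0, "label": OTHER_LABEL,
                       "n_pixels": n_other, "area_km2": n_other * area})
    return InteractionCodeRaster(out, codes.grid, legend, codes.es_order)


def attribute_causes(codes: InteractionCodeRaster,
                     lu_t0, lu_t1) -> pd.DataFrame:
    """Cross-tabulate interaction classes against land-use transitions.

    Returns a tidy table with one row per (interaction class, from->to
    transition): pixel counts, the row percentage within the class, and a
    ``dominant`` flag on each class's most frequent transition.  Pixels whose
    class did not change are labelled "no transition".
    """
    if lu_t0.classes.shape != lu_t1.classes.shape or \
            lu_t0.classes.shape != tuple(codes.grid.shape):
        raise AlignmentError("code raster and land-use maps are misaligned")
    c = pd.Series(codes.codes.ravel())
    a = lu_t0.classes.ravel()
    b = lu_t1.classes.ravel()
    label_map = {0: OTHER_LABEL}
    label_map.update({code: decode_code(code) for code in c.unique() if code != 0})
    labels = c.map(label_map)
    trans = pd.Series(
        [f"{CLASS_NAMES[int(x)]}->{CLASS_NAMES[int(y)]}" for x, y in zip(a, b)])
    trans[a == b] = "no transition"
    df = (pd.DataFrame({"interaction": labels, "transition": trans})
          .groupby(["interaction", "transition"]).size()
          .rename("n_pixels").reset_index())
    totals = df.groupby("interaction")["n_pixels"].transform("sum")
    df["row_pct"] = 100.0 * df["n_pixels"] / totals
    idx_max = df.groupby("interaction")["n_pixels"].idxmax()
    df["dominant"] = False
    df.loc[idx_max, "dominant"] = True
    return df
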