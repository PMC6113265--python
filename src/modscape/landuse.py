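"""Land-use scenario simulation: Markov demand, ANN suitability, CA allocation.

Land demand is projected with a row-stochastic transition-probability matrix
estimated from two calibration maps, optionally altered by named policy
scenarios (business-as-usual BAU, economic development ED, ecological
conservation EC) that scale specific class-to-class conversion probabilities.
Spatial allocation follows the FLUS recipe: a single-hidden-layer neural
network turns driving factors into per-class suitability probabilities, and a
cellular automaton with neighbourhood enrichment, conversion costs and
self-adaptive inertia allocates the projected demand on the map.  Validation
is by per-class ROC-AUC of the suitability surface and Cohen's kappa of the
simulated map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.linalg import fractional_matrix_power
from sklearn.metrics import cohen_kappa_score, roc_auc_score
from sklearn.neural_network import MLPClassifier

from .grids import (
    CLASS_CODES,
    AlignmentError,
    ConfigurationError,
    LandUseMap,
    ValidationError,
    require_aligned,
)

DEFAULT_CLASSES = tuple(CLASS_CODES)  # cropland, forest, grassland, water, built-up, bare


# ---------------------------------------------------------------------------
# Transition matrices and demand
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    """Row-stochastic class-to-class transition probabilities over one period.

    Parameters
    ----------
    classes : ordered class labels (rows/columns).
    probs : square array, ``probs[i, j] = P(class i -> class j)`` per period.
    period_years : length of the period the probabilities refer to.
    meta : free-form provenance (e.g. step-split residual error).
    """

    classes: tuple[str, ...]
    probs: np.ndarray
    period_years: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.classes = tuple(self.classes)
        self.probs = np.asarray(self.probs, dtype=float)
        k = len(self.classes)
        if self.probs.shape != (k, k):
            raise ValidationError(f"probs shape {self.probs.shape} != ({k},{k})")
        self.validate()

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.probs < -atol) or np.any(self.probs > 1 + atol):
            raise ValidationError("transition probabilities must lie in [0, 1]")
        rows = self.probs.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValidationError(f"rows must sum to 1, got {rows}")

    def index(self, label: str) -> int:
        try:
            return self.classes.index(label)
        except ValueError:
            raise ValidationError(f"unknown class {label!r}; have {self.classes}") from None

    def copy(self) -> "TransitionMatrix":
        return TransitionMatrix(self.classes, self.probs.copy(),
                                self.period_years, dict(self.meta))


@dataclass
class ScenarioSpec:
    """Named set of multiplicative modifiers on transition probabilities.

    ``modifiers`` is a list of ``(from_class, to_class, relative_change)``;
    a relative change of +0.5 scales that conversion probability by 1.5,
    -1.0 suppresses it entirely.  BAU carries an empty list.
    """

    name: str
    modifiers: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for frm, to, change in self.modifiers:
            if change < -1:
                raise ValidationError(
                    f"{self.name}: relative change {change} for {frm}->{to} "
                    "is below -1 (would give a negative probability)"
                )
            if frm == to:
                raise ValidationError(
                    f"{self.name}: modifiers must target off-diagonal entries, got {frm}->{to}"
                )


def default_scenarios() -> dict[str, ScenarioSpec]:
    """The three shipped policy scenarios.

    * BAU — historical trends continue; the calibration matrix is unchanged.
    * ED — economic development: conversions of forest, grassland, water and
      bare land into cropland rise by 50%, and conversions of cropland,
      forest, grassland and bare land into built-up area rise by 200%.
    * EC — ecological conservation: conversions of forest, grassland and
      water into cropland and built-up stop entirely (-100%), conversions of
      bare land into cropland and built-up halve (-50%), and conversions of
      cropland back into forest, grassland and water rise by 80%.
    """
    ed = [(frm, "cropland", 0.5) for frm in ("forest", "grassland", "water", "bare")]
    ed += [(frm, "built-up", 2.0) for frm in ("cropland", "forest", "grassland", "bare")]
    ec = [(frm, to, -1.0) for frm in ("forest", "grassland", "water")
          for to in ("cropland", "built-up")]
    ec += [("bare", to, -0.5) for to in ("cropland", "built-up")]
    ec += [("cropland", to, 0.8) for to in ("forest", "grassland", "water")]
    return {
        "BAU": ScenarioSpec("BAU", []),
        "ED": ScenarioSpec("ED", ed),
        "EC": ScenarioSpec("EC", ec),
    }


@dataclass
class DemandTrajectory:
    """Per-class areas (km^2) along a list of years; total area is conserved."""

    classes: tuple[str, ...]
    years: list[int]
    areas: np.ndarray  # shape (n_years, n_classes)

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.years), len(self.classes)):
            raise ValidationError("areas shape must be (n_years, n_classes)")
        if np.any(self.areas < -1e-12):
            raise ValidationError("areas must be non-negative")
        totals = self.areas.sum(axis=1)
        if totals[0] > 0 and not np.allclose(totals, totals[0], rtol=1e-6):
            raise ValidationError("total area must be conserved across years")

    def at(self, year: int) -> dict[str, float]:
        i = self.years.index(year)
        return dict(zip(self.classes, self.areas[i]))


def estimate_transition_matrix(
    map_t0: LandUseMap,
    map_t1: LandUseMap,
    period_years: float,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
) -> TransitionMatrix:
    """Cross-tabulate two aligned maps into a row-stochastic transition matrix.

    ``P[i, j]`` is the fraction of period-start pixels of class i found as
    class j at period end.  Classes absent at the start get an identity row
    (no invented dynamics).
    """
    if map_t0.classes.shape != map_t1.classes.shape:
        raise AlignmentError(
            f"maps are misaligned: {map_t0.classes.shape} vs {map_t1.classes.shape}"
        )
    codes = [CLASS_CODES[c] for c in classes]
    k = len(codes)
    code_to_idx = {c: i for i, c in enumerate(codes)}
    a = map_t0.classes.ravel()
    b = map_t1.classes.ravel()
    # map raster codes -> matrix indices (codes are small ints)
    lut = np.full(max(codes) + 1, -1, dtype=np.int64)
    for c, i in code_to_idx.items():
        lut[c] = i
    ia, ib = lut[a], lut[b]
    keep = (ia >= 0) & (ib >= 0)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (ia[keep], ib[keep]), 1)
    row_sums = counts.sum(axis=1)
    probs = np.eye(k)
    nz = row_sums > 0
    probs[nz] = counts[nz] / row_sums[nz, None]
    return TransitionMatrix(classes, probs, period_years,
                            meta={"counts": counts.tolist()})


def apply_scenario_modifiers(matrix: TransitionMatrix, scenario: ScenarioSpec) -> TransitionMatrix:
    """Scale targeted off-diagonal conversion probabilities; re-balance rows.

    Each targeted entry p becomes ``p * (1 + relative_change)``.  The diagonal
    (stay) probability absorbs the residual so each row still sums to 1; if
    the diagonal would go negative, all off-diagonal entries of that row are
    rescaled proportionally so the diagonal is exactly 0.
    """
    out = matrix.probs.copy()
    for frm, to, change in scenario.modifiers:
        i, j = matrix.index(frm), matrix.index(to)
        out[i, j] = matrix.probs[i, j] * (1.0 + change)
        if out[i, j] < 0:
            raise ValidationError(f"{scenario.name}: {frm}->{to} became negative")
    k = out.shape[0]
    for i in range(k):
        off = out[i].sum() - out[i, i]
        if off <= 1.0:
            out[i, i] = 1.0 - off
        else:  # diagonal would go negative: rescale off-diagonal mass to 1
            diag = out[i, i]
            out[i, i] = 0.0
            mask = np.arange(k) != i
            out[i, mask] *= 1.0 / off
    result = TransitionMatrix(matrix.classes, out, matrix.period_years,
                              meta={**matrix.meta, "scenario": scenario.name})
    return result


def step_split_matrix(matrix: TransitionMatrix, n_steps: int) -> TransitionMatrix:
    """Split a period matrix P into a per-step matrix Q with Q**n ~ P.

    Uses the principal fractional matrix power; any small negative entries
    produced by the eigendecomposition are clipped and rows renormalized
    (regularization fallback, flagged in ``meta``).  The Frobenius norm of
    ``Q**n - P`` is recorded in ``meta['split_residual']``.
    """
    if n_steps < 1:
        raise ValidationError("n_steps must be >= 1")
    if n_steps == 1:
        return matrix.copy()
    p = matrix.probs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # complex-to-real casts on defective spectra
        q = fractional_matrix_power(p, 1.0 / n_steps)
    q = np.real(q)
    regularized = bool(np.any(q < -1e-12))
    q = np.clip(q, 0.0, None)
    rows = q.sum(axis=1)
    rows[rows == 0] = 1.0
    q = q / rows[:, None]
    residual = float(np.linalg.norm(np.linalg.matrix_power(q, n_steps) - p, "fro"))
    return TransitionMatrix(
        matrix.classes, q, matrix.period_years / n_steps,
        meta={**matrix.meta, "split_residual": residual, "split_regularized": regularized},
    )


def project_demand(
    matrix: TransitionMatrix,
    initial_areas: dict[str, float] | np.ndarray,
    years: list[int],
) -> DemandTrajectory:
    """Iterate ``a_{t+1} = a_t @ P`` from the first listed year.

    One application of the matrix advances one matrix period; ``years`` must
    be spaced accordingly.  Total area is conserved exactly (row-stochastic P).
    """
    if isinstance(initial_areas, dict):
        a0 = np.array([initial_areas[c] for c in matrix.classes], dtype=float)
    else:
        a0 = np.asarray(initial_areas, dtype=float)
    if np.any(a0 < 0):
        raise ValidationError("initial areas must be non-negative")
    traj = [a0]
    for _ in years[1:]:
        traj.append(traj[-1] @ matrix.probs)
    return DemandTrajectory(matrix.classes, list(years), np.vstack(traj))


# ---------------------------------------------------------------------------
# Suitability (ANN) and validation statistics
# ---------------------------------------------------------------------------

@dataclass
class SuitabilitySurface:
    """Per-class suitability probability rasters, normalized to sum 1 per pixel."""

    classes: tuple[str, ...]
    probs: np.ndarray  # shape (n_classes, rows, cols)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValidationError("per-pixel class probabilities must sum to 1")


def train_suitability(
    factors: np.ndarray,
    landuse: LandUseMap,
    sample_fraction: float = 0.05,
    seed: int = 0,
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    hidden_factor: int = 2,
    min_class_samples: int = 50,
) -> SuitabilitySurface:
    """Train a one-hidden-layer network mapping driving factors to class probabilities.

    Factors are min-max normalized; training pixels are a uniform random
    sample of the map (``sample_fraction``).  The hidden layer has
    ``hidden_factor * n_factors`` units.  Classes absent from the map are
    excluded with a warning and receive a uniform share of the probability.

    Raises :class:`ConfigurationError` if fewer than 3 factors are given or a
    present class draws fewer than ``min_class_samples`` training pixels.
    """
    factors = np.asarray(factors, dtype=float)
    if factors.ndim != 3 or factors.shape[0] < 3:
        raise ConfigurationError("need a (n_factors, rows, cols) stack with >= 3 factors")
    n_f, rows, cols = factors.shape
    require_aligned(landuse.grid, factors[0], what="factor")
    rng = np.random.default_rng(seed)

    x_all = factors.reshape(n_f, -1).T
    lo, hi = x_all.min(axis=0), x_all.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    x_all = (x_all - lo) / span
    y_all = landuse.classes.ravel()

    n = y_all.size
    n_sample = max(int(round(sample_fraction * n)), 1)
    idx = rng.choice(n, size=n_sample, replace=False)
    x_tr, y_tr = x_all[idx], y_all[idx]

    present = [c for c in classes if CLASS_CODES[c] in set(np.unique(y_all).tolist())]
    absent = [c for c in classes if c not in present]
    if absent:
        warnings.warn(f"classes absent from map, assigned uniform probability: {absent}")
    # stratified top-up: rare present classes get extra pixels so each class
    # reaches min_class_samples (or its full extent if smaller)
    extra = []
    for c in present:
        code = CLASS_CODES[c]
        n_c = int(np.sum(y_tr == code))
        if n_c < min_class_samples:
            pool = np.flatnonzero(y_all == code)
            want = min(min_class_samples, pool.size) - n_c
            if want > 0:
                pool = np.setdiff1d(pool, idx, assume_unique=False)
                if pool.size:
                    extra.append(rng.choice(pool, size=min(want, pool.size),
                                            replace=False))
    if extra:
        idx = np.concatenate([idx] + extra)
        x_tr, y_tr = x_all[idx], y_all[idx]
    for c in present:
        n_c = int(np.sum(y_tr == CLASS_CODES[c]))
        if n_c < min(min_class_samples, int(np.sum(y_all == CLASS_CODES[c]))):
            raise ConfigurationError(
                f"class {c!r} drew only {n_c} training pixels (< {min_class_samples}); "
                "increase sample_fraction or grid size"
            )

    net = MLPClassifier(
        hidden_layer_sizes=(hidden_factor * n_f,),
        max_iter=500,
        random_state=int(rng.integers(2**31 - 1)),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings on tiny fixtures
        net.fit(x_tr, y_tr)
    proba = net.predict_proba(x_all)  # columns follow net.classes_

    k = len(classes)
    out = np.zeros((k, n), dtype=float)
    code_col = {int(code): i for i, code in enumerate(net.classes_)}
    for i, c in enumerate(classes):
        code = CLASS_CODES[c]
        if code in code_col:
            out[i] = proba[:, code_col[code]]
    # absent classes: small uniform floor, then renormalize
    if absent:
        floor = 1.0 / (10.0 * k)
        for i, c in enumerate(classes):
            if c in absent:
                out[i] = floor
    out /= out.sum(axis=0, keepdims=True)
    return SuitabilitySurface(
        classes, out.reshape(k, rows, cols),
        meta={"n_factors": n_f, "n_samples": n_sample, "seed": seed,
              "absent_classes": absent},
    )


def roc_auc(surface: SuitabilitySurface, actual: LandUseMap) -> dict[str, float | None]:
    """Per-class ROC-AUC of the suitability surface against an actual map.

    Rank-based (Mann-Whitney) computation; classes absent from the actual map
    are reported as ``None``.
    """
    require_aligned(actual.grid, surface.probs[0], what="suitability")
    y = actual.classes.ravel()
    out: dict[str, float | None] = {}
    for i, c in enumerate(surface.classes):
        pos = y == CLASS_CODES[c]
        if pos.all() or not pos.any():
            out[c] = None
            continue
        out[c] = float(roc_auc_score(pos, surface.probs[i].ravel()))
    return out


def auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC-AUC of raw scores against binary labels (rank-based)."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(scores)))


def kappa(simulated: LandUseMap, actual: LandUseMap) -> float:
    """Cohen's kappa between two aligned categorical maps.

    ``(p_o - p_e) / (1 - p_e)`` from the confusion matrix; if both maps are
    the same single class everywhere (p_e = 1), kappa is defined as 1.
    """
    if simulated.classes.shape != actual.classes.shape:
        raise AlignmentError("maps are misaligned")
    a = simulated.classes.ravel()
    b = actual.classes.ravel()
    if np.array_equal(a, b):
        return 1.0
    return float(cohen_kappa_score(a, b))


# ---------------------------------------------------------------------------
# Cellular-automaton allocation
# ---------------------------------------------------------------------------

@dataclass
class CAParams:
    """Tuning knobs of the cellular-automaton allocator.

    neighborhood_weights : per-class weight in [0, 1] scaling the
        neighbourhood-enrichment term (expansion strength of each class).
    conversion_cost : square matrix, ``cost[i, j] = 1`` allows i -> j,
        0 forbids it.  The diagonal is always allowed.
    window : odd Moore-neighbourhood size (default 3).
    demand_tolerance : convergence threshold as a fraction of total pixels.
    max_iterations : iteration cap; hitting it reports non-convergence.
    seed : RNG seed for the roulette-wheel draws.
    """

    classes: tuple[str, ...] = DEFAULT_CLASSES
    neighborhood_weights: np.ndarray | None = None
    conversion_cost: np.ndarray | None = None
    window: int = 3
    demand_tolerance: float = 0.005
    max_iterations: int = 200
    seed: int = 0
    inertia_gain: float = 1.1  # per-iteration multiplier bound for lagging classes

    def __post_init__(self) -> None:
        k = len(self.classes)
        if self.neighborhood_weights is None:
            self.neighborhood_weights = np.ones(k)
        self.neighborhood_weights = np.asarray(self.neighborhood_weights, dtype=float)
        if self.conversion_cost is None:
            self.conversion_cost = np.ones((k, k))
        self.conversion_cost = np.asarray(self.conversion_cost, dtype=float)
        np.fill_diagonal(self.conversion_cost, 1.0)
        if self.window < 3 or self.window % 2 == 0:
            raise ValidationError("window must be odd and >= 3")
        if self.demand_tolerance <= 0:
            raise ValidationError("demand_tolerance must be > 0")


def _neighborhood_share(classes: np.ndarray, code: int, window: int) -> np.ndarray:
    """Fraction of window neighbours (centre excluded) holding ``code``."""
    onehot = (classes == code).astype(float)
    total = ndimage.uniform_filter(onehot, size=window, mode="constant") * window**2
    share = (total - onehot) / (window**2 - 1)
    return np.clip(share, 0.0, 1.0)


def ca_allocate(
    initial: LandUseMap,
    surface: SuitabilitySurface,
    params: CAParams,
    demand: dict[str, float] | np.ndarray,
) -> tuple[LandUseMap, dict]:
    """Allocate per-class pixel demand on the map, FLUS-style.

    Each iteration computes, for every pixel and class, a combined
    probability = suitability x (neighbourhood share x class weight + a small
    floor so isolated seeds can appear) x conversion-cost gate x self-adaptive
    inertia; a seeded roulette wheel proposes a class per pixel, and proposals
    are accepted while they move lagging classes toward demand at the expense
    of over-allocated classes.  Inertia of a class rises while its allocation
    lags demand and falls when it overshoots.  Stops when every class count is
    within ``demand_tolerance`` (fraction of total pixels) of demand.

    Returns the allocated map and a diagnostics dict with ``converged``,
    ``iterations`` and the final per-class deviation.
    """
    classes = params.classes
    k = len(classes)
    codes = np.array([CLASS_CODES[c] for c in classes])
    rng = np.random.default_rng(params.seed)
    lu = initial.classes.copy()
    n_total = lu.size

    if isinstance(demand, dict):
        demand_px = np.array([demand[c] for c in classes], dtype=float)
    else:
        demand_px = np.asarray(demand, dtype=float)
    if abs(demand_px.sum() - n_total) > max(1.0, 0.01 * n_total):
        raise ValidationError(
            f"demand total {demand_px.sum():.1f} px does not match map size {n_total} px"
        )
    demand_px = demand_px * (n_total / demand_px.sum())  # exact closure

    suit = surface.probs.reshape(k, -1).T  # (n, k)
    tol_px = np.maximum(params.demand_tolerance * demand_px, 1.0)  # per class
    inertia = np.ones(k)
    prev_deficit = None
    converged = False
    it = 0

    lut = np.full(codes.max() + 1, -1, dtype=np.int64)
    for i, c in enumerate(codes):
        lut[c] = i

    for it in range(1, params.max_iterations + 1):
        counts = np.array([(lu == c).sum() for c in codes], dtype=float)
        deficit = demand_px - counts
        if np.all(np.abs(deficit) <= tol_px):
            converged = True
            break

        # self-adaptive inertia: push classes that lag, damp ones that overshoot
        if prev_deficit is not None:
            worsening = np.abs(deficit) > np.abs(prev_deficit)
            inertia = np.where(
                (deficit > tol_px) & worsening, inertia * params.inertia_gain, inertia)
            inertia = np.where(
                (deficit < -tol_px) & worsening, inertia / params.inertia_gain, inertia)
            inertia = np.clip(inertia, 1e-3, 1e3)
        prev_deficit = deficit

        neigh = np.stack(
            [_neighborhood_share(lu, c, params.window) for c in codes]).reshape(k, -1).T
        cur_idx = lut[lu.ravel()]
        gate = params.conversion_cost[cur_idx]  # (n, k)
        combined = (
            suit
            * (params.neighborhood_weights[None, :] * neigh + 0.01)
            * inertia[None, :]
            * gate
        )
        row_sum = combined.sum(axis=1, keepdims=True)
        row_sum[row_sum == 0] = 1.0
        combined /= row_sum

        # seeded roulette wheel, one proposal per pixel
        cum = np.cumsum(combined, axis=1)
        draw = rng.random((n_total, 1))
        proposal = (draw > cum).sum(axis=1).clip(max=k - 1)

        growing = deficit > tol_px
        shrinking = deficit < 0  # any surplus can donate
        new_lu = lu.ravel().copy()
        order = rng.permutation(k)
        remaining_give = np.maximum(-deficit, 0.0)
        for j in order:
            if not growing[j]:
                continue
            cand = np.flatnonzero(
                (proposal == j) & (cur_idx != j) & shrinking[cur_idx]
                & (params.conversion_cost[cur_idx, j] > 0)
            )
            if cand.size == 0:
                continue
            take = int(min(np.ceil(deficit[j]), cand.size))
            # favour the best-suited candidates among the roulette winners
            pick = cand[np.argsort(combined[cand, j])[::-1][:take]]
            # cap removals per donor class at its surplus
            for src in np.unique(cur_idx[pick]):
                src_pick = pick[cur_idx[pick] == src]
                cap = int(remaining_give[src])
                if src_pick.size > cap:
                    src_pick = src_pick[:cap]
                new_lu[src_pick] = codes[j]
                remaining_give[src] -= src_pick.size
        if np.array_equal(new_lu, lu.ravel()):
            # no admissible move this round; re-draw next iteration
            lu = new_lu.reshape(lu.shape)
            continue
        lu = new_lu.reshape(lu.shape)

    counts = np.array([(lu == c).sum() for c in codes], dtype=float)
    diagnostics = {
        "converged": converged,
        "iterations": it,
        "deviation_px": dict(zip(classes, (counts - demand_px).tolist())),
        "demand_px": dict(zip(classes, demand_px.tolist())),
    }
    return LandUseMap(lu, initial.grid, initial.zones), diagnostics
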