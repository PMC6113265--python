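"""Markov demand, scenario modifiers, suitability, validation stats, CA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modscape import (
    CAParams,
    CLASS_CODES,
    LandUseMap,
    RasterGrid,
    ScenarioSpec,
    TransitionMatrix,
    ValidationError,
    apply_scenario_modifiers,
    ca_allocate,
    default_scenarios,
    estimate_transition_matrix,
    generate_markov_pair,
    kappa,
    project_demand,
    roc_auc,
    step_split_matrix,
    train_suitability,
)
from modscape.landuse import DEFAULT_CLASSES, SuitabilitySurface, auc_from_scores


def _map(arr):
    arr = np.asarray(arr, dtype=np.uint8)
    return LandUseMap(arr, RasterGrid(shape=arr.shape))


class TestEstimateTransitionMatrix:
    def test_hand_cross_tabulation(self):
        t0 = _map([[1, 1], [1, 2]])
        t1 = _map([[1, 2], [1, 2]])
        m = estimate_transition_matrix(t0, t1, 15, classes=("cropland", "forest"))
        assert m.probs[0, 0] == pytest.approx(2 / 3)
        assert m.probs[0, 1] == pytest.approx(1 / 3)
        assert m.probs[1, 1] == 1.0

    def test_identical_maps_give_identity(self):
        t0 = _map([[1, 2], [3, 6]])
        m = estimate_transition_matrix(t0, t0, 15)
        assert np.allclose(m.probs, np.eye(6))

    def test_absent_class_gets_identity_row(self):
        t0 = _map([[1, 1], [1, 1]])
        t1 = _map([[1, 1], [1, 2]])
        m = estimate_transition_matrix(t0, t1, 15)
        i_water = DEFAULT_CLASSES.index("water")
        assert m.probs[i_water, i_water] == 1.0

    def test_recovers_generating_matrix(self):
        """Estimated matrix from a 1e5-pixel Markov pair recovers the
        generator with max-abs entry error <= 0.02."""
        gen = TransitionMatrix(
            ("cropland", "grassland", "bare"),
            [[0.85, 0.1, 0.05], [0.05, 0.9, 0.05], [0.1, 0.05, 0.85]])
        t0, t1 = generate_markov_pair(gen, 100_000, seed=4)
        est = estimate_transition_matrix(t0, t1, 15,
                                         classes=("cropland", "grassland", "bare"))
        assert np.max(np.abs(est.probs - gen.probs)) <= 0.02


class TestScenarioModifiers:
    def test_ed_arithmetic_on_single_row(self):
        """(stay 0.8, ->crop 0.1, ->built 0.1) under +50% crop, +200% built
        becomes (0.55, 0.15, 0.30)."""
        m = TransitionMatrix(("bare", "cropland", "built-up"),
                             [[0.8, 0.1, 0.1], [0, 1, 0], [0, 0, 1]])
        spec = ScenarioSpec("ED", [("bare", "cropland", 0.5),
                                   ("bare", "built-up", 2.0)])
        out = apply_scenario_modifiers(m, spec)
        assert np.allclose(out.probs[0], [0.55, 0.15, 0.30])

    def test_bau_leaves_matrix_unchanged(self):
        m = TransitionMatrix(("cropland", "bare"), [[0.9, 0.1], [0.2, 0.8]])
        out = apply_scenario_modifiers(m, default_scenarios()["BAU"])
        assert np.array_equal(out.probs, m.probs)

    def test_full_suppression_renormalizes_via_diagonal(self):
        m = TransitionMatrix(("forest", "cropland"), [[0.96, 0.04], [0.0, 1.0]])
        spec = ScenarioSpec("EC", [("forest", "cropland", -1.0)])
        out = apply_scenario_modifiers(m, spec)
        assert out.probs[0, 1] == 0.0
        assert out.probs[0, 0] == 1.0
        assert np.allclose(out.probs.sum(axis=1), 1.0)

    def test_diagonal_deficit_triggers_proportional_rescale(self):
        m = TransitionMatrix(("bare", "cropland", "built-up"),
                             [[0.2, 0.4, 0.4], [0, 1, 0], [0, 0, 1]])
        spec = ScenarioSpec("ED", [("bare", "cropland", 2.0),
                                   ("bare", "built-up", 2.0)])
        out = apply_scenario_modifiers(m, spec)
        assert out.probs[0, 0] == 0.0
        assert np.allclose(out.probs.sum(axis=1), 1.0)
        # targeted entries keep their relative sizes
        assert out.probs[0, 1] == pytest.approx(out.probs[0, 2])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_stay_stochastic(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(6) * 2, size=6)
        # diagonally load so the matrix looks like a land-use matrix
        p = 0.7 * np.eye(6) + 0.3 * p
        p /= p.sum(axis=1, keepdims=True)
        m = TransitionMatrix(DEFAULT_CLASSES, p)
        for spec in default_scenarios().values():
            out = apply_scenario_modifiers(m, spec)
            assert np.allclose(out.probs.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(out.probs >= 0)


class TestStepSplit:
    def test_identity_root_is_identity(self):
        m = TransitionMatrix(("cropland", "bare"), np.eye(2))
        q = step_split_matrix(m, 4)
        assert np.allclose(q.probs, np.eye(2))

    def test_square_root_matches_eigendecomposition(self):
        """Q with Q^2 ~ P for a diagonally dominant matrix; oracle = explicit
        eigendecomposition root."""
        p = np.array([[0.9, 0.1], [0.05, 0.95]])
        m = TransitionMatrix(("cropland", "bare"), p)
        q = step_split_matrix(m, 2)
        assert np.linalg.norm(q.probs @ q.probs - p, "fro") < 1e-8
        w, v = np.linalg.eig(p)
        root = np.real(v @ np.diag(np.sqrt(w)) @ np.linalg.inv(v))
        assert np.allclose(q.probs, root, atol=1e-8)

    def test_single_step_returns_input(self):
        m = TransitionMatrix(("cropland", "bare"), [[0.9, 0.1], [0.2, 0.8]])
        q = step_split_matrix(m, 1)
        assert np.array_equal(q.probs, m.probs)

    def test_residual_reported(self):
        m = TransitionMatrix(("cropland", "bare"), [[0.9, 0.1], [0.05, 0.95]])
        q = step_split_matrix(m, 3)
        assert q.meta["split_residual"] < 1e-8


class TestProjectDemand:
    def test_identity_keeps_areas_constant(self):
        m = TransitionMatrix(("cropland", "bare"), np.eye(2))
        d = project_demand(m, {"cropland": 30.0, "bare": 70.0}, [0, 1, 2, 3])
        assert np.allclose(d.areas, [[30, 70]] * 4)

    def test_matrix_vector_arithmetic(self):
        m = TransitionMatrix(("cropland", "bare"), [[0.5, 0.5], [0.0, 1.0]])
        d = project_demand(m, np.array([100.0, 0.0]), [2015, 2020, 2025])
        assert np.allclose(d.areas[1], [50, 50])
        assert np.allclose(d.areas[2], [25, 75])

    def test_mass_conserved(self, rng):
        p = rng.dirichlet(np.ones(6), size=6)
        m = TransitionMatrix(DEFAULT_CLASSES, p)
        a0 = rng.uniform(0, 100, 6)
        d = project_demand(m, a0, list(range(10)))
        assert np.allclose(d.areas.sum(axis=1), a0.sum(), rtol=1e-6)

    def test_negative_areas_rejected(self):
        m = TransitionMatrix(("cropland", "bare"), np.eye(2))
        with pytest.raises(ValidationError):
            project_demand(m, np.array([-1.0, 2.0]), [0, 1])

    def test_ed_scenario_dominates_bau_for_targeted_classes(self):
        """Under ED modifiers, projected cropland and built-up areas at every
        horizon are >= the BAU projection from the same base matrix."""
        rng = np.random.default_rng(7)
        p = 0.8 * np.eye(6) + 0.2 * rng.dirichlet(np.ones(6), size=6)
        p /= p.sum(axis=1, keepdims=True)
        base = TransitionMatrix(DEFAULT_CLASSES, p)
        ed = apply_scenario_modifiers(base, default_scenarios()["ED"])
        a0 = np.array([100.0, 150.0, 400.0, 30.0, 20.0, 500.0])
        years = list(range(5))
        d_bau = project_demand(base, a0, years)
        d_ed = project_demand(ed, a0, years)
        i_crop = DEFAULT_CLASSES.index("cropland")
        i_built = DEFAULT_CLASSES.index("built-up")
        assert np.all(d_ed.areas[:, i_crop] >= d_bau.areas[:, i_crop] - 1e-9)
        assert np.all(d_ed.areas[:, i_built] >= d_bau.areas[:, i_built] - 1e-9)


class TestSuitability:
    def test_separable_factor_gives_perfect_auc(self):
        """A factor equal to the class id forces AUC = 1 for every class."""
        rng = np.random.default_rng(0)
        classes = rng.choice([1, 3, 6], size=(40, 40)).astype(np.uint8)
        lu = _map(classes)
        factors = np.stack([classes.astype(float),
                            rng.normal(size=(40, 40)),
                            rng.normal(size=(40, 40))])
        surf = train_suitability(factors, lu, sample_fraction=0.3, seed=0,
                                 min_class_samples=5)
        aucs = roc_auc(surf, lu)
        for cls in ("cropland", "grassland", "bare"):
            assert aucs[cls] == pytest.approx(1.0, abs=1e-6)

    def test_noise_factors_give_chance_auc(self):
        """Pure-noise factors on two balanced classes: AUC within 0.5 +/- 0.05."""
        rng = np.random.default_rng(1)
        classes = np.where(rng.random((60, 60)) < 0.5, 1, 6).astype(np.uint8)
        lu = _map(classes)
        factors = rng.normal(size=(4, 60, 60))
        surf = train_suitability(factors, lu, sample_fraction=0.2, seed=1,
                                 min_class_samples=5)
        aucs = roc_auc(surf, lu)
        assert abs(aucs["cropland"] - 0.5) <= 0.05
        assert abs(aucs["bare"] - 0.5) <= 0.05

    def test_deterministic_for_fixed_seed(self, bundle100, factors100):
        a = train_suitability(factors100, bundle100.landuse_t0, 0.05, seed=3,
                              min_class_samples=5)
        b = train_suitability(factors100, bundle100.landuse_t0, 0.05, seed=3,
                              min_class_samples=5)
        assert np.array_equal(a.probs, b.probs)

    def test_probabilities_sum_to_one(self, surface100):
        assert np.allclose(surface100.probs.sum(axis=0), 1.0, atol=1e-6)


class TestValidationStats:
    def test_one_hot_truth_gives_auc_one(self):
        lu = _map([[1, 1], [6, 6]])
        onehot = np.zeros((6, 2, 2))
        onehot[0, lu.classes == 1] = 1.0
        onehot[5, lu.classes == 6] = 1.0
        surf = SuitabilitySurface(DEFAULT_CLASSES, onehot / onehot.sum(0))
        aucs = roc_auc(surf, lu)
        assert aucs["cropland"] == 1.0 and aucs["bare"] == 1.0

    def test_anti_classifier_gives_auc_zero(self):
        lu = _map([[1, 1], [6, 6]])
        anti = np.full((6, 2, 2), 0.5)
        anti[0] = np.where(lu.classes == 1, 0.0, 1.0)
        surf = SuitabilitySurface(DEFAULT_CLASSES, anti / anti.sum(0))
        assert roc_auc(surf, lu)["cropland"] == 0.0

    def test_four_point_ranking_fixture(self):
        """AUC 0.75 on scores (.9,.8,.4,.3) labels (1,0,1,0); oracle =
        brute force over all positive-negative pairs."""
        scores = np.array([0.9, 0.8, 0.4, 0.3])
        labels = np.array([1, 0, 1, 0])
        pos, neg = scores[labels == 1], scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        oracle = wins / (len(pos) * len(neg))
        assert oracle == 0.75
        assert auc_from_scores(scores, labels) == pytest.approx(oracle)

    def test_kappa_of_map_with_itself(self):
        lu = _map([[1, 2], [3, 6]])
        assert kappa(lu, lu) == 1.0

    def test_kappa_hand_confusion_fixture(self):
        """Confusion [[40,10],[10,40]]: p_o=0.8, p_e=0.5, kappa=0.6."""
        a = np.array([1] * 50 + [6] * 50, dtype=np.uint8).reshape(10, 10)
        b = np.array([1] * 40 + [6] * 10 + [1] * 10 + [6] * 40,
                     dtype=np.uint8).reshape(10, 10)
        assert kappa(_map(a), _map(b)) == pytest.approx(0.6)

    def test_kappa_complete_disagreement(self):
        a = np.array([[1, 1], [6, 6]], dtype=np.uint8)
        b = np.array([[6, 6], [1, 1]], dtype=np.uint8)
        assert kappa(_map(a), _map(b)) == pytest.approx(-1.0)

    def test_kappa_relabel_invariance(self, rng):
        a = rng.choice([1, 3, 6], size=(20, 20)).astype(np.uint8)
        b = rng.choice([1, 3, 6], size=(20, 20)).astype(np.uint8)
        relabel = {1: 2, 3: 4, 6: 5}
        ra = np.vectorize(relabel.get)(a).astype(np.uint8)
        rb = np.vectorize(relabel.get)(b).astype(np.uint8)
        assert kappa(_map(a), _map(b)) == pytest.approx(kappa(_map(ra), _map(rb)))

    def test_constant_identical_maps_kappa_one(self):
        lu = _map(np.ones((3, 3)))
        assert kappa(lu, lu) == 1.0


class TestCAAllocate:
    def test_demand_satisfaction(self, bundle100, surface100):
        """Moving 500 pixels bare -> cropland lands every class within 0.5%
        of demand, counted directly on the output map."""
        lu = bundle100.landuse_t0
        counts = lu.class_counts()
        demand = {c: float(counts[CLASS_CODES[c]]) for c in DEFAULT_CLASSES}
        demand["cropland"] += 500
        demand["bare"] -= 500
        out, diag = ca_allocate(lu, surface100, CAParams(seed=21), demand)
        assert diag["converged"]
        final = out.class_counts()
        for c in DEFAULT_CLASSES:
            assert abs(final[CLASS_CODES[c]] - demand[c]) <= \
                max(0.005 * demand[c], 1.0)
        assert out.classes.size == lu.classes.size  # area conserved

    def test_frozen_costs_and_matching_demand_identity(self, bundle100, surface100):
        lu = bundle100.landuse_t0
        counts = lu.class_counts()
        demand = {c: float(counts[CLASS_CODES[c]]) for c in DEFAULT_CLASSES}
        params = CAParams(seed=1, conversion_cost=np.zeros((6, 6)))
        out, diag = ca_allocate(lu, surface100, params, demand)
        assert diag["converged"]
        assert np.array_equal(out.classes, lu.classes)

    def test_forbidden_transitions_never_occur(self, bundle100, surface100):
        lu = bundle100.landuse_t0
        counts = lu.class_counts()
        demand = {c: float(counts[CLASS_CODES[c]]) for c in DEFAULT_CLASSES}
        demand["cropland"] += 300
        demand["bare"] -= 300
        cost = np.ones((6, 6))
        cost[:, DEFAULT_CLASSES.index("water")] = 0.0
        out, _ = ca_allocate(lu, surface100,
                             CAParams(seed=2, conversion_cost=cost), demand)
        newly_water = ((out.classes == CLASS_CODES["water"])
                       & (lu.classes != CLASS_CODES["water"]))
        assert newly_water.sum() == 0

    def test_infeasible_demand_reports_nonconvergence(self, bundle100, surface100):
        lu = bundle100.landuse_t0
        counts = lu.class_counts()
        demand = {c: float(counts[CLASS_CODES[c]]) for c in DEFAULT_CLASSES}
        demand["water"] += 200
        demand["bare"] -= 200
        cost = np.ones((6, 6))
        cost[:, DEFAULT_CLASSES.index("water")] = 0.0  # growth is impossible
        params = CAParams(seed=3, conversion_cost=cost, max_iterations=30)
        out, diag = ca_allocate(lu, surface100, params, demand)
        assert not diag["converged"]
        assert "deviation_px" in diag
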