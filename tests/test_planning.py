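"""Threshold-dose plan evaluation, power optimization and annealing."""

import itertools

import numpy as np
import pytest

import ipdtplan as ip
from ipdtplan.mesh import Region, TetraMesh
from ipdtplan.planning import SAParams, _min_scale_for_coverage
from ipdtplan.transport import FluenceField


def toy_mesh(n_tumor=8, n_oar=4, seed=0):
    """Small disconnected-tet mesh: unit-volume cells with labels."""
    rng = np.random.default_rng(seed)
    n = n_tumor + n_oar
    nodes = []
    tets = []
    base = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 6.0]])  # volume 1
    for i in range(n):
        offset = np.array([3.0 * i, 0, 0])
        nodes.append(base + offset)
        tets.append(np.arange(4) + 4 * i)
    labels = np.array(
        [int(Region.TUMOR_CORE)] * n_tumor + [int(Region.GRAY_MATTER)] * n_oar
    )
    return TetraMesh(
        nodes=np.vstack(nodes), tetrahedra=np.array(tets), region_label=labels
    )


def fields_from(matrix):
    return [FluenceField(fluence=np.asarray(col, float), n_packets=1, seed=0) for col in np.asarray(matrix).T]


MODEL = ip.ThresholdModel({int(Region.TUMOR_CORE): 1.0, int(Region.GRAY_MATTER): 1.0})


class TestEvaluatePlan:
    def test_zero_powers_destroy_nothing(self):
        mesh = toy_mesh()
        Phi = np.ones((mesh.n_cells, 2))
        sol = ip.evaluate_plan(mesh, fields_from(Phi), [0.0, 0.0], MODEL)
        assert sol.destruction_fraction == 0.0
        assert all(v == 0.0 for v in sol.v100.values())

    def test_hand_set_fluences_match_manual_enumeration(self):
        mesh = toy_mesh(n_tumor=6, n_oar=4)
        phi = np.array([2.0, 1.5, 1.0, 0.6, 0.4, 0.2, 1.2, 0.9, 0.5, 0.1])
        sol = ip.evaluate_plan(mesh, fields_from(phi[:, None]), [1.0], MODEL)
        destroyed_tumor = (phi[:6] >= 1.0).sum()
        assert sol.destruction_fraction == pytest.approx(destroyed_tumor / 6.0)
        assert sol.v100[int(Region.GRAY_MATTER)] == pytest.approx(
            (phi[6:] >= 1.0).sum() / 1000.0
        )

    def test_multiplier_scales_dose(self):
        mesh = toy_mesh(n_tumor=4, n_oar=0)
        phi = np.array([0.6, 0.6, 0.6, 0.6])
        from ipdtplan.meshmodels import PSField

        field = PSField(
            multiplier=np.array([2.0, 2.0, 0.5, 0.5]), mean_ps=1.0, scenario=0
        )
        sol = ip.evaluate_plan(mesh, fields_from(phi[:, None]), [1.0], MODEL, field)
        assert sol.destruction_fraction == pytest.approx(0.5)

    def test_raising_power_never_reduces_destruction(self):
        mesh = toy_mesh()
        rng = np.random.default_rng(3)
        Phi = rng.uniform(0, 1, (mesh.n_cells, 2))
        f = fields_from(Phi)
        prev = 0.0
        for p in (0.5, 1.0, 2.0, 4.0):
            sol = ip.evaluate_plan(mesh, f, [p, 1.0], MODEL)
            assert sol.destruction_fraction >= prev
            prev = sol.destruction_fraction

    def test_missing_threshold_raises(self):
        mesh = toy_mesh()
        bad = ip.ThresholdModel({int(Region.TUMOR_CORE): 1.0})
        with pytest.raises(ValueError, match="missing death threshold"):
            ip.evaluate_plan(mesh, fields_from(np.ones((mesh.n_cells, 1))), [1.0], bad)


class TestOptimizePower:
    def test_single_source_equals_bisection_oracle(self):
        mesh = toy_mesh(n_tumor=50, n_oar=10, seed=1)
        rng = np.random.default_rng(5)
        phi = rng.uniform(0.1, 2.0, mesh.n_cells)
        f = fields_from(phi[:, None])
        p = ip.optimize_power(mesh, f, MODEL, target=0.98)

        # independent oracle: 1-D bisection on power
        def frac(power):
            return ip.evaluate_plan(mesh, f, [power], MODEL).destruction_fraction

        lo, hi = 0.0, 1.0
        while frac(hi) < 0.98:
            hi *= 2
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if frac(mid) >= 0.98:
                hi = mid
            else:
                lo = mid
        assert p[0] == pytest.approx(hi, rel=1e-6)

    def test_achieved_fraction_pinned_to_target(self):
        for seed in range(5):
            mesh = toy_mesh(n_tumor=100, n_oar=20, seed=seed)
            rng = np.random.default_rng(seed)
            Phi = rng.uniform(0.05, 2.0, (mesh.n_cells, 2))
            f = fields_from(Phi)
            p = ip.optimize_power(mesh, f, MODEL, target=0.98, seed=seed)
            sol = ip.evaluate_plan(mesh, f, p, MODEL)
            assert 0.98 <= sol.destruction_fraction <= 0.98 + 1.0 / 100 + 1e-9

    def test_symmetric_two_source_geometry_splits_power_equally(self):
        mesh = toy_mesh(n_tumor=40, n_oar=20, seed=2)
        rng = np.random.default_rng(2)
        # mirror-symmetric unit fields: source B sees the tumor and OAR
        # cell lists reversed relative to source A
        tumor_a = rng.uniform(0.1, 1.0, 40)
        oar_a = rng.uniform(0.05, 0.4, 20)
        phi_a = np.concatenate([tumor_a, oar_a])
        phi_b = np.concatenate([tumor_a[::-1], oar_a[::-1]])
        f = fields_from(np.column_stack([phi_a, phi_b]))
        p = ip.optimize_power(mesh, f, MODEL, target=0.98, seed=0)
        assert p[0] == pytest.approx(p[1], rel=0.02)

    def test_beats_brute_force_grid_on_toy_mesh(self):
        mesh = toy_mesh(n_tumor=60, n_oar=40, seed=7)
        rng = np.random.default_rng(7)
        Phi = rng.uniform(0.02, 1.5, (mesh.n_cells, 2))
        f = fields_from(Phi)
        p = ip.optimize_power(mesh, f, MODEL, target=0.98, seed=0)
        sol = ip.evaluate_plan(mesh, f, p, MODEL)
        assert sol.destruction_fraction >= 0.98

        # 50x50 grid oracle over powers meeting the coverage constraint
        pmax = 3.0 * p.sum()
        best = np.inf
        for p1, p2 in itertools.product(np.linspace(0, pmax, 50), repeat=2):
            s = ip.evaluate_plan(mesh, f, [p1, p2], MODEL)
            if s.destruction_fraction >= 0.98:
                best = min(best, s.objective)
        assert sol.objective <= best + 1e-9

    def test_infeasible_target_reports_max_achievable(self):
        mesh = toy_mesh(n_tumor=10, n_oar=0)
        phi = np.zeros(mesh.n_cells)
        phi[:5] = 1.0  # half the tumor can never be covered
        with pytest.raises(ValueError, match="infeasible"):
            ip.optimize_power(mesh, fields_from(phi[:, None]), MODEL, target=0.98)

    def test_min_scale_quantile_matches_definition(self):
        rng = np.random.default_rng(11)
        dose = rng.uniform(0.1, 2.0, 200)
        vols = rng.uniform(0.5, 1.5, 200)
        thresholds = np.ones(200)
        sel = np.ones(200, dtype=bool)
        s = _min_scale_for_coverage(dose, sel, thresholds, vols, 0.98)
        covered = vols[(s * dose) >= thresholds - 1e-12].sum() / vols.sum()
        assert covered >= 0.98
        covered_less = vols[(0.999 * s * dose) >= thresholds].sum() / vols.sum()
        assert covered_less < 0.98


class TestAnnealing:
    @staticmethod
    def analytic_plan_env(seed=0):
        """Two-lobe tumor with analytic exponential fluence (no MC)."""
        mesh, union = ip.make_tumor_geometry(
            n_spheres=2, radius_range=(5.0, 5.0), preset="low", seed=4, margin=2.0
        )
        model = ip.ThresholdModel(
            {
                int(Region.TUMOR_CORE): 1.0,
                int(Region.TUMOR_RIM): 1.0,
                int(Region.WHITE_MATTER): 1.0,
            }
        )
        cents = mesh.centroids()
        optics = ip.TissueOptics(0.05, 2.0, 0.8, 1.4)

        def fluence_fn(source, n_packets):
            mids = np.linspace(0, 1, 5)[:, None] * (source.p1 - source.p0)[None, :] + source.p0
            d = np.linalg.norm(cents[:, None, :] - mids[None, :, :], axis=2).min(axis=1)
            d = np.maximum(d, 0.3)
            return FluenceField(
                fluence=ip.diffusion_oracle(d, optics), n_packets=n_packets, seed=0
            )

        return mesh, union, model, fluence_fn

    def test_zero_iterations_returns_initial_plan(self):
        mesh, union, model, fluence_fn = self.analytic_plan_env()
        init = ip.place_sources(mesh, 1, surface=union, length_mm=4.0)
        sol = ip.anneal_positions(
            mesh, init, model, None, sa_params=SAParams(n_iter=0), seed=1,
            fluence_fn=fluence_fn,
        )
        np.testing.assert_allclose(sol.sources[0].center, init[0].center)

    def test_best_seen_objective_never_worse_than_initial(self):
        mesh, union, model, fluence_fn = self.analytic_plan_env()
        init = ip.place_sources(mesh, 2, surface=union, length_mm=4.0, spacing_mm=4.0)
        base_fields = [fluence_fn(s, 0) for s in init]
        p0 = ip.optimize_power(mesh, base_fields, model, seed=1)
        initial_obj = ip.evaluate_plan(mesh, base_fields, p0, model).objective
        sol = ip.anneal_positions(
            mesh, init, model, None, sa_params=SAParams(n_iter=15), seed=1,
            fluence_fn=fluence_fn,
        )
        assert sol.objective <= initial_obj + 1e-9

    def test_deterministic_under_seed(self):
        mesh, union, model, fluence_fn = self.analytic_plan_env()
        init = ip.place_sources(mesh, 1, surface=union, length_mm=4.0)
        sols = [
            ip.anneal_positions(
                mesh, init, model, None, sa_params=SAParams(n_iter=10), seed=7,
                fluence_fn=fluence_fn,
            )
            for _ in range(2)
        ]
        np.testing.assert_array_equal(
            sols[0].sources[0].center, sols[1].sources[0].center
        )
        np.testing.assert_array_equal(sols[0].powers, sols[1].powers)


class TestComparePlans:
    @staticmethod
    def plan_with(centers, v100=None):
        sources = [
            ip.Source(p0=np.asarray(c, float) - [0, 0, 1], p1=np.asarray(c, float) + [0, 0, 1])
            for c in centers
        ]
        return ip.PlanSolution(
            sources=sources,
            powers=np.ones(len(sources)),
            destruction_fraction=0.98,
            v100=v100 or {3: 1.0},
            dvh={},
        )

    def test_identical_plans_compare_to_zero(self):
        a = self.plan_with([[0, 0, 0], [5, 0, 0]])
        delta, disp = ip.compare_plans(a, a)
        assert all(v == 0 for v in delta.delta.values())
        np.testing.assert_allclose(disp.distances, 0)

    def test_translation_gives_three_four_five(self):
        a = self.plan_with([[0, 0, 0], [10, 0, 0]])
        b = self.plan_with([[3, 4, 0], [13, 4, 0]])
        _, disp = ip.compare_plans(a, b)
        np.testing.assert_allclose(disp.distances, 5.0)

    def test_matching_equals_brute_force_permutation(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(2, 5))
            ca = rng.uniform(-10, 10, (n, 3))
            cb = rng.uniform(-10, 10, (n, 3))
            a, b = self.plan_with(ca), self.plan_with(cb)
            _, disp = ip.compare_plans(a, b)
            best = min(
                sum(np.linalg.norm(ca[i] - cb[perm[i]]) for i in range(n))
                for perm in itertools.permutations(range(n))
            )
            assert disp.distances.sum() == pytest.approx(best)

    def test_v100_delta_signed(self):
        a = self.plan_with([[0, 0, 0]], v100={3: 2.0})
        b = self.plan_with([[0, 0, 0]], v100={3: 1.2})
        delta, _ = ip.compare_plans(a, b)
        assert delta.delta[3] == pytest.approx(-0.8)
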