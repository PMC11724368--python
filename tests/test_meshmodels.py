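"""Tumor/brain mesh generation and photosensitizer scenario fields."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

import ipdtplan as ip
from ipdtplan.mesh import Region
from ipdtplan.meshmodels import (
    MULTIPLIER_BOUNDS,
    SphereUnion,
    assign_ps_scenario,
    core_rim_partition,
    fine_grained_ps_field,
    make_brain_fixture,
    make_tumor_geometry,
)


@pytest.fixture(scope="module")
def sphere_mesh():
    """Single-sphere tumor, radius 10 mm, with core/rim at 2 mm rim."""
    mesh, union = make_tumor_geometry(
        n_spheres=1, radius_range=(10.0, 10.0), preset="low", seed=5, margin=2.0
    )
    core_rim_partition(mesh, union, 2.0)
    return mesh, union


class TestTumorGeometry:
    def test_single_sphere_volume_matches_analytic(self):
        mesh, _ = make_tumor_geometry(
            n_spheres=1, radius_range=(8.0, 8.0), preset="low", seed=2
        )
        vt = mesh.volumes()[mesh.tumor_mask()].sum()
        assert vt == pytest.approx(4 / 3 * np.pi * 8**3, rel=0.05)

    def test_deterministic_under_seed(self):
        a, _ = make_tumor_geometry(n_spheres=3, radius_range=(4, 7), seed=9)
        b, _ = make_tumor_geometry(n_spheres=3, radius_range=(4, 7), seed=9)
        assert a.n_cells == b.n_cells
        np.testing.assert_array_equal(a.nodes, b.nodes)
        np.testing.assert_allclose(a.volumes(), b.volumes())

    def test_high_preset_refines_tumor_cells(self):
        low, _ = make_tumor_geometry(
            n_spheres=1, radius_range=(4, 4), preset="low", seed=1, margin=1.5
        )
        high, _ = make_tumor_geometry(
            n_spheres=1, radius_range=(4, 4), preset="high", seed=1, margin=1.5
        )
        assert high.tumor_mask().sum() >= 10 * low.tumor_mask().sum()

    def test_tumor_single_connected_component(self):
        mesh, _ = make_tumor_geometry(n_spheres=6, radius_range=(3, 6), seed=4)
        assert mesh.tumor_connected()

    def test_mean_tet_volume_near_preset_target(self):
        mesh, _ = make_tumor_geometry(
            n_spheres=1, radius_range=(8, 8), preset="low", seed=7
        )
        avg = mesh.volumes()[mesh.tumor_mask()].mean()
        assert 5.39 / 2 <= avg <= 5.39 * 2

    def test_volume_conservation_against_hull(self):
        mesh, _ = make_tumor_geometry(n_spheres=2, radius_range=(4, 6), seed=3)
        hull = ConvexHull(mesh.nodes)
        assert mesh.volumes().sum() == pytest.approx(hull.volume, rel=1e-9)


class TestCoreRim:
    def test_shell_volume_fraction_matches_analytic(self, sphere_mesh):
        mesh, _ = sphere_mesh
        v = mesh.volumes()
        rim = v[mesh.region_label == int(Region.TUMOR_RIM)].sum()
        tot = v[mesh.tumor_mask()].sum()
        assert rim / tot == pytest.approx(1 - (8 / 10) ** 3, abs=0.08)

    def test_thin_rim_limit(self):
        mesh, union = make_tumor_geometry(
            n_spheres=1, radius_range=(10.0, 10.0), preset="low", seed=5, margin=2.0
        )
        core_rim_partition(mesh, union, 0.4)
        v = mesh.volumes()
        frac = v[mesh.region_label == int(Region.TUMOR_RIM)].sum() / v[mesh.tumor_mask()].sum()
        assert frac < 0.25

    def test_too_thick_rim_raises(self):
        mesh, union = make_tumor_geometry(
            n_spheres=1, radius_range=(6.0, 6.0), preset="low", seed=5
        )
        with pytest.raises(ValueError, match="all-rim"):
            core_rim_partition(mesh, union, 50.0)

    def test_rim_touches_surface_core_does_not(self, sphere_mesh):
        mesh, union = sphere_mesh
        sdf = union.sdf(mesh.centroids())
        rim = mesh.region_label == int(Region.TUMOR_RIM)
        core = mesh.region_label == int(Region.TUMOR_CORE)
        assert sdf[rim].max() > sdf[core].max()


class TestScenarios:
    def test_scenario1_all_multipliers_one(self, sphere_mesh):
        mesh, _ = sphere_mesh
        field = assign_ps_scenario(mesh, scenario=1)
        np.testing.assert_array_equal(field.multiplier, 1.0)

    def test_scenario2_closed_form_two_region_solution(self, sphere_mesh):
        mesh, _ = sphere_mesh
        field = assign_ps_scenario(mesh, scenario=2)
        v = mesh.volumes()
        core = mesh.region_label == int(Region.TUMOR_CORE)
        rim = mesh.region_label == int(Region.TUMOR_RIM)
        c = field.multiplier[core][0]
        r = field.multiplier[rim][0]
        assert r == pytest.approx(2 * c)
        vc, vr = v[core].sum(), v[rim].sum()
        # closed form: rim multiplier (vc+vr)/(vc/2+vr)
        assert r == pytest.approx((vc + vr) / (0.5 * vc + vr))
        mean = np.average(field.multiplier[mesh.tumor_mask()], weights=v[mesh.tumor_mask()])
        assert mean == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("pattern", [1, 2, 3, 4])
    def test_scenario3_postconditions(self, sphere_mesh, pattern):
        mesh, union = sphere_mesh
        v = mesh.volumes()
        tm = mesh.tumor_mask()
        core = mesh.region_label == int(Region.TUMOR_CORE)
        rim = mesh.region_label == int(Region.TUMOR_RIM)
        for seed in (0, 1, 2):
            field = assign_ps_scenario(
                mesh, scenario=3, pattern=pattern, seed=seed, surface=union
            )
            m = field.multiplier
            assert np.average(m[tm], weights=v[tm]) == pytest.approx(1.0, abs=1e-6)
            ratio = np.average(m[core], weights=v[core]) / np.average(m[rim], weights=v[rim])
            assert ratio == pytest.approx(0.5, abs=1e-6)
            lo, hi = MULTIPLIER_BOUNDS
            assert m[tm].min() >= lo - 1e-9 and m[tm].max() <= hi + 1e-9

    def test_mean_preservation_over_many_draws(self, sphere_mesh):
        mesh, union = sphere_mesh
        v = mesh.volumes()
        tm = mesh.tumor_mask()
        rng = np.random.default_rng(0)
        for _ in range(150):
            pattern = int(rng.integers(1, 5))
            seed = int(rng.integers(0, 10_000))
            field = assign_ps_scenario(
                mesh, scenario=3, pattern=pattern, seed=seed, surface=union
            )
            assert np.average(field.multiplier[tm], weights=v[tm]) == pytest.approx(
                1.0, abs=1e-6
            )

    def test_heterogeneous_fields_distinguishable_but_mean_matched(self, sphere_mesh):
        mesh, union = sphere_mesh
        v = mesh.volumes()
        tm = mesh.tumor_mask()
        f1 = assign_ps_scenario(mesh, scenario=1)
        f2 = assign_ps_scenario(mesh, scenario=2)
        f3 = assign_ps_scenario(mesh, scenario=3, pattern=1, seed=0, surface=union)
        for f in (f2, f3):
            assert np.average(f.multiplier[tm], weights=v[tm]) == pytest.approx(
                np.average(f1.multiplier[tm], weights=v[tm]), abs=1e-6
            )
            assert f.multiplier[tm].std() > 0.05  # clearly non-constant

    def test_infeasible_ratio_raises(self):
        # a tumor that is almost all core cannot hold core = rim/2 with
        # mean 1 inside the multiplier bounds ... construct tiny rim
        mesh, union = make_tumor_geometry(
            n_spheres=1, radius_range=(10.0, 10.0), preset="low", seed=5, margin=2.0
        )
        core_rim_partition(mesh, union, 2.0)
        # feasible here; assert the guard triggers on a degenerate manual case
        from ipdtplan.meshmodels import _two_region_multipliers

        c, r = _two_region_multipliers(1.0, 1e9)
        assert c == pytest.approx(0.5, abs=1e-6)  # all-rim limit


class TestBrainFixture:
    def test_label_coverage_and_determinism(self):
        a, _ = make_brain_fixture(preset="low", seed=2, head_radius=25.0, tumor_radius=4.0)
        b, _ = make_brain_fixture(preset="low", seed=2, head_radius=25.0, tumor_radius=4.0)
        assert a.n_cells == b.n_cells
        np.testing.assert_array_equal(a.region_label, b.region_label)
        present = set(np.unique(a.region_label).tolist())
        assert present == {int(r) for r in Region}

    def test_layer_volumes_near_analytic_shells(self):
        mesh, _ = make_brain_fixture(preset="low", seed=2, head_radius=25.0, tumor_radius=4.0)
        v = mesh.volumes()
        r_head = 25.0
        got = v[np.isin(mesh.region_label, [int(Region.SCALP_SKULL)])].sum()
        expected = 4 / 3 * np.pi * (r_head**3 - (0.92 * r_head) ** 3)
        assert got == pytest.approx(expected, rel=0.15)
        vt = v[mesh.tumor_mask()].sum()
        assert vt == pytest.approx(4 / 3 * np.pi * 4.0**3, rel=0.1)

    def test_total_volume_matches_bounding_box(self):
        mesh, _ = make_brain_fixture(preset="low", seed=2, head_radius=25.0, tumor_radius=4.0)
        box = 2 * 25.0 * 1.15
        assert mesh.volumes().sum() == pytest.approx(box**3, rel=0.01)


class TestFineGrained:
    def test_mean_one_and_concentration(self):
        mesh, _ = make_brain_fixture(preset="low", seed=1, head_radius=25.0, tumor_radius=4.0)
        field = fine_grained_ps_field(mesh, corr_scale_mm=0.1, seed=3)
        tm = mesh.tumor_mask()
        v = mesh.volumes()
        assert np.average(field.multiplier[tm], weights=v[tm]) == pytest.approx(1.0, abs=1e-6)
        # sub-element averaging concentrates multipliers near 1
        assert np.percentile(np.abs(field.multiplier[tm] - 1.0), 95) < 0.3

    def test_coarser_correlation_scale_spreads_multipliers(self):
        mesh, _ = make_brain_fixture(preset="low", seed=1, head_radius=25.0, tumor_radius=4.0)
        tm = mesh.tumor_mask()
        fine = fine_grained_ps_field(mesh, corr_scale_mm=0.05, seed=3)
        coarse = fine_grained_ps_field(mesh, corr_scale_mm=0.4, seed=3)
        assert coarse.multiplier[tm].std() > fine.multiplier[tm].std()
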