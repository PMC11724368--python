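"""Shared fixtures: synthetic maps, small meshes, and the (expensive)
Monte Carlo fields reused across planning and transport tests."""

from __future__ import annotations

import numpy as np
import pytest

import ipdtplan as ip
from ipdtplan.mesh import Region
from ipdtplan.meshmodels import _delaunay_mesh, _lattice_points, make_brain_fixture


@pytest.fixture(scope="session")
def refs():
    return ip.ReferenceSet(mac_ref=500.0, rx_ref=0.6, rm_ref=0.5)


@pytest.fixture(scope="session")
def cal():
    return ip.Calibration(k_ps=50.0, mu_a_x=0.02)


@pytest.fixture(scope="session")
def bimodal_map():
    ps_map, truth = ip.gen_bimodal_tumor_map(
        shape=(96, 96), tumor_radius_px=36, seed=11
    )
    return ps_map, truth


def homogeneous_ball(radius=9.0, cell_volume=1.2, label=Region.TUMOR_CORE, seed=1):
    """Homogeneous ball mesh with an absorbing far boundary."""
    rng = np.random.default_rng(seed)
    pts = _lattice_points(np.array([-radius] * 3), np.array([radius] * 3), cell_volume, rng)
    mesh, _ = _delaunay_mesh(pts)
    mesh.region_label[:] = int(label)
    r = np.linalg.norm(mesh.centroids(), axis=1)
    mesh.region_label[r > radius - 1.0] = int(Region.BOUNDING)
    return mesh, r


@pytest.fixture(scope="session")
def oracle_ball():
    """Ball mesh + MC field for the diffusion closed-form comparison.

    Generic soft-tissue optics keep the walk length desk-friendly while
    still spanning several attenuation lengths over the test radii.
    """
    mesh, r = homogeneous_ball(radius=9.0, cell_volume=1.2)
    props = {int(Region.TUMOR_CORE): ip.TissueOptics(0.05, 5.0, 0.8, 1.4)}
    src = ip.Source(p0=np.zeros(3), p1=np.zeros(3), kind="point")
    field = ip.mc_fluence(mesh, props, src, n_packets=300_000, seed=3)
    return mesh, r, props[int(Region.TUMOR_CORE)], field


@pytest.fixture(scope="session")
def brain_plan():
    """Desk-scale layered-head fixture with one diffuser and its unit
    Monte Carlo fluence field (shared by the planning-contract and
    scenario-sensitivity tests)."""
    mesh, surface = make_brain_fixture(preset="low", seed=1)
    sources = ip.place_sources(mesh, 1, surface=surface, length_mm=4.0, seed=1)
    field = ip.mc_fluence(
        mesh, ip.TABLE_OPTICS_635NM, sources[0], n_packets=300_000, seed=1
    )
    model = ip.ThresholdModel(ip.DEFAULT_THRESHOLDS)
    return mesh, surface, sources, field, model
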