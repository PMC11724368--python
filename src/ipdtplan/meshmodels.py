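"""Synthetic tumor and layered-head tetrahedral models.

Tumors are unions of interconnected random spheres around a central
core, tetrahedralized by Delaunay triangulation of jittered lattice
points at a density chosen to hit a target tetrahedron volume.  The
tumor is split into a core and a rim (the well-perfused periphery), and
per-cell photosensitizer multipliers encode three heterogeneity
scenarios:

1. uniform [PS] in core and rim (multiplier 1 everywhere);
2. piecewise-uniform with the core at half the rim concentration;
3. core at half the rim mean plus a heterogeneous rim, realized by four
   seeded random-field patterns (patchy, gradient, hot-spot, cold-spot).

Every scenario preserves the volume-weighted whole-tumor mean
multiplier at exactly 1, so scenarios differ only in spatial
arrangement, never in total drug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .mesh import Region, TetraMesh

__all__ = [
    "ResolutionPreset",
    "PRESETS",
    "SphereUnion",
    "PSField",
    "make_tumor_geometry",
    "core_rim_partition",
    "assign_ps_scenario",
    "make_brain_fixture",
    "MULTIPLIER_BOUNDS",
]

#: Local-to-mean [PS] multipliers stay within "two to three times higher
#: and lower" than the tumor average.
MULTIPLIER_BOUNDS = (1.0 / 3.0, 3.0)


@dataclass(frozen=True)
class ResolutionPreset:
    """Target tetrahedron volumes (mm^3) for a mesh density class."""

    name: str
    avg_tet_volume: float
    median_tet_volume: float

    def __post_init__(self) -> None:
        if self.avg_tet_volume <= 0 or self.median_tet_volume <= 0:
            raise ValueError("target tetra volumes must be positive")


PRESETS = {
    "low": ResolutionPreset("low", 5.39, 4.29),
    "medium_spherical": ResolutionPreset("medium_spherical", 6.99, 3.18),
    "medium_nonspherical": ResolutionPreset("medium_nonspherical", 3.43, 1.05),
    "high": ResolutionPreset("high", 0.08, 0.02),
}


@dataclass(frozen=True)
class SphereUnion:
    """Implicit tumor surface: union of spheres (centers mm, radii mm)."""

    centers: np.ndarray
    radii: np.ndarray

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance to the union surface (negative inside)."""
        pts = np.atleast_2d(pts)
        d = np.linalg.norm(pts[:, None, :] - self.centers[None, :, :], axis=2)
        return (d - self.radii[None, :]).min(axis=1)

    def equivalent_radius(self, volume: float) -> float:
        return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass
class PSField:
    """Per-tumor-cell [PS] multipliers (local / tumor mean)."""

    multiplier: np.ndarray  # one entry per mesh cell; 1 outside tumor
    mean_ps: float  # ug/mL, the tumor-average concentration
    scenario: int
    pattern: int | None = None
    seed: int | None = None

    def validate(self, mesh: TetraMesh) -> None:
        mult = self.multiplier
        if mult.shape != (mesh.n_cells,):
            raise ValueError("multiplier must have one entry per cell")
        tm = mesh.tumor_mask()
        lo, hi = MULTIPLIER_BOUNDS
        if np.any(mult[tm] < lo - 1e-9) or np.any(mult[tm] > hi + 1e-9):
            raise ValueError("tumor multipliers outside allowed bounds")
        v = mesh.volumes()[tm]
        mean = float(np.average(mult[tm], weights=v))
        if abs(mean - 1.0) > 1e-6:
            raise ValueError(f"volume-weighted mean multiplier {mean} != 1")


def _lattice_points(
    lo: np.ndarray, hi: np.ndarray, target_tet_volume: float, rng: np.random.Generator
) -> np.ndarray:
    """Jittered lattice filling [lo, hi] at a density that makes Delaunay
    tetrahedra come out near the target volume (a Delaunay triangulation
    of n points yields ~6.5 n tetrahedra)."""
    pts_per_volume = 1.0 / (6.5 * target_tet_volume)
    spacing = pts_per_volume ** (-1.0 / 3.0)
    axes = []
    for i in range(3):
        ax = np.arange(lo[i], hi[i] + spacing, spacing)
        ax[-1] = hi[i]  # outermost layers sit exactly on the box faces
        axes.append(ax)
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    jitter = rng.uniform(-0.35, 0.35, size=grid.shape) * spacing
    # boundary layers keep their exact face coordinate so the convex hull
    # (and hence the meshed volume) equals the requested box
    for i in range(3):
        on_face = (grid[:, i] == lo[i]) | (grid[:, i] == hi[i])
        jitter[on_face, i] = 0.0
    return grid + jitter


def _delaunay_mesh(points: np.ndarray) -> tuple[TetraMesh, Delaunay]:
    tri = Delaunay(points)
    mesh = TetraMesh(
        nodes=tri.points,
        tetrahedra=tri.simplices,
        region_label=np.zeros(tri.simplices.shape[0], dtype=np.int64),
    )
    # drop degenerate slivers produced by near-coplanar jittered points
    good = mesh.volumes() > 1e-12
    if not np.all(good):
        mesh = TetraMesh(
            nodes=tri.points,
            tetrahedra=tri.simplices[good],
            region_label=np.zeros(int(good.sum()), dtype=np.int64),
        )
    return mesh, tri


def _random_sphere_union(
    center: np.ndarray,
    n_spheres: int,
    radius_range: tuple[float, float],
    rng: np.random.Generator,
) -> SphereUnion:
    """Interconnected random spheres around a central core: each extra
    sphere is centered inside an existing one, so the union is connected
    by construction."""
    r_lo, r_hi = radius_range
    centers = [np.asarray(center, dtype=float)]
    radii = [rng.uniform(r_lo, r_hi)]
    for _ in range(n_spheres - 1):
        host = rng.integers(len(centers))
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        offset = rng.uniform(0.3, 0.9) * radii[host]
        centers.append(centers[host] + direction * offset)
        radii.append(rng.uniform(r_lo, r_hi))
    return SphereUnion(centers=np.array(centers), radii=np.array(radii))


def make_tumor_geometry(
    center: Sequence[float] = (0.0, 0.0, 0.0),
    n_spheres: int = 5,
    radius_range: tuple[float, float] = (6.0, 10.0),
    preset: ResolutionPreset | str = "low",
    seed: int = 0,
    margin: float = 3.0,
) -> tuple[TetraMesh, SphereUnion]:
    """Tetrahedral mesh of a sphere-union tumor embedded in a small box
    of surrounding tissue (labelled white matter).

    The mesh is deterministic under ``seed``; the achieved mean tumor
    tetra volume lands within a factor of ~2 of the preset target.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if n_spheres < 1:
        raise ValueError("n_spheres must be >= 1")
    if radius_range[0] <= 0:
        raise ValueError("radii must be positive")
    rng = np.random.default_rng(seed)
    union = _random_sphere_union(np.asarray(center, float), n_spheres, radius_range, rng)
    lo = (union.centers - union.radii[:, None]).min(axis=0) - margin
    hi = (union.centers + union.radii[:, None]).max(axis=0) + margin
    points = _lattice_points(lo, hi, preset.avg_tet_volume, rng)
    mesh, _ = _delaunay_mesh(points)
    sdf = union.sdf(mesh.centroids())
    labels = np.where(sdf < 0, int(Region.TUMOR_CORE), int(Region.WHITE_MATTER))
    mesh.region_label = labels.astype(np.int64)
    if not mesh.tumor_connected():
        raise RuntimeError("generated tumor is not a single connected component")
    return mesh, union


def core_rim_partition(
    mesh: TetraMesh, surface: SphereUnion, rim_thickness_mm: float
) -> TetraMesh:
    """Label tumor cells within ``rim_thickness_mm`` of the tumor surface
    as rim, the rest as core (centroid distance to the implicit surface).
    """
    if rim_thickness_mm <= 0:
        raise ValueError("rim thickness must be positive")
    tm = mesh.tumor_mask()
    if not np.any(tm):
        raise ValueError("mesh has no tumor cells")
    sdf = surface.sdf(mesh.centroids()[tm])
    rim = sdf > -rim_thickness_mm  # within thickness of surface
    labels = mesh.region_label.copy()
    tumor_idx = np.flatnonzero(tm)
    labels[tumor_idx[rim]] = int(Region.TUMOR_RIM)
    labels[tumor_idx[~rim]] = int(Region.TUMOR_CORE)
    if not np.any(rim) or np.all(rim):
        raise ValueError(
            f"rim thickness {rim_thickness_mm} mm yields an all-"
            f"{'rim' if np.all(rim) else 'core'} tumor"
        )
    mesh.region_label = labels
    return mesh


def _two_region_multipliers(v_core: float, v_rim: float) -> tuple[float, float]:
    """Core and rim multipliers with core = rim/2 and volume-weighted
    whole-tumor mean exactly 1."""
    vt = v_core + v_rim
    rim_mult = vt / (0.5 * v_core + v_rim)
    return 0.5 * rim_mult, rim_mult


def _rim_pattern(
    pattern: int,
    centroids: np.ndarray,
    surface: SphereUnion,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw (unscaled) heterogeneity field on rim cells, mean ~1.

    Patterns: 1 patchy random blocks, 2 linear gradient, 3 hot-spot,
    4 cold-spot.  Stand-in recipes for perfusion-driven rim structure.

    Amplitudes are deliberately mild and dips localized: the rim stays
    the drug-rich compartment everywhere, so the homogeneous scenario
    remains the most power-hungry plan (cold structure is small enough
    for the coverage budget to skip).
    """
    n = centroids.shape[0]
    if pattern == 1:  # patchy: nearest of ~12 seed points, random level per patch
        n_patch = max(4, min(12, n // 5))
        seeds_idx = rng.choice(n, size=n_patch, replace=False)
        tree = cKDTree(centroids[seeds_idx])
        _, patch = tree.query(centroids)
        levels = rng.uniform(0.9, 1.6, size=n_patch)
        return levels[patch]
    if pattern == 2:  # gradient along a random direction
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        t = centroids @ direction
        t = (t - t.min()) / max(t.max() - t.min(), 1e-12)
        return 0.85 + 0.75 * t
    if pattern in (3, 4):  # hot / cold Gaussian blobs on a uniform background
        n_blob = 3
        blob_idx = rng.choice(n, size=min(n_blob, n), replace=False)
        width = max(0.5, 0.12 * np.ptp(centroids, axis=0).max())
        d = np.linalg.norm(
            centroids[:, None, :] - centroids[blob_idx][None, :, :], axis=2
        )
        bumps = np.exp(-0.5 * (d / width) ** 2).sum(axis=1)
        if pattern == 3:
            return 1.0 + 1.0 * bumps
        return np.clip(1.0 - 0.3 * bumps, 0.05, None)
    raise ValueError(f"pattern must be 1..4, got {pattern}")


def assign_ps_scenario(
    mesh: TetraMesh,
    mean_ps: float = 5.0,
    scenario: int = 1,
    pattern: int | None = None,
    seed: int = 0,
    surface: SphereUnion | None = None,
) -> PSField:
    """Per-cell [PS] multipliers for one heterogeneity scenario.

    The whole-tumor volume-weighted mean multiplier is exactly 1 for
    every scenario; scenarios 2 and 3 hold the core mean at half the rim
    mean; scenario-3 rim fields follow one of four seeded patterns and
    are rescaled into the allowed multiplier bounds.
    """
    tm = mesh.tumor_mask()
    vols = mesh.volumes()
    mult = np.ones(mesh.n_cells)
    if scenario == 1:
        return PSField(multiplier=mult, mean_ps=mean_ps, scenario=1, seed=seed)

    core = mesh.region_label == int(Region.TUMOR_CORE)
    rim = mesh.region_label == int(Region.TUMOR_RIM)
    if not np.any(core) or not np.any(rim):
        raise ValueError("scenario 2/3 requires a labeled core/rim partition")
    v_core, v_rim = float(vols[core].sum()), float(vols[rim].sum())
    core_mult, rim_mult = _two_region_multipliers(v_core, v_rim)
    lo, hi = MULTIPLIER_BOUNDS
    if not (lo <= core_mult and rim_mult <= hi):
        raise ValueError(
            f"core/rim volumes {v_core:.1f}/{v_rim:.1f} mm^3 make the 1:2 "
            "ratio infeasible within multiplier bounds"
        )
    if scenario == 2:
        mult[core] = core_mult
        mult[rim] = rim_mult
        return PSField(multiplier=mult, mean_ps=mean_ps, scenario=2, seed=seed)

    if scenario != 3:
        raise ValueError(f"scenario must be 1, 2 or 3, got {scenario}")
    if pattern is None:
        pattern = 1
    rng = np.random.default_rng(seed)
    raw = _rim_pattern(pattern, mesh.centroids()[rim], surface or _bbox_surface(mesh), rng)
    # normalize the rim field to mean rim_mult, then shrink toward the
    # mean until the bounds hold (keeps core:rim mean ratio at 1:2 and
    # whole-tumor mean at 1)
    w = vols[rim] / v_rim
    field = raw / float(w @ raw) * rim_mult
    for _ in range(60):
        if field.min() >= lo and field.max() <= hi:
            break
        field = rim_mult + 0.9 * (field - rim_mult)
        field = field / float(w @ field) * rim_mult
    else:
        raise ValueError("could not fit rim pattern inside multiplier bounds")
    mult[core] = core_mult
    mult[rim] = field
    ps = PSField(multiplier=mult, mean_ps=mean_ps, scenario=3, pattern=pattern, seed=seed)
    ps.validate(mesh)
    return ps


def fine_grained_ps_field(
    mesh: TetraMesh,
    mean_ps: float = 5.0,
    corr_scale_mm: float = 0.1,
    amplitude: float = 3.0,
    seed: int = 0,
) -> PSField:
    """Sub-element photosensitizer heterogeneity.

    Models random [PS] variation (up to ``amplitude`` times higher/lower
    than the mean) whose correlation length is ``corr_scale_mm`` -- far
    below 1/mu_eff and below the cell size.  Each cell's multiplier is
    the volume average of the many independent sub-volumes it contains,
    so per-cell multipliers concentrate near 1 as corr_scale_mm shrinks:
    the mesh element, not the microscale, sets what the dose model can
    see.  Whole-tumor volume-weighted mean is 1 exactly.
    """
    rng = np.random.default_rng(seed)
    tm = mesh.tumor_mask()
    if not np.any(tm):
        raise ValueError("mesh has no tumor cells")
    vols = mesh.volumes()[tm]
    # log-uniform microscale draws in [1/amplitude, amplitude]
    log_amp = np.log(amplitude)
    micro_var = (2 * log_amp) ** 2 / 12.0  # variance of ln m at microscale
    micro_mean = np.sinh(log_amp) / log_amp  # E[m] of log-uniform draw
    k = np.maximum(1, np.round(vols / corr_scale_mm**3).astype(int))
    # cell multiplier = average of k iid draws: mean micro_mean,
    # var (E[m^2]-E[m]^2)/k; sample via normal approximation for large k
    m2 = np.sinh(2 * log_amp) / (2 * log_amp)
    sd = np.sqrt(np.maximum(m2 - micro_mean**2, 0.0) / k)
    mult_t = rng.normal(micro_mean, sd)
    lo, hi = MULTIPLIER_BOUNDS
    for _ in range(200):
        mult_t = np.clip(mult_t, lo, hi)
        mult_t = mult_t / np.average(mult_t, weights=vols)
        if mult_t.min() >= lo and mult_t.max() <= hi:
            break
    else:
        # shrink toward 1 until the bounds and mean can coexist
        mult_t = 1.0 + 0.5 * (mult_t - 1.0)
        mult_t = np.clip(mult_t, lo, hi)
        mult_t = mult_t / np.average(mult_t, weights=vols)
    mult = np.ones(mesh.n_cells)
    mult[tm] = mult_t
    field = PSField(multiplier=mult, mean_ps=mean_ps, scenario=3, pattern=0, seed=seed)
    field.validate(mesh)
    return field


def _bbox_surface(mesh: TetraMesh) -> SphereUnion:
    # fallback implicit surface when none is supplied: a sphere matching
    # the tumor's bounding volume (only pattern recipes use it, loosely)
    tm = mesh.tumor_mask()
    c = mesh.centroids()[tm].mean(axis=0)
    v = float(mesh.volumes()[tm].sum())
    r = (3 * v / (4 * np.pi)) ** (1 / 3)
    return SphereUnion(centers=c[None, :], radii=np.array([r]))


def make_brain_fixture(
    preset: ResolutionPreset | str = "low",
    seed: int = 1,
    *,
    head_radius: float = 35.0,
    tumor_radius: float = 5.0,
    tumor_tet_volume: float | None = 0.12,
    rim_fraction: float = 0.2,
) -> tuple[TetraMesh, SphereUnion]:
    """Desk-scale layered head: bounding box, scalp/skull shell, CSF
    shell, gray-matter shell, white-matter interior, and a spherical
    tumor at the center.

    The head is meshed at the preset density; the tumor ball (plus a
    small collar) is refined to ``tumor_tet_volume`` mm^3 so that the
    tumor-volume quantum is small enough for sub-0.1% coverage control.
    Layer radii scale with ``head_radius``; the rim is the outer
    ``rim_fraction`` of the tumor radius.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    rng = np.random.default_rng(seed)
    r_head = head_radius
    r_skull_in = 0.92 * r_head
    r_csf_in = 0.86 * r_head
    r_gm_in = 0.72 * r_head
    box = r_head * 1.15

    lo = np.array([-box] * 3)
    hi = np.array([box] * 3)
    coarse = _lattice_points(lo, hi, preset.avg_tet_volume, rng)
    r_fine = tumor_radius + 2.0
    keep = np.linalg.norm(coarse, axis=1) > r_fine
    pts = [coarse[keep]]
    if tumor_tet_volume is not None and tumor_tet_volume < preset.avg_tet_volume:
        fine = _lattice_points(
            np.array([-r_fine] * 3), np.array([r_fine] * 3), tumor_tet_volume, rng
        )
        pts.append(fine[np.linalg.norm(fine, axis=1) <= r_fine])
    else:
        pts.append(coarse[~keep])
    corners = np.array(np.meshgrid([-box, box], [-box, box], [-box, box])).T.reshape(-1, 3)
    points = np.vstack(pts + [corners])
    mesh, _ = _delaunay_mesh(points)

    c = mesh.centroids()
    r = np.linalg.norm(c, axis=1)
    labels = np.full(mesh.n_cells, int(Region.BOUNDING), dtype=np.int64)
    labels[r <= r_head] = int(Region.SCALP_SKULL)
    labels[r <= r_skull_in] = int(Region.CSF)
    labels[r <= r_csf_in] = int(Region.GRAY_MATTER)
    labels[r <= r_gm_in] = int(Region.WHITE_MATTER)
    labels[r <= tumor_radius] = int(Region.TUMOR_CORE)
    mesh.region_label = labels
    surface = SphereUnion(centers=np.zeros((1, 3)), radii=np.array([tumor_radius]))
    core_rim_partition(mesh, surface, rim_fraction * tumor_radius)
    return mesh, surface
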