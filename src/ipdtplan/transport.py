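"""Monte Carlo photon-packet transport on tetrahedral meshes.

Packets are launched from interstitial sources (cylindrical diffusers
modelled as uniform lines of isotropic point emitters, or isotropic
points), propagated with exponential free paths at mu_t = mu_a + mu_s,
scattered by Henyey-Greenstein, and attenuated by continuous absorption
weighting: at each interaction a fraction mu_a/mu_t of the packet weight
is deposited in the enclosing cell and the survivor is rouletted below a
weight floor.  Cell-to-cell stepping is exact ray-face traversal with
Fresnel reflection/refraction at refractive-index mismatches; cells of
the bounding region terminate packets (perfect absorber).

Fluence per unit source energy is deposited-weight / (mu_a * cell
volume * packets launched), in 1/mm^2.

Two scattering representations are available.  ``mode="transport"``
(default) uses the similarity relation: isotropic scattering at the
reduced coefficient mu_s', which preserves mu_a and mu_s' and therefore
the diffusive fluence, at a small fraction of the interaction count of
anisotropic stepping.  ``mode="hg"`` uses the full anisotropic walk with
mu_s = mu_s'/(1-g) and the tabulated g.  The closed-form diffusion
solution (``diffusion_oracle``) depends only on mu_a and mu_s' and
validates both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from numba import njit

from .mesh import Region, TetraMesh, locate_points

__all__ = [
    "TissueOptics",
    "OpticalPropertySet",
    "TABLE_OPTICS_635NM",
    "Source",
    "FluenceField",
    "mc_fluence",
    "diffusion_oracle",
    "superpose",
]


@dataclass(frozen=True)
class TissueOptics:
    """mu_a, mu_s' in 1/mm; g anisotropy; n refractive index."""

    mu_a: float
    mu_s_prime: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s_prime < 0:
            raise ValueError("mu_a and mu_s' must be nonnegative")
        if not (-1.0 <= self.g < 1.0):
            raise ValueError("g must lie in [-1, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_s(self) -> float:
        return self.mu_s_prime / (1.0 - self.g)

    @property
    def mu_eff(self) -> float:
        return float(np.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_prime)))

    @property
    def diffusion_coefficient(self) -> float:
        """D in mm."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))


class OpticalPropertySet(dict):
    """Mapping region label -> TissueOptics."""

    def require(self, labels: np.ndarray) -> None:
        missing = sorted(set(np.unique(labels).tolist()) - set(self.keys()) - {int(Region.BOUNDING)})
        if missing:
            raise ValueError(f"no optical properties for region labels {missing}")


#: Brain-tissue optical properties at 635 nm (1/mm).
TABLE_OPTICS_635NM = OpticalPropertySet(
    {
        int(Region.SCALP_SKULL): TissueOptics(0.55, 10.8, 0.8, 1.56),
        int(Region.CSF): TissueOptics(0.0038, 0.005, 0.87, 1.3891),
        int(Region.GRAY_MATTER): TissueOptics(0.01, 8.8, 0.89, 1.36),
        int(Region.WHITE_MATTER): TissueOptics(0.08, 40.7, 0.84, 1.467),
        int(Region.TUMOR_CORE): TissueOptics(0.18, 10.0, 0.8, 1.39),
        int(Region.TUMOR_RIM): TissueOptics(0.18, 10.0, 0.8, 1.39),
    }
)


@dataclass(frozen=True)
class Source:
    """Interstitial light source.

    A cylindrical diffuser emits uniformly along the segment p0-p1; a
    point source has p1 == p0.  ``power`` in W (1.0 = unit source).
    """

    p0: np.ndarray
    p1: np.ndarray
    power: float = 1.0
    kind: str = "cylindrical_diffuser"

    def __post_init__(self) -> None:
        object.__setattr__(self, "p0", np.asarray(self.p0, dtype=float))
        object.__setattr__(self, "p1", np.asarray(self.p1, dtype=float))
        if self.kind not in ("cylindrical_diffuser", "point"):
            raise ValueError(f"unknown source kind {self.kind!r}")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.p0 + self.p1)


@dataclass
class FluenceField:
    """Per-cell fluence per unit source energy (1/mm^2)."""

    fluence: np.ndarray
    n_packets: int
    seed: int
    rel_std_error: np.ndarray | None = None
    balance: dict = field(default_factory=dict)

    def validate(self) -> None:
        if np.any(self.fluence < 0):
            raise ValueError("fluence must be nonnegative")


@njit(cache=True, fastmath=True)
def _mc_kernel(
    face_normal,
    face_offset,
    neighbors,
    mua,
    mus,
    g_cell,
    n_cell,
    absorbing,
    launch_pos,
    launch_tet,
    n_packets,
    n_batches,
    seed,
    roulette_floor,
    max_events,
):  # pragma: no cover - exercised through mc_fluence
    np.random.seed(seed)
    n_cells = neighbors.shape[0]
    A = np.zeros((n_batches, n_cells))
    # stats: absorbed, escaped, roulette_killed, roulette_boost, lost
    stats = np.zeros(5)
    n_sites = launch_pos.shape[0]
    eps = 1e-12

    for p in range(n_packets):
        site = p % n_sites
        batch = (p * n_batches) // n_packets
        px = launch_pos[site, 0]
        py = launch_pos[site, 1]
        pz = launch_pos[site, 2]
        tet = launch_tet[site]
        # isotropic emission (Marsaglia rejection: no trig)
        while True:
            ux = 2.0 * np.random.random() - 1.0
            uy = 2.0 * np.random.random() - 1.0
            uz = 2.0 * np.random.random() - 1.0
            rr2 = ux * ux + uy * uy + uz * uz
            if 1e-12 < rr2 <= 1.0:
                break
        inv = 1.0 / np.sqrt(rr2)
        ux *= inv
        uy *= inv
        uz *= inv
        w = 1.0
        alive = True
        events = 0

        while alive:
            tau = -np.log(np.random.random() + 1e-300)
            # traverse cells until the optical depth is used up
            while True:
                mt = mua[tet] + mus[tet]
                s = tau / mt if mt > 0 else 1e30
                # exit distance: nearest outgoing face (unit outward
                # normals and plane offsets precomputed per cell)
                t_exit = 1e30
                f_exit = -1
                nx_o = 0.0
                ny_o = 0.0
                nz_o = 0.0
                for k in range(4):
                    nx = face_normal[tet, k, 0]
                    ny = face_normal[tet, k, 1]
                    nz = face_normal[tet, k, 2]
                    denom = nx * ux + ny * uy + nz * uz
                    if denom > eps:
                        t = (
                            face_offset[tet, k] - (nx * px + ny * py + nz * pz)
                        ) / denom
                        if t < 0.0:
                            t = 0.0
                        if t < t_exit:
                            t_exit = t
                            f_exit = k
                            nx_o = nx
                            ny_o = ny
                            nz_o = nz
                if f_exit < 0:  # numerically stuck
                    stats[4] += w
                    alive = False
                    break
                if s < t_exit:
                    px += s * ux
                    py += s * uy
                    pz += s * uz
                    break  # interact here
                # cross the face
                px += t_exit * ux
                py += t_exit * uy
                pz += t_exit * uz
                tau -= t_exit * mt
                nb = neighbors[tet, f_exit]
                if nb < 0:
                    stats[1] += w
                    alive = False
                    break
                if absorbing[nb]:
                    stats[1] += w
                    alive = False
                    break
                n1 = n_cell[tet]
                n2 = n_cell[nb]
                if n1 != n2:
                    cos_i = ux * nx_o + uy * ny_o + uz * nz_o
                    if cos_i < 0.0:
                        cos_i = -cos_i
                    eta = n1 / n2
                    sin2t = eta * eta * (1.0 - cos_i * cos_i)
                    if sin2t >= 1.0:
                        refl = 1.0
                        cos_t = 0.0
                    else:
                        cos_t = np.sqrt(1.0 - sin2t)
                        rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
                        rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
                        refl = 0.5 * (rs * rs + rp * rp)
                    if np.random.random() < refl:
                        d = ux * nx_o + uy * ny_o + uz * nz_o
                        ux -= 2.0 * d * nx_o
                        uy -= 2.0 * d * ny_o
                        uz -= 2.0 * d * nz_o
                    else:
                        # d = cos_i*n_o + tangential; transmitted dir is
                        # eta*d + (cos_t - eta*cos_i)*n_o
                        f = cos_t - eta * cos_i
                        ux = eta * ux + f * nx_o
                        uy = eta * uy + f * ny_o
                        uz = eta * uz + f * nz_o
                        norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= norm
                        uy /= norm
                        uz /= norm
                        tet = nb
                else:
                    tet = nb
                events += 1
                if events > max_events:
                    stats[4] += w
                    alive = False
                    break
            if not alive:
                break
            # interaction: deposit and scatter
            mt = mua[tet] + mus[tet]
            dep = w * mua[tet] / mt
            A[batch, tet] += dep
            stats[0] += dep
            w -= dep
            if w < roulette_floor:
                if np.random.random() < 0.1:
                    boost = w * 9.0
                    stats[3] += boost
                    w *= 10.0
                else:
                    stats[2] += w
                    alive = False
                    continue
            g = g_cell[tet]
            if g == 0.0:
                while True:
                    ux = 2.0 * np.random.random() - 1.0
                    uy = 2.0 * np.random.random() - 1.0
                    uz = 2.0 * np.random.random() - 1.0
                    rr2 = ux * ux + uy * uy + uz * uz
                    if 1e-12 < rr2 <= 1.0:
                        break
                inv = 1.0 / np.sqrt(rr2)
                ux *= inv
                uy *= inv
                uz *= inv
            else:
                u = np.random.random()
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                cos_t = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if cos_t > 1.0:
                    cos_t = 1.0
                elif cos_t < -1.0:
                    cos_t = -1.0
                sin_t = np.sqrt(1.0 - cos_t * cos_t)
                phi = 2.0 * np.pi * np.random.random()
                cp = np.cos(phi)
                sp = np.sin(phi)
                if abs(uz) > 0.99999:
                    nux = sin_t * cp
                    nuy = sin_t * sp
                    nuz = cos_t * (1.0 if uz > 0 else -1.0)
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    nux = sin_t * (ux * uz * cp - uy * sp) / den + ux * cos_t
                    nuy = sin_t * (uy * uz * cp + ux * sp) / den + uy * cos_t
                    nuz = -sin_t * cp * den + uz * cos_t
                ux, uy, uz = nux, nuy, nuz
            events += 1
            if events > max_events:
                stats[4] += w
                alive = False
    return A, stats


def mc_fluence(
    mesh: TetraMesh,
    props: Mapping[int, TissueOptics],
    source: Source,
    n_packets: int = 1_000_000,
    seed: int = 1,
    ps_field=None,
    *,
    beta: float = 0.0,
    mode: str = "transport",
    roulette_floor: float = 1e-4,
    max_events: int = 200_000,
    n_batches: int = 10,
    n_launch_sites: int = 4096,
) -> FluenceField:
    """Per-cell fluence per unit source energy from one source.

    ``ps_field`` with ``beta`` > 0 scales tumor absorption by
    (1 + beta*(multiplier - 1)); the default beta = 0 keeps optics
    independent of the photosensitizer map, so heterogeneity enters only
    through the dose threshold.
    """
    if n_packets < 1_000:
        raise ValueError("n_packets must be >= 1000")
    if mode not in ("transport", "hg"):
        raise ValueError("mode must be 'transport' or 'hg'")
    labels = mesh.region_label
    if isinstance(props, dict) and not isinstance(props, OpticalPropertySet):
        props = OpticalPropertySet(props)
    props.require(labels)

    n_cells = mesh.n_cells
    mua = np.zeros(n_cells)
    mus = np.zeros(n_cells)
    g_cell = np.zeros(n_cells)
    n_cell = np.ones(n_cells)
    absorbing = labels == int(Region.BOUNDING)
    for lab, op in props.items():
        m = labels == lab
        mua[m] = op.mu_a
        if mode == "transport":
            mus[m] = op.mu_s_prime
            g_cell[m] = 0.0
        else:
            mus[m] = op.mu_s
            g_cell[m] = op.g
        n_cell[m] = op.n
    if ps_field is not None and beta != 0.0:
        tm = mesh.tumor_mask()
        mua[tm] *= 1.0 + beta * (ps_field.multiplier[tm] - 1.0)

    rng = np.random.default_rng(seed)
    n_sites = min(n_launch_sites, n_packets)
    if source.kind == "point" or source.length == 0:
        sites = np.tile(source.p0, (1, 1))
    else:
        t = (np.arange(n_sites) + rng.random(n_sites)) / n_sites
        sites = source.p0[None, :] + t[:, None] * (source.p1 - source.p0)[None, :]
    site_tets = locate_points(mesh, sites)
    good = site_tets >= 0
    if not np.all(good):
        if not np.any(good):
            raise ValueError("source lies outside the mesh")
        sites, site_tets = sites[good], site_tets[good]
    if np.any(absorbing[site_tets]):
        raise ValueError("source placed inside the absorbing bounding region")

    face_normal, face_offset = mesh.face_planes()
    A, stats = _mc_kernel(
        face_normal,
        face_offset,
        mesh.neighbors(),
        mua,
        mus,
        g_cell,
        n_cell,
        absorbing,
        np.ascontiguousarray(sites),
        site_tets,
        int(n_packets),
        int(n_batches),
        int(seed) % (2**31 - 1),
        float(roulette_floor),
        int(max_events),
    )
    deposited = A.sum(axis=0)
    volumes = mesh.volumes()
    with np.errstate(divide="ignore", invalid="ignore"):
        fluence = deposited / (mua * volumes * n_packets)
    fluence[mua == 0] = 0.0

    batch_fluence = A / (np.maximum(mua * volumes, 1e-300)[None, :] * (n_packets / n_batches))
    bmean = batch_fluence.mean(axis=0)
    bstd = batch_fluence.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rse = bstd / (np.sqrt(n_batches) * bmean)
    rse[~np.isfinite(rse)] = np.inf

    balance = {
        "launched": float(n_packets),
        "absorbed": float(stats[0]),
        "escaped": float(stats[1]),
        "roulette_killed": float(stats[2]),
        "roulette_boost": float(stats[3]),
        "lost": float(stats[4]),
    }
    return FluenceField(
        fluence=fluence,
        n_packets=n_packets,
        seed=seed,
        rel_std_error=rse,
        balance=balance,
    )


def diffusion_oracle(r: float | np.ndarray, props: TissueOptics) -> float | np.ndarray:
    """Diffusion-approximation fluence of an isotropic point source of
    unit power in an infinite homogeneous medium:

        phi(r) = exp(-mu_eff r) / (4 pi D r)   [1/mm^2]
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    phi = np.exp(-props.mu_eff * r) / (4.0 * np.pi * props.diffusion_coefficient * r)
    return float(phi) if phi.ndim == 0 else phi


def superpose(fields: Sequence[FluenceField], powers: Sequence[float]) -> np.ndarray:
    """Total fluence from per-source unit fields and source powers."""
    if len(fields) != len(powers):
        raise ValueError("need one power per field")
    shapes = {f.fluence.shape for f in fields}
    if len(shapes) > 1:
        raise ValueError("fields live on different meshes")
    total = np.zeros(fields[0].fluence.shape)
    for f, p in zip(fields, powers):
        if p < 0:
            raise ValueError("powers must be nonnegative")
        total += p * f.fluence
    return total
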