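"""Tetrahedral meshes with per-cell tissue labels.

Coordinates are in mm, fields are cell-centered, node indexing is
0-based.  Region labels follow the layered-head convention used
throughout the package: a photon-terminating bounding region, scalp and
skull, CSF, gray matter, white matter, and the tumor split into core and
rim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components


class Region(IntEnum):
    """Tissue labels; BOUNDING terminates photons (perfect absorber)."""

    BOUNDING = 0
    SCALP_SKULL = 1
    CSF = 2
    GRAY_MATTER = 3
    WHITE_MATTER = 4
    TUMOR_CORE = 5
    TUMOR_RIM = 6


TUMOR_REGIONS = (Region.TUMOR_CORE, Region.TUMOR_RIM)

REGION_NAMES = {r.value: r.name.lower() for r in Region}


@dataclass
class TetraMesh:
    """Tetrahedral mesh: nodes (n,3) in mm, tetrahedra (m,4) node indices,
    ``region_label`` (m,) integer tissue labels, optional extra cell data."""

    nodes: np.ndarray
    tetrahedra: np.ndarray
    region_label: np.ndarray
    cell_data: dict[str, np.ndarray] = field(default_factory=dict)
    _volumes: np.ndarray | None = field(default=None, repr=False)
    _neighbors: np.ndarray | None = field(default=None, repr=False)
    _face_planes: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=np.float64)
        self.tetrahedra = np.ascontiguousarray(self.tetrahedra, dtype=np.int64)
        self.region_label = np.asarray(self.region_label, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.tetrahedra.ndim != 2 or self.tetrahedra.shape[1] != 4:
            raise ValueError("tetrahedra must be (m, 4)")
        if self.region_label.shape != (self.n_cells,):
            raise ValueError("region_label must have one entry per cell")

    @property
    def n_cells(self) -> int:
        return self.tetrahedra.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def volumes(self) -> np.ndarray:
        """Per-cell volumes in mm^3 (always positive)."""
        if self._volumes is None:
            p = self.nodes[self.tetrahedra]
            d1 = p[:, 1] - p[:, 0]
            d2 = p[:, 2] - p[:, 0]
            d3 = p[:, 3] - p[:, 0]
            self._volumes = np.abs(np.einsum("ij,ij->i", d1, np.cross(d2, d3))) / 6.0
        return self._volumes

    def centroids(self) -> np.ndarray:
        return self.nodes[self.tetrahedra].mean(axis=1)

    def neighbors(self) -> np.ndarray:
        """(m, 4) face-adjacency; entry k is the cell sharing the face
        opposite local vertex k, or -1 on the mesh boundary."""
        if self._neighbors is None:
            self._neighbors = _face_neighbors(self.tetrahedra)
        return self._neighbors

    def face_planes(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell outward unit face normals (m,4,3) and plane offsets
        (m,4) with n . x = d on face k (the face opposite local vertex k)."""
        if self._face_planes is None:
            p = self.nodes[self.tetrahedra]  # (m, 4, 3)
            normals = np.empty((self.n_cells, 4, 3))
            offsets = np.empty((self.n_cells, 4))
            for k in range(4):
                idx = [i for i in range(4) if i != k]
                a, b, c = p[:, idx[0]], p[:, idx[1]], p[:, idx[2]]
                n = np.cross(b - a, c - a)
                # orient away from the opposite vertex
                flip = np.einsum("ij,ij->i", n, p[:, k] - a) > 0
                n[flip] *= -1.0
                n /= np.linalg.norm(n, axis=1, keepdims=True)
                normals[:, k] = n
                offsets[:, k] = np.einsum("ij,ij->i", n, a)
            self._face_planes = (normals, offsets)
        return self._face_planes

    def tumor_mask(self) -> np.ndarray:
        return np.isin(self.region_label, [int(r) for r in TUMOR_REGIONS])

    def region_volume(self, *labels: int) -> float:
        mask = np.isin(self.region_label, list(labels))
        return float(self.volumes()[mask].sum())

    def validate(self) -> None:
        if np.any(self.volumes() <= 0):
            raise ValueError("mesh contains degenerate (zero-volume) cells")
        known = {int(r) for r in Region}
        present = set(np.unique(self.region_label).tolist())
        if not present <= known:
            raise ValueError(f"unknown region labels {sorted(present - known)}")

    def tumor_connected(self) -> bool:
        """True if the tumor cells form one face-connected component."""
        mask = self.tumor_mask()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return False
        remap = -np.ones(self.n_cells, dtype=np.int64)
        remap[idx] = np.arange(idx.size)
        nb = self.neighbors()[idx]
        rows, cols = [], []
        for k in range(4):
            nk = nb[:, k]
            good = (nk >= 0) & mask[np.clip(nk, 0, None)]
            rows.append(np.arange(idx.size)[good])
            cols.append(remap[nk[good]])
        g = coo_matrix(
            (np.ones(sum(len(r) for r in rows)), (np.concatenate(rows), np.concatenate(cols))),
            shape=(idx.size, idx.size),
        )
        n_comp, _ = connected_components(g, directed=False)
        return n_comp == 1


def _face_neighbors(tets: np.ndarray) -> np.ndarray:
    """Face adjacency via a sorted-face table (vectorized)."""
    m = tets.shape[0]
    # face opposite local vertex k
    faces = np.stack(
        [tets[:, [1, 2, 3]], tets[:, [0, 2, 3]], tets[:, [0, 1, 3]], tets[:, [0, 1, 2]]],
        axis=1,
    ).reshape(-1, 3)
    faces = np.sort(faces, axis=1)
    order = np.lexsort(faces.T)
    sorted_faces = faces[order]
    same = np.all(sorted_faces[1:] == sorted_faces[:-1], axis=1)
    neighbors = -np.ones(4 * m, dtype=np.int64)
    a = order[:-1][same]  # flat index of first of a matched pair
    b = order[1:][same]
    neighbors[a] = b // 4
    neighbors[b] = a // 4
    return neighbors.reshape(m, 4)


def locate_points(mesh: TetraMesh, points: np.ndarray, *, k_max: int = 64) -> np.ndarray:
    """Cell index containing each point (-1 if outside the mesh).

    Candidate cells come from a KD-tree over centroids; membership is a
    barycentric-coordinate check.
    """
    from scipy.spatial import cKDTree

    points = np.atleast_2d(np.asarray(points, dtype=float))
    tree = cKDTree(mesh.centroids())
    result = -np.ones(points.shape[0], dtype=np.int64)
    pending = np.arange(points.shape[0])
    k = 8
    while pending.size and k <= k_max:
        _, cand = tree.query(points[pending], k=k)
        cand = np.atleast_2d(cand)
        for col in range(cand.shape[1]):
            unresolved = result[pending] < 0
            if not np.any(unresolved):
                break
            rows = pending[unresolved]
            cells = cand[unresolved, col]
            inside = _points_in_cells(mesh, points[rows], cells)
            result[rows[inside]] = cells[inside]
        pending = pending[result[pending] < 0]
        k *= 2
    return result


def _points_in_cells(mesh: TetraMesh, pts: np.ndarray, cells: np.ndarray) -> np.ndarray:
    verts = mesh.nodes[mesh.tetrahedra[cells]]  # (q, 4, 3)
    t = verts[:, 1:] - verts[:, :1]  # (q, 3, 3) edge matrix
    rhs = pts - verts[:, 0]
    try:
        bary = np.linalg.solve(t.transpose(0, 2, 1), rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:  # degenerate candidate cell
        return np.zeros(len(cells), dtype=bool)
    tol = 1e-10
    return (bary.min(axis=1) >= -tol) & (bary.sum(axis=1) <= 1 + tol)
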