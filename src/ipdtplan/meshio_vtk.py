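"""Readers and writers for tetrahedral unstructured grids.

Supports the VTK legacy dialect (ASCII and big-endian binary) and the
XML ``.vtu`` dialect (inline ASCII).  Only tetrahedral cells (VTK type
10) are accepted; named cell-data arrays such as ``region_label`` and
``ps_multiplier`` round-trip losslessly.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import TetraMesh

__all__ = ["read_mesh", "write_mesh"]

VTK_TETRA = 10


def read_mesh(path: str | Path) -> TetraMesh:
    """Read a tetrahedral mesh from a legacy ``.vtk`` or XML ``.vtu`` file.

    The ``region_label`` cell array becomes the mesh labels (defaulting
    to zero if absent); all other cell arrays land in ``cell_data``.
    """
    path = Path(path)
    head = path.open("rb").read(6)
    if head.startswith(b"<") or path.suffix.lower() == ".vtu":
        nodes, tets, cell_data = _read_vtu(path)
    else:
        nodes, tets, cell_data = _read_legacy(path)
    region = cell_data.pop("region_label", np.zeros(len(tets), dtype=np.int64))
    return TetraMesh(
        nodes=nodes,
        tetrahedra=tets,
        region_label=np.asarray(region, dtype=np.int64),
        cell_data=cell_data,
    )


def write_mesh(
    mesh: TetraMesh,
    path: str | Path,
    extra_cell_data: dict[str, np.ndarray] | None = None,
    *,
    fmt: str | None = None,
) -> None:
    """Write a mesh as ``.vtu`` (XML ASCII, default) or legacy ``.vtk``.

    ``region_label`` is always written; ``mesh.cell_data`` and
    ``extra_cell_data`` are appended as named cell arrays.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vtk" if path.suffix.lower() == ".vtk" else "vtu"
    cell_data: dict[str, np.ndarray] = {"region_label": mesh.region_label}
    cell_data.update(mesh.cell_data)
    if extra_cell_data:
        cell_data.update(extra_cell_data)
    if fmt == "vtu":
        _write_vtu(mesh, cell_data, path)
    elif fmt == "vtk":
        _write_legacy(mesh, cell_data, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


# ---------------------------------------------------------------- legacy


def _read_legacy(path: Path):
    raw = path.read_bytes()
    lines_end = raw.find(b"DATASET")
    header = raw[:lines_end].decode("ascii", errors="replace")
    binary = "BINARY" in header.upper()

    if not binary:
        return _read_legacy_ascii(raw.decode("ascii"))
    return _read_legacy_binary(raw)


def _read_legacy_ascii(text: str):
    tokens = text.split()
    idx = 0

    def expect(word):
        nonlocal idx
        while idx < len(tokens) and tokens[idx].upper() != word:
            idx += 1
        if idx >= len(tokens):
            raise ValueError(f"legacy VTK: missing {word} section")
        idx += 1

    expect("DATASET")
    if tokens[idx].upper() != "UNSTRUCTURED_GRID":
        raise ValueError(f"unsupported dataset type {tokens[idx]}")
    expect("POINTS")
    n_pts = int(tokens[idx]); idx += 2  # count, dtype
    nodes = np.array(tokens[idx : idx + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    idx += 3 * n_pts
    expect("CELLS")
    n_cells = int(tokens[idx]); total = int(tokens[idx + 1]); idx += 2
    conn = np.array(tokens[idx : idx + total], dtype=np.int64)
    idx += total
    expect("CELL_TYPES")
    n_types = int(tokens[idx]); idx += 1
    types = np.array(tokens[idx : idx + n_types], dtype=np.int64)
    idx += n_types
    tets = _connectivity_to_tets(conn, types)

    cell_data: dict[str, np.ndarray] = {}
    while idx < len(tokens):
        word = tokens[idx].upper()
        if word == "CELL_DATA":
            idx += 2
        elif word == "SCALARS":
            name = tokens[idx + 1]
            dtype = tokens[idx + 2].lower()
            idx += 3
            if idx < len(tokens) and tokens[idx].isdigit():
                idx += 1  # optional numComp
            # LOOKUP_TABLE default
            if idx < len(tokens) and tokens[idx].upper() == "LOOKUP_TABLE":
                idx += 2
            vals = np.array(tokens[idx : idx + n_cells], dtype=float)
            idx += n_cells
            if dtype in ("int", "long", "vtkidtype", "short"):
                vals = vals.astype(np.int64)
            cell_data[name] = vals
        else:
            idx += 1
    return nodes, tets, cell_data


def _read_legacy_binary(raw: bytes):
    # Header lines are ASCII; payload blocks are big-endian per VTK spec.
    def find_line(key, start=0):
        pos = raw.find(key, start)
        if pos < 0:
            raise ValueError(f"legacy VTK: missing {key.decode()} section")
        eol = raw.find(b"\n", pos)
        return raw[pos:eol].decode("ascii"), eol + 1

    line, off = find_line(b"POINTS")
    _, n_pts, dtype = line.split()
    n_pts = int(n_pts)
    itemsize = 8 if dtype == "double" else 4
    nodes = np.frombuffer(
        raw[off : off + 3 * n_pts * itemsize], dtype=f">f{itemsize}"
    ).reshape(n_pts, 3).astype(float)

    line, off = find_line(b"CELLS", off)
    _, n_cells, total = line.split()
    n_cells, total = int(n_cells), int(total)
    conn = np.frombuffer(raw[off : off + 4 * total], dtype=">i4").astype(np.int64)
    off += 4 * total
    line, off = find_line(b"CELL_TYPES", off)
    n_types = int(line.split()[1])
    types = np.frombuffer(raw[off : off + 4 * n_types], dtype=">i4").astype(np.int64)
    off += 4 * n_types
    tets = _connectivity_to_tets(conn, types)

    cell_data: dict[str, np.ndarray] = {}
    pos = raw.find(b"SCALARS", off)
    while pos >= 0:
        line, off = find_line(b"SCALARS", pos)
        parts = line.split()
        name, dtype = parts[1], parts[2]
        _, off = find_line(b"LOOKUP_TABLE", off)
        if dtype in ("int", "long"):
            width = 4 if dtype == "int" else 8
            vals = np.frombuffer(raw[off : off + width * n_cells], dtype=f">i{width}")
            vals = vals.astype(np.int64)
        else:
            width = 8 if dtype == "double" else 4
            vals = np.frombuffer(raw[off : off + width * n_cells], dtype=f">f{width}")
            vals = vals.astype(float)
        off += width * n_cells
        cell_data[name] = vals
        pos = raw.find(b"SCALARS", off)
    return nodes, tets, cell_data


def _connectivity_to_tets(conn: np.ndarray, types: np.ndarray) -> np.ndarray:
    bad = set(types.tolist()) - {VTK_TETRA}
    if bad:
        raise ValueError(
            f"only tetrahedral cells (type {VTK_TETRA}) are supported; "
            f"file contains cell types {sorted(bad)}"
        )
    conn = conn.reshape(-1, 5)
    if np.any(conn[:, 0] != 4):
        raise ValueError("malformed tetra connectivity (cell size != 4)")
    return conn[:, 1:].copy()


def _write_legacy(mesh: TetraMesh, cell_data: dict, path: Path) -> None:
    m = mesh.n_cells
    with path.open("w") as f:
        f.write("# vtk DataFile Version 3.0\nipdtplan mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.17g")
        f.write(f"CELLS {m} {5 * m}\n")
        cells = np.column_stack([np.full(m, 4, dtype=np.int64), mesh.tetrahedra])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {m}\n")
        np.savetxt(f, np.full(m, VTK_TETRA, dtype=np.int64), fmt="%d")
        f.write(f"CELL_DATA {m}\n")
        for name, vals in cell_data.items():
            vals = np.asarray(vals)
            if np.issubdtype(vals.dtype, np.integer):
                f.write(f"SCALARS {name} long 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, vals, fmt="%d")
            else:
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, vals, fmt="%.17g")


# ------------------------------------------------------------------ vtu


def _parse(text, dtype):
    return np.array((text or "").split(), dtype=dtype)


def _read_vtu(path: Path):
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise ValueError("VTU file has no Piece element")

    def data_array(parent, name):
        for da in parent.findall("DataArray"):
            if da.get("Name") == name:
                return da
        raise ValueError(f"VTU: missing DataArray {name}")

    pts = piece.find("Points")
    nodes = _parse(data_array(pts, "Points").text, float).reshape(-1, 3)
    cells_el = piece.find("Cells")
    conn = _parse(data_array(cells_el, "connectivity").text, np.int64)
    offsets = _parse(data_array(cells_el, "offsets").text, np.int64)
    types = _parse(data_array(cells_el, "types").text, np.int64)
    bad = set(types.tolist()) - {VTK_TETRA}
    if bad:
        raise ValueError(f"only tetrahedra supported; found cell types {sorted(bad)}")
    if np.any(np.diff(np.concatenate([[0], offsets])) != 4):
        raise ValueError("malformed tetra connectivity in VTU")
    tets = conn.reshape(-1, 4)

    cell_data: dict[str, np.ndarray] = {}
    cd = piece.find("CellData")
    if cd is not None:
        for da in cd.findall("DataArray"):
            name = da.get("Name")
            is_int = "Int" in (da.get("type") or "")
            vals = _parse(da.text, float)
            cell_data[name] = vals.astype(np.int64) if is_int else vals
    return nodes, tets, cell_data


def _write_vtu(mesh: TetraMesh, cell_data: dict, path: Path) -> None:
    m = mesh.n_cells

    def arr_text(a, fmt):
        return "\n".join(" ".join(fmt % v for v in row) for row in np.atleast_2d(a))

    with path.open("w") as f:
        f.write('<?xml version="1.0"?>\n')
        f.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        f.write("<UnstructuredGrid>\n")
        f.write(f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{m}">\n')
        f.write("<Points>\n")
        f.write('<DataArray type="Float64" Name="Points" NumberOfComponents="3" format="ascii">\n')
        f.write(arr_text(mesh.nodes, "%.17g"))
        f.write("\n</DataArray>\n</Points>\n<Cells>\n")
        f.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        f.write(arr_text(mesh.tetrahedra, "%d"))
        f.write("\n</DataArray>\n")
        f.write('<DataArray type="Int64" Name="offsets" format="ascii">\n')
        f.write(" ".join(str(4 * (i + 1)) for i in range(m)))
        f.write("\n</DataArray>\n")
        f.write('<DataArray type="UInt8" Name="types" format="ascii">\n')
        f.write(" ".join(str(VTK_TETRA) for _ in range(m)))
        f.write("\n</DataArray>\n</Cells>\n<CellData>\n")
        for name, vals in cell_data.items():
            vals = np.asarray(vals)
            if np.issubdtype(vals.dtype, np.integer):
                f.write(f'<DataArray type="Int64" Name="{name}" format="ascii">\n')
                f.write(" ".join(str(int(v)) for v in vals))
            else:
                f.write(f'<DataArray type="Float64" Name="{name}" format="ascii">\n')
                f.write(" ".join("%.17g" % v for v in vals))
            f.write("\n</DataArray>\n")
        f.write("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
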