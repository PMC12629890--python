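"""Mesh readers and writers: STL (ASCII + binary), PLY (ASCII), VTK legacy ASCII.

STL stores per-facet vertex triplets, so reading merges bit-identical
duplicate vertices to recover shared connectivity; a write-then-read round
trip preserves vertex coordinates to better than 1e-6 mm (binary STL and
VTK/PLY are exact float round trips up to text formatting).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .geometry import TriangleMesh

__all__ = ["read_mesh", "write_mesh"]

_FORMATS = {".stl": "stl", ".ply": "ply", ".vtk": "vtk"}


def read_mesh(path) -> TriangleMesh:
    """Read a triangle mesh, dispatching on file extension."""
    path = Path(path)
    fmt = _FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"unsupported mesh format: {path.suffix!r}")
    if fmt == "stl":
        return _read_stl(path)
    if fmt == "ply":
        return _read_ply(path)
    return _read_vtk(path)


def write_mesh(mesh: TriangleMesh, path, *, binary: bool = False) -> None:
    """Write a triangle mesh, dispatching on file extension.

    ``binary`` selects binary STL; PLY and VTK are always ASCII.
    """
    path = Path(path)
    fmt = _FORMATS.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"unsupported mesh format: {path.suffix!r}")
    if fmt == "stl":
        (_write_stl_binary if binary else _write_stl_ascii)(mesh, path)
    elif fmt == "ply":
        _write_ply(mesh, path)
    else:
        _write_vtk(mesh, path)


# ---------------------------------------------------------------- STL

def _merge_triangle_soup(tris: np.ndarray) -> TriangleMesh:
    flat = tris.reshape(-1, 3)
    verts, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return TriangleMesh(verts, faces)


def _read_stl(path: Path) -> TriangleMesh:
    raw = path.read_bytes()
    is_ascii = raw[:5] == b"solid"
    if is_ascii:
        # binary files sometimes start with 'solid' too; verify the body parses
        try:
            return _read_stl_ascii(raw.decode("ascii", errors="strict"))
        except (UnicodeDecodeError, ValueError):
            pass
    return _read_stl_binary(raw)


def _read_stl_ascii(text: str) -> TriangleMesh:
    coords: list[list[float]] = []
    for line in text.splitlines():
        parts = line.split()
        if parts and parts[0] == "vertex":
            coords.append([float(x) for x in parts[1:4]])
    if not coords or len(coords) % 3:
        raise ValueError("malformed ASCII STL")
    return _merge_triangle_soup(np.asarray(coords).reshape(-1, 3, 3))


def _read_stl_binary(raw: bytes) -> TriangleMesh:
    if len(raw) < 84:
        raise ValueError("truncated binary STL")
    (n,) = struct.unpack_from("<I", raw, 80)
    if len(raw) < 84 + 50 * n:
        raise ValueError("truncated binary STL body")
    rec = np.frombuffer(raw, dtype=np.uint8, count=50 * n, offset=84).reshape(n, 50)
    data = rec[:, :48].copy().view("<f4").reshape(n, 4, 3)
    return _merge_triangle_soup(data[:, 1:, :].astype(np.float64))


def _facet_normals(mesh: TriangleMesh) -> np.ndarray:
    tri = mesh.triangles()
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return n / norms


def _write_stl_ascii(mesh: TriangleMesh, path: Path) -> None:
    tri = mesh.triangles()
    normals = _facet_normals(mesh)
    lines = ["solid mesh"]
    for t, n in zip(tri, normals):
        lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
        lines.append("    outer loop")
        for v in t:
            lines.append(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append("endsolid mesh")
    path.write_text("\n".join(lines) + "\n")


def _write_stl_binary(mesh: TriangleMesh, path: Path) -> None:
    tri = mesh.triangles().astype("<f4")
    normals = _facet_normals(mesh).astype("<f4")
    n = len(tri)
    rec = np.zeros((n, 50), dtype=np.uint8)
    body = np.concatenate([normals[:, None, :], tri], axis=1).reshape(n, 48 // 4)
    rec[:, :48] = body.view(np.uint8).reshape(n, 48)
    with open(path, "wb") as fh:
        fh.write(b"\0" * 80)
        fh.write(struct.pack("<I", n))
        fh.write(rec.tobytes())


# ---------------------------------------------------------------- PLY

def _read_ply(path: Path) -> TriangleMesh:
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ValueError("not a PLY file")
    n_vert = n_face = None
    i = 1
    if "ascii" not in lines[i]:
        raise ValueError("only ASCII PLY is supported")
    while i < len(lines):
        parts = lines[i].split()
        if parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "face"]:
            n_face = int(parts[2])
        elif parts[:1] == ["end_header"]:
            i += 1
            break
        i += 1
    if n_vert is None or n_face is None:
        raise ValueError("PLY header missing vertex/face elements")
    verts = np.array(
        [[float(x) for x in lines[i + k].split()[:3]] for k in range(n_vert)]
    )
    i += n_vert
    faces = []
    for k in range(n_face):
        parts = [int(x) for x in lines[i + k].split()]
        if parts[0] != 3:
            raise ValueError("only triangle faces are supported")
        faces.append(parts[1:4])
    return TriangleMesh(verts, np.asarray(faces))


def _write_ply(mesh: TriangleMesh, path: Path) -> None:
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines += [f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in mesh.vertices]
    lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces]
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- VTK legacy

def _read_vtk(path: Path) -> TriangleMesh:
    tokens_lines = path.read_text().splitlines()
    if len(tokens_lines) < 4 or "vtk" not in tokens_lines[0].lower():
        raise ValueError("not a legacy VTK file")
    if tokens_lines[2].strip().upper() != "ASCII":
        raise ValueError("only ASCII legacy VTK is supported")
    tokens = " ".join(tokens_lines[4:]).split()
    try:
        i = tokens.index("POINTS")
        n_vert = int(tokens[i + 1])
        at = i + 3
        verts = np.array(
            [float(x) for x in tokens[at:at + 3 * n_vert]]
        ).reshape(n_vert, 3)
        at += 3 * n_vert
        j = tokens.index("POLYGONS", at)
        n_face = int(tokens[j + 1])
        at = j + 3
        faces = []
        for _ in range(n_face):
            cnt = int(tokens[at])
            if cnt != 3:
                raise ValueError("only triangle polygons are supported")
            faces.append([int(x) for x in tokens[at + 1:at + 4]])
            at += 4
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed legacy VTK polydata: {exc}") from exc
    return TriangleMesh(verts, np.asarray(faces))


def _write_vtk(mesh: TriangleMesh, path: Path) -> None:
    lines = [
        "# vtk DataFile Version 3.0",
        "triangle mesh",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {mesh.n_vertices} double",
    ]
    lines += [f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}" for v in mesh.vertices]
    lines.append(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}")
    lines += [f"3 {f[0]} {f[1]} {f[2]}" for f in mesh.faces]
    path.write_text("\n".join(lines) + "\n")
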