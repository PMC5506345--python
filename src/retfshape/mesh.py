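"""Triangulated surface container and plain-text mesh I/O.

Surfaces are stored in millimetres in a right-handed frame with the enface
plane spanned by x (temporal->nasal) and y (inferior->superior) and z axial
(anterior up).  Per-vertex scalar channels (e.g. ``thickness_mm``) ride on
the mesh and are carried through cropping and file round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh


@dataclass
class TriSurface:
    """A triangulated surface with optional named per-vertex scalar channels."""

    vertices: np.ndarray  # (n, 3) float, mm
    faces: np.ndarray  # (m, 3) int
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        for name, values in list(self.channels.items()):
            values = np.asarray(values, dtype=float).ravel()
            if values.shape[0] != self.n_vertices:
                raise ValueError(
                    f"channel {name!r} has {values.shape[0]} values for "
                    f"{self.n_vertices} vertices"
                )
            self.channels[name] = values

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def copy(self) -> "TriSurface":
        return TriSurface(
            self.vertices.copy(),
            self.faces.copy(),
            {k: v.copy() for k, v in self.channels.items()},
        )

    # -- derived face quantities -------------------------------------------

    def face_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        f = self.faces
        return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]

    def face_centers(self) -> np.ndarray:
        a, b, c = self.face_corners()
        return (a + b + c) / 3.0

    def face_raw_normals(self) -> np.ndarray:
        """Cross-product normals with length 2*area (unnormalized)."""
        a, b, c = self.face_corners()
        return np.cross(b - a, c - a)

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_raw_normals(), axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of each incident face area."""
        areas = self.face_areas()
        out = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(out, self.faces[:, k], areas / 3.0)
        return out

    def vertex_normals(self) -> np.ndarray:
        raw = self.face_raw_normals()
        out = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(out, self.faces[:, k], raw)
        norms = np.linalg.norm(out, axis=1)
        norms[norms == 0] = 1.0
        return out / norms[:, None]

    def validate(self, min_area: float = 1e-12) -> None:
        """Raise if the mesh has out-of-range indices or degenerate faces."""
        if self.n_faces and (self.faces.min() < 0 or self.faces.max() >= self.n_vertices):
            raise ValueError("face indices out of range")
        if np.any(self.face_areas() <= min_area):
            raise ValueError("degenerate (zero-area) faces present")

    def is_consistently_oriented(self) -> bool:
        m = trimesh.Trimesh(self.vertices, self.faces, process=False)
        return bool(m.is_winding_consistent)

    def transform(self, matrix: np.ndarray) -> "TriSurface":
        """Apply a 4x4 homogeneous transform; flips winding if det < 0."""
        matrix = np.asarray(matrix, dtype=float)
        v = self.vertices @ matrix[:3, :3].T + matrix[:3, 3]
        f = self.faces.copy()
        if np.linalg.det(matrix[:3, :3]) < 0:
            f = f[:, ::-1]
        return TriSurface(v, f, {k: c.copy() for k, c in self.channels.items()})


# -- file formats -----------------------------------------------------------


def save_surface(surface: TriSurface, path) -> None:
    """Write a surface as ASCII PLY or legacy-ASCII VTK polydata by extension."""
    path = str(path)
    if path.endswith(".ply"):
        _save_ply(surface, path)
    elif path.endswith(".vtk"):
        _save_vtk(surface, path)
    else:
        raise ValueError(f"unsupported mesh extension: {path}")


def load_surface(path) -> TriSurface:
    path = str(path)
    if path.endswith(".ply"):
        return _load_ply(path)
    if path.endswith(".vtk"):
        return _load_vtk(path)
    raise ValueError(f"unsupported mesh extension: {path}")


def _save_ply(surface: TriSurface, path: str) -> None:
    mesh = trimesh.Trimesh(surface.vertices, surface.faces, process=False)
    for name, values in surface.channels.items():
        mesh.vertex_attributes[name] = values
    mesh.export(path, encoding="ascii")


def _load_ply(path: str) -> TriSurface:
    mesh = trimesh.load(path, process=False, force="mesh")
    channels = {
        name: np.asarray(vals, dtype=float)
        for name, vals in mesh.vertex_attributes.items()
        if np.ndim(vals) == 1
    }
    # trimesh keeps non-geometric vertex properties in the raw PLY metadata
    raw = mesh.metadata.get("_ply_raw", {}).get("vertex", {}).get("data", {})
    for name, vals in raw.items():
        if name in ("x", "y", "z") or name in channels:
            continue
        arr = np.asarray(vals, dtype=float).ravel()
        if arr.shape[0] == mesh.vertices.shape[0]:
            channels[name] = arr
    return TriSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces), channels)


def _save_vtk(surface: TriSurface, path: str) -> None:
    # legacy ASCII polydata; small and self-describing, viewable in ParaView
    lines = [
        "# vtk DataFile Version 3.0",
        "retfshape surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {surface.n_vertices} double",
    ]
    lines += [" ".join(f"{x:.12g}" for x in row) for row in surface.vertices]
    lines.append(f"POLYGONS {surface.n_faces} {4 * surface.n_faces}")
    lines += ["3 " + " ".join(str(i) for i in row) for row in surface.faces]
    if surface.channels:
        lines.append(f"POINT_DATA {surface.n_vertices}")
        for name, values in surface.channels.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [f"{v:.12g}" for v in values]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _load_vtk(path: str) -> TriSurface:
    with open(path) as fh:
        tokens = fh.read().split()
    it = iter(range(len(tokens)))

    def find(word: str, start: int = 0) -> int:
        for i in range(start, len(tokens)):
            if tokens[i] == word:
                return i
        raise ValueError(f"{word} section not found in {path}")

    ip = find("POINTS")
    n = int(tokens[ip + 1])
    coords = np.array(tokens[ip + 3 : ip + 3 + 3 * n], dtype=float).reshape(n, 3)
    ig = find("POLYGONS")
    m = int(tokens[ig + 1])
    face_block = np.array(tokens[ig + 3 : ig + 3 + 4 * m], dtype=np.int64).reshape(m, 4)
    if not np.all(face_block[:, 0] == 3):
        raise ValueError("non-triangular polygons in VTK file")
    channels: dict[str, np.ndarray] = {}
    try:
        ipd = find("POINT_DATA")
    except ValueError:
        ipd = None
    if ipd is not None:
        i = ipd + 2
        while i < len(tokens):
            if tokens[i] != "SCALARS":
                break
            name = tokens[i + 1]
            i += 4  # SCALARS name type 1 / LOOKUP_TABLE default
            i += 2
            channels[name] = np.array(tokens[i : i + n], dtype=float)
            i += n
    return TriSurface(coords, face_block[:, 1:], channels)
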