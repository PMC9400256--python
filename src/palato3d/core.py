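"""Mesh / landmark / voxel-grid data model, standard-format I/O and geometric primitives.

Conventions used throughout the package:

* all coordinates and spacings are millimetres;
* triangle meshes are :class:`trimesh.Trimesh` objects (``process=False`` so the
  package controls welding explicitly);
* voxel grids map array index ``(i, j, k)`` (axes ordered x, y, z) to world
  coordinates via ``index * spacing + origin``;
* face winding defines orientation; closed meshes are oriented so the signed
  volume is positive (outward normals).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import (
    DegenerateConfigurationError,
    EmptyMeshError,
    MeshFormatError,
    ValidationError,
)

#: welding tolerance for duplicate vertices on read (STL carries no connectivity)
WELD_TOL = 1e-6

#: Table-1 style internal ROI boundary landmark names, anterior -> posterior
BOUNDARY_LANDMARKS = (
    "mesial_first_premolar",
    "palatal_cusp_second_premolar",
    "distal_fissure_first_molar",
    "distal_fissure_second_molar",
)

TriangleMesh = trimesh.Trimesh


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation + translation, no scale)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValidationError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValidationError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def to_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    # angular magnitude of the rotation, degrees
    def rotation_angle_deg(self) -> float:
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_json(self, path) -> None:
        payload = {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.array(payload["rotation"]), np.array(payload["translation"]))


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------


@dataclass
class Landmark:
    name: str
    side: str  # "L" | "R" | "mid"
    xyz: np.ndarray

    def __post_init__(self):
        if self.side not in ("L", "R", "mid"):
            raise ValidationError(f"landmark side must be L/R/mid, got {self.side!r}")
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(3)


@dataclass
class LandmarkSet:
    """Ordered collection of named anatomical points.

    Naming scheme: ``sulcus`` (ordered curve samples per side),
    the four Table-1 style boundary landmarks (:data:`BOUNDARY_LANDMARKS`),
    ``posterior_border`` samples, ``incisal_midpoint`` and ``tooth_seed`` points.
    """

    points: list = field(default_factory=list)

    def add(self, name: str, side: str, xyz) -> None:
        self.points.append(Landmark(name, side, xyz))

    def by_name(self, name: str, side: str | None = None) -> np.ndarray:
        """All points with this name (file order preserved), shape (n, 3)."""
        sel = [
            p.xyz
            for p in self.points
            if p.name == name and (side is None or p.side == side)
        ]
        return np.array(sel).reshape(-1, 3)

    def get(self, name: str, side: str) -> np.ndarray:
        pts = self.by_name(name, side)
        if len(pts) == 0:
            raise KeyError(f"landmark {name!r} side {side!r} not present")
        return pts[0]

    def sulcus_curve(self, side: str) -> np.ndarray:
        return self.by_name("sulcus", side)

    def names(self) -> set:
        return {p.name for p in self.points}

    def validate(self) -> None:
        for name in BOUNDARY_LANDMARKS:
            for side in ("L", "R", "mid"):
                if len(self.by_name(name, side)) > 1:
                    raise ValidationError(
                        f"boundary landmark {name!r} appears more than once on side {side}"
                    )
        for side in ("L", "R"):
            n = len(self.sulcus_curve(side))
            if 0 < n < 4:
                raise ValidationError(
                    f"sulcus curve needs >= 4 samples per side, got {n} on {side}"
                )

    def transform(self, T: RigidTransform) -> "LandmarkSet":
        out = LandmarkSet()
        for p in self.points:
            out.add(p.name, p.side, T.apply(p.xyz))
        return out

    # -- JSON schema: {"points": [{"name": str, "side": "L"|"R"|"mid", "xyz": [x,y,z]}]}
    def to_json(self, path) -> None:
        payload = {
            "points": [
                {"name": p.name, "side": p.side, "xyz": p.xyz.tolist()}
                for p in self.points
            ]
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LandmarkSet":
        with open(path) as fh:
            payload = json.load(fh)
        out = cls()
        for p in payload["points"]:
            out.add(p["name"], p["side"], p["xyz"])
        out.validate()
        return out


# ---------------------------------------------------------------------------
# voxel grid
# ---------------------------------------------------------------------------


@dataclass
class VoxelGrid:
    """Scalar field (Hounsfield units or binary mask) on a regular grid.

    ``data[i, j, k]`` lives at world position ``(i, j, k) * spacing + origin``;
    array axes are ordered (x, y, z).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValidationError("voxel grid must be a non-empty 3D array")
        if np.any(self.spacing <= 0):
            raise ValidationError("voxel spacing must be strictly positive")

    def to_nifti(self, path) -> None:
        import nibabel as nib

        affine = np.diag(np.append(self.spacing, 1.0))
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "VoxelGrid":
        import nibabel as nib

        img = nib.load(str(path))
        affine = img.affine
        spacing = np.linalg.norm(affine[:3, :3], axis=0)
        return cls(np.asarray(img.get_fdata()), spacing, affine[:3, 3])

    def to_npy(self, path_npy, path_json) -> None:
        np.save(path_npy, self.data)
        with open(path_json, "w") as fh:
            json.dump({"spacing": self.spacing.tolist(), "origin": self.origin.tolist()}, fh)

    @classmethod
    def from_npy(cls, path_npy, path_json) -> "VoxelGrid":
        with open(path_json) as fh:
            meta = json.load(fh)
        return cls(np.load(path_npy), meta["spacing"], meta["origin"])


# ---------------------------------------------------------------------------
# mesh construction / IO
# ---------------------------------------------------------------------------


def weld_vertices(vertices, faces, tol: float = WELD_TOL):
    """Merge duplicate vertices within ``tol`` and drop degenerate faces."""
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    # keep the first-seen coordinates for determinism
    new_vertices = vertices[np.sort(first)]
    order = np.argsort(first)
    remap = np.empty(len(first), dtype=np.int64)
    remap[order] = np.arange(len(first))
    new_faces = remap[inverse][faces]
    new_faces = new_faces[_nondegenerate_mask(new_vertices, new_faces)]
    return new_vertices, new_faces


def _nondegenerate_mask(vertices, faces, area_eps: float = 1e-12):
    if len(faces) == 0:
        return np.zeros(0, dtype=bool)
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    tri = vertices[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    return distinct & (areas > area_eps)


def mesh_from_arrays(vertices, faces, weld: bool = True, tol: float = WELD_TOL) -> TriangleMesh:
    """Build a TriangleMesh enforcing the package invariants."""
    if weld:
        vertices, faces = weld_vertices(vertices, faces, tol)
    else:
        vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
        faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
        faces = faces[_nondegenerate_mask(vertices, faces)]
    if len(vertices) == 0 or len(faces) == 0:
        raise EmptyMeshError("mesh has no vertices or faces after cleanup")
    if faces.min() < 0 or faces.max() >= len(vertices):
        raise ValidationError("face indices out of range")
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def orient_outward(mesh: TriangleMesh) -> TriangleMesh:
    """Flip winding so that a closed mesh encloses positive signed volume."""
    if mesh.is_watertight and mesh.volume < 0:
        mesh = trimesh.Trimesh(
            vertices=mesh.vertices.copy(), faces=mesh.faces[:, ::-1].copy(), process=False
        )
    return mesh


def read_mesh(path, fmt: str | None = None) -> TriangleMesh:
    """Read an STL or PLY mesh, weld duplicate vertices and validate invariants.

    Per-vertex RGB colours (PLY) are preserved. Raises
    :class:`~palato3d.errors.MeshFormatError` on unparseable input and
    :class:`~palato3d.errors.EmptyMeshError` on empty meshes.
    """
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    if fmt not in ("stl", "ply"):
        raise MeshFormatError(path, 0, f"unsupported format {fmt!r}")
    try:
        loaded = trimesh.load(path, file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - report as a format error
        raise MeshFormatError(path, 0, str(exc)) from exc
    if loaded is None or loaded.is_empty or len(loaded.faces) == 0:
        raise EmptyMeshError(f"{path}: empty mesh")
    vertices = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    colors = None
    if fmt == "ply" and loaded.visual.kind == "vertex":
        colors = np.asarray(loaded.visual.vertex_colors).copy()
    new_vertices, new_faces = weld_vertices(vertices, faces)
    if len(new_faces) == 0:
        raise EmptyMeshError(f"{path}: no non-degenerate faces after welding")
    mesh = trimesh.Trimesh(vertices=new_vertices, faces=new_faces, process=False)
    if colors is not None and len(new_vertices) == len(vertices):
        mesh.visual.vertex_colors = colors
    elif colors is not None:
        # map colours through the weld (first occurrence wins)
        keys = np.round(vertices / WELD_TOL).astype(np.int64)
        _, first = np.unique(keys, axis=0, return_index=True)
        mesh.visual.vertex_colors = colors[np.sort(first)]
    return mesh


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None, ascii: bool = False) -> None:
    """Write STL (binary/ASCII) or PLY (binary little-endian / ASCII)."""
    path = str(path)
    if fmt is None:
        fmt = path.rsplit(".", 1)[-1].lower()
    if fmt == "stl":
        data = trimesh.exchange.stl.export_stl_ascii(mesh) if ascii else trimesh.exchange.stl.export_stl(mesh)
    elif fmt == "ply":
        data = trimesh.exchange.ply.export_ply(
            mesh, encoding="ascii" if ascii else "binary_little_endian"
        )
    else:
        raise ValidationError(f"unsupported mesh format {fmt!r}")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


# ---------------------------------------------------------------------------
# geometric primitives
# ---------------------------------------------------------------------------


def surface_area(mesh: TriangleMesh, face_subset=None) -> float:
    """Sum of triangle areas (mm^2) over ``face_subset`` (all faces when None)."""
    areas = mesh.area_faces
    if face_subset is None:
        return float(areas.sum())
    face_subset = np.asarray(face_subset)
    if face_subset.dtype == bool:
        face_subset = np.flatnonzero(face_subset)
    if len(face_subset) == 0:
        warnings.warn("surface_area: empty face subset", stacklevel=2)
        return 0.0
    return float(areas[face_subset].sum())


def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Area-weighted per-vertex unit normals.

    Isolated vertices receive a zero vector (flagged for downstream exclusion).
    """
    faces = mesh.faces
    tri = mesh.vertices.view(np.ndarray)[faces]
    face_n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # 2*area weighted
    acc = np.zeros_like(mesh.vertices, dtype=float)
    for k in range(3):
        np.add.at(acc, faces[:, k], face_n)
    norm = np.linalg.norm(acc, axis=1)
    ok = norm > 1e-20
    acc[ok] /= norm[ok, None]
    acc[~ok] = 0.0
    return acc


def fit_plane(points: np.ndarray):
    """Least-squares plane through points: returns (centroid, unit normal)."""
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise DegenerateConfigurationError("need >= 3 points to fit a plane")
    c = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - c)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateConfigurationError("points are collinear; plane undefined")
    return c, vt[2]
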