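"""Surface-to-surface deviation analysis: distance field, ROI summaries, volume.

The gingival (actual) mesh is compared against the bone (reference) mesh in a
common frame. Every gingival vertex is matched to its nearest point on the
bone surface; the distance is signed by the bone's outward normal at the foot
point (positive = gingiva outside the bone, i.e. soft tissue present).
Correspondences farther than ``max_distance`` or hitting the reference at a
grazing angle above ``max_angle`` are invalid and excluded from every summary.

Per-ROI soft-tissue volume integrates a frustum per valid gingival face:
``V = d_mean/3 * (A_top + A_bot + sqrt(A_top*A_bot))`` where ``A_top`` is the
gingival face area and ``A_bot`` the area of the triangle of its three foot
points on the bone. This is exact for parallel plates and for conical frusta
(e.g. concentric spherical shells) and needs no closed solid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TriangleMesh, surface_area
from .errors import EmptyMeshError
from .proximity import MeshProximity
from .roi import ROI_NAMES, RoiLabels

REPORT_COLUMNS = ["roi", "area_mm2", "mean_mm", "min_mm", "max_mm", "vol_mm3", "ratio_mm"]


@dataclass
class DistanceField:
    """Per-vertex signed distance from the actual to the reference surface."""

    distances: np.ndarray  # signed, mm
    valid: np.ndarray  # bool
    foot_points: np.ndarray  # (n, 3) nearest points on the reference
    angles_deg: np.ndarray  # incidence angle vs the foot normal

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class RoiRow:
    """One Table-row of the deviation report (all fields may be NaN when empty)."""

    area_mm2: float = np.nan
    mean_mm: float = np.nan
    min_mm: float = np.nan
    max_mm: float = np.nan
    vol_mm3: float = np.nan
    ratio_mm: float = np.nan


@dataclass
class RoiReport:
    """Per-ROI (1-5) and total deviation quantities."""

    rows: dict = field(default_factory=dict)  # keys: "ROI1".."ROI5", "total"

    def row(self, key: str) -> RoiRow:
        return self.rows.setdefault(key, RoiRow())

    def to_frame(self) -> pd.DataFrame:
        records = []
        for key in (*ROI_NAMES, "total"):
            r = self.rows.get(key, RoiRow())
            records.append(
                {
                    "roi": key,
                    "area_mm2": r.area_mm2,
                    "mean_mm": r.mean_mm,
                    "min_mm": r.min_mm,
                    "max_mm": r.max_mm,
                    "vol_mm3": r.vol_mm3,
                    "ratio_mm": r.ratio_mm,
                }
            )
        return pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)

    def to_csv(self, path) -> None:
        # fixed float formatting keeps identical runs byte-identical
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    def to_json(self, path) -> None:
        payload = {
            key: {
                k: (None if np.isnan(v) else float(v))
                for k, v in vars(r).items()
            }
            for key, r in self.rows.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @staticmethod
    def merge(distance_part: "RoiReport", volume_part: "RoiReport") -> "RoiReport":
        out = RoiReport()
        for key in set(distance_part.rows) | set(volume_part.rows):
            r = RoiRow()
            for src in (distance_part.rows.get(key), volume_part.rows.get(key)):
                if src is None:
                    continue
                for name, val in vars(src).items():
                    if not np.isnan(val):
                        setattr(r, name, val)
            out.rows[key] = r
        return out


def compute_distance_field(
    actual: TriangleMesh,
    reference: TriangleMesh,
    max_distance: float = 15.0,
    max_angle: float = 60.0,
) -> DistanceField:
    """Signed nearest-surface distance from each actual-mesh vertex to the reference."""
    if len(reference.faces) == 0:
        raise EmptyMeshError("reference mesh is empty")
    prox = MeshProximity(reference)
    pts = actual.vertices.view(np.ndarray)
    foot, dist, faces = prox.query(pts)
    seg = pts - foot
    normals = prox.face_normals[faces]
    dots = np.einsum("ij,ij->i", seg, normals)
    sign = np.where(dots < 0, -1.0, 1.0)
    signed = sign * dist
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(dots) / np.maximum(dist, 1e-12)
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    angles[dist < 1e-9] = 0.0  # coincident points hit at normal incidence
    valid = (dist <= max_distance) & (angles <= max_angle)
    if not valid.any():
        warnings.warn("distance field: every correspondence was rejected", stacklevel=2)
    return DistanceField(signed, valid, foot, angles)


def _roi_face_sets(labels: RoiLabels):
    sets = {name: labels.faces_of(i + 1) for i, name in enumerate(ROI_NAMES)}
    sets["total"] = np.flatnonzero(labels.included)
    return sets


def summarize_roi(field: DistanceField, labels: RoiLabels, mesh: TriangleMesh) -> RoiReport:
    """Distance part of the report: valid area, area-weighted mean, min, max.

    A face is valid when all three vertices are valid; the vertex weight is one
    third of its incident valid-face area (invariant to mesh refinement).
    MinDist/MaxDist are extrema over valid vertices of the ROI's faces. ROIs
    with no valid vertex report NaN (missing), not zero.
    """
    report = RoiReport()
    faces = mesh.faces
    areas = mesh.area_faces
    face_valid = field.valid[faces].all(axis=1)
    for key, fset in _roi_face_sets(labels).items():
        row = report.row(key)
        if len(fset) == 0:
            continue
        fv = fset[face_valid[fset]]
        row.area_mm2 = float(areas[fv].sum()) if len(fv) else 0.0
        if len(fv) == 0:
            continue
        # area-weighted vertex mean over valid faces
        w = np.repeat(areas[fv] / 3.0, 3)
        d = field.distances[faces[fv].ravel()]
        row.mean_mm = float(np.sum(w * d) / np.sum(w))
        vids = np.unique(faces[fv].ravel())
        vd = field.distances[vids[field.valid[vids]]]
        row.min_mm = float(vd.min())
        row.max_mm = float(vd.max())
    return report


def compute_volume(field: DistanceField, labels: RoiLabels, mesh: TriangleMesh) -> RoiReport:
    """Volume part of the report: per-ROI frustum-integrated soft-tissue volume.

    Negative distances (gingiva below bone, e.g. registration noise) are
    clipped to zero for the volume (tissue volume is non-negative) but kept in
    the distance summaries; the clip count is reported via a warning.
    """
    report = RoiReport()
    faces = mesh.faces
    areas = mesh.area_faces
    face_valid = field.valid[faces].all(axis=1)
    d = field.distances
    n_clipped = int(np.sum((d < 0) & field.valid))
    if n_clipped:
        warnings.warn(
            f"compute_volume: clipped {n_clipped} negative distances to 0", stacklevel=2
        )
    d = np.maximum(d, 0.0)
    verts = mesh.vertices.view(np.ndarray)
    foot_tri = field.foot_points[faces]
    top_cross = np.cross(
        verts[faces[:, 1]] - verts[faces[:, 0]], verts[faces[:, 2]] - verts[faces[:, 0]]
    )
    bot_cross = np.cross(
        foot_tri[:, 1] - foot_tri[:, 0], foot_tri[:, 2] - foot_tri[:, 0]
    )
    # sweep direction per face: mean vertex->foot segment (fallback: top normal);
    # each frustum face is projected onto the plane orthogonal to the sweep so
    # tilted faces (thickness gradients, roughness) do not inflate the volume
    seg = (verts[faces] - foot_tri).mean(axis=1)
    seg_norm = np.linalg.norm(seg, axis=1)
    top_norm = np.linalg.norm(top_cross, axis=1)
    sweep = np.where(
        (seg_norm > 1e-9)[:, None],
        seg / np.maximum(seg_norm, 1e-30)[:, None],
        top_cross / np.maximum(top_norm, 1e-30)[:, None],
    )
    a_top_all = 0.5 * np.abs(np.einsum("ij,ij->i", top_cross, sweep))
    a_bot_all = 0.5 * np.abs(np.einsum("ij,ij->i", bot_cross, sweep))
    d_face = d[faces].mean(axis=1)
    for key, fset in _roi_face_sets(labels).items():
        row = report.row(key)
        if len(fset) == 0:
            continue
        fv = fset[face_valid[fset]]
        row.area_mm2 = float(areas[fv].sum()) if len(fv) else 0.0
        if len(fv) == 0 or row.area_mm2 == 0.0:
            continue
        a_top = a_top_all[fv]
        a_bot = a_bot_all[fv]
        # degenerate foot triangles fall back to a straight prism
        a_bot = np.where(a_bot > 1e-12, a_bot, a_top)
        vol = np.sum(d_face[fv] / 3.0 * (a_top + a_bot + np.sqrt(a_top * a_bot)))
        row.vol_mm3 = float(vol)
        row.ratio_mm = float(vol / row.area_mm2)
    return report


def roi_report(field: DistanceField, labels: RoiLabels, mesh: TriangleMesh) -> RoiReport:
    """Full Table-style report: distances + volumes + ratio per ROI and total."""
    return RoiReport.merge(
        summarize_roi(field, labels, mesh), compute_volume(field, labels, mesh)
    )


# ---------------------------------------------------------------------------
# colour-coded distance map
# ---------------------------------------------------------------------------

#: colour ramp anchors at fractions of scale_max
_RAMP = np.array(
    [
        (0.0, 0, 170, 0),  # green: contacting surfaces
        (1 / 3, 255, 255, 0),  # yellow
        (2 / 3, 255, 0, 0),  # red
        (1.0, 139, 0, 0),  # dark red: large separation
    ]
)

GREY = np.array([128, 128, 128, 255], dtype=np.uint8)


def distance_ramp(values: np.ndarray, scale_max: float) -> np.ndarray:
    """RGBA colours for distances on the green->yellow->red->dark-red ramp."""
    f = np.clip(np.asarray(values, dtype=float) / scale_max, 0.0, 1.0)
    rgb = np.empty((len(f), 3))
    for c in range(3):
        rgb[:, c] = np.interp(f, _RAMP[:, 0], _RAMP[:, c + 1])
    out = np.empty((len(f), 4), dtype=np.uint8)
    out[:, :3] = np.rint(rgb).astype(np.uint8)
    out[:, 3] = 255
    return out


def export_distance_map(
    field: DistanceField, mesh: TriangleMesh, scale_max: float, path=None
) -> TriangleMesh:
    """Colour the mesh by distance (invalid vertices grey) and optionally write a PLY."""
    if scale_max <= 0:
        raise ValueError("scale_max must be > 0")
    colors = distance_ramp(np.maximum(field.distances, 0.0), scale_max)
    colors[~field.valid] = GREY
    import trimesh

    out = trimesh.Trimesh(
        vertices=mesh.vertices.copy(), faces=mesh.faces.copy(), process=False
    )
    out.visual.vertex_colors = colors
    if path is not None:
        from .core import write_mesh

        write_mesh(out, path, fmt="ply")
    return out
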