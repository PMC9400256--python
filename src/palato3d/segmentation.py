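"""Bone segmentation: HU window thresholding, iso-surfacing and hole closing.

Converts a Hounsfield-unit voxel grid into a bone-surface triangle mesh the
way CBCT planning software does: keep voxels inside a bone window (default
150–2000 HU, which also suppresses metal), extract the 0.5 iso-surface of the
binary mask with marching cubes, and close small boundary holes automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .core import TriangleMesh, VoxelGrid, mesh_from_arrays, orient_outward
from .errors import EmptySegmentationError, ValidationError


@dataclass
class SegmentationParams:
    """Bone-window segmentation parameters.

    hu_low/hu_high : Hounsfield window; a voxel is foreground iff
        ``hu_low <= HU <= hu_high``.
    min_component_voxels : connected components smaller than this are removed.
    keep_largest : keep only the largest connected component (the maxilla is a
        single structure).
    max_hole_boundary_edges : boundary loops with at most this many edges are
        closed automatically; larger holes are reported and left open.
    decimation_fraction : optional target fraction of faces after decimation
        (None = no decimation).
    """

    hu_low: float = 150.0
    hu_high: float = 2000.0
    min_component_voxels: int = 27
    keep_largest: bool = True
    max_hole_boundary_edges: int = 100
    decimation_fraction: float | None = None

    def __post_init__(self):
        if not (np.isfinite(self.hu_low) and np.isfinite(self.hu_high)):
            raise ValidationError("HU thresholds must be finite")
        if self.hu_low >= self.hu_high:
            raise ValidationError("hu_low must be < hu_high")
        if self.max_hole_boundary_edges < 3:
            raise ValidationError("hole boundary-edge limit must be >= 3")


def threshold_mask(grid: VoxelGrid, params: SegmentationParams | None = None) -> VoxelGrid:
    """Binary foreground mask of the HU window, small components removed."""
    params = params or SegmentationParams()
    data = np.asarray(grid.data, dtype=float)
    mask = (data >= params.hu_low) & (data <= params.hu_high)
    if mask.any() and params.min_component_voxels > 1:
        labels, n = ndimage.label(mask)
        if n:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            keep = counts >= params.min_component_voxels
            if params.keep_largest and keep.any():
                keep = np.zeros_like(keep)
                keep[np.argmax(counts)] = True
            mask = keep[labels]
    if not mask.any():
        raise EmptySegmentationError(
            f"no voxels inside HU window [{params.hu_low}, {params.hu_high}] "
            "after component filtering"
        )
    return VoxelGrid(mask.astype(np.uint8), grid.spacing, grid.origin)


def extract_isosurface(mask: VoxelGrid) -> TriangleMesh:
    """Marching-cubes surface at the 0.5 level of a binary mask, in mm.

    The mask is padded with one background layer so one-voxel-thick slabs and
    boundary-touching foreground still produce a closed surface. Output is
    oriented outward (positive signed volume for closed components).
    """
    data = np.asarray(mask.data).astype(np.uint8)
    if not data.any():
        raise EmptySegmentationError("mask has no foreground voxels")
    padded = np.pad(data, 1)
    verts, faces, _, _ = measure.marching_cubes(
        padded.astype(float), level=0.5, spacing=tuple(mask.spacing)
    )
    verts = verts - mask.spacing + mask.origin  # undo padding offset
    mesh = mesh_from_arrays(verts, faces)
    return orient_outward(mesh)


def boundary_loops(mesh: TriangleMesh):
    """Closed boundary loops as ordered vertex lists.

    Boundary edges are edges used by exactly one face, traversed in the face's
    winding direction. Loops touching a non-manifold boundary vertex (more than
    one outgoing boundary edge) are skipped and reported.
    """
    edges = mesh.edges  # directed, per face winding
    edges_sorted = np.sort(edges, axis=1)
    _, inverse, counts = np.unique(
        edges_sorted, axis=0, return_inverse=True, return_counts=True
    )
    boundary = edges[counts[inverse] == 1]
    loops, skipped = [], 0
    nxt: dict[int, list[int]] = {}
    for a, b in boundary:
        nxt.setdefault(int(a), []).append(int(b))
    nonmanifold = {v for v, outs in nxt.items() if len(outs) > 1}
    visited = set()
    for a, b in boundary:
        a, b = int(a), int(b)
        if (a, b) in visited:
            continue
        loop = [a]
        cur, ok = b, True
        visited.add((a, b))
        while cur != a:
            if cur in nonmanifold or cur not in nxt:
                ok = False
                break
            loop.append(cur)
            new = nxt[cur][0]
            if (cur, new) in visited:
                ok = False
                break
            visited.add((cur, new))
            cur = new
        if ok and len(loop) >= 3:
            loops.append(loop)
        else:
            skipped += 1
    return loops, skipped


def close_small_holes(
    mesh: TriangleMesh, max_boundary_edges: int = 100
) -> tuple[TriangleMesh, dict]:
    """Triangulate every boundary loop with <= ``max_boundary_edges`` edges.

    Holes are filled with a deterministic fan from the loop centroid; existing
    vertices are never moved. Larger loops are left untouched and reported in
    the returned summary dict.
    """
    loops, nonmanifold_skipped = boundary_loops(mesh)
    vertices = mesh.vertices.view(np.ndarray).copy()
    faces = [mesh.faces.view(np.ndarray).copy()]
    closed = 0
    skipped_large = 0
    for loop in loops:
        if len(loop) > max_boundary_edges:
            skipped_large += 1
            continue
        centroid = vertices[loop].mean(axis=0)
        cidx = len(vertices)
        vertices = np.vstack([vertices, centroid])
        loop_arr = np.array(loop)
        # boundary edge a->b belongs to a face; the new triangles (b, a, c)
        # share each edge with opposite direction, keeping orientation coherent
        a = loop_arr
        b = np.roll(loop_arr, -1)
        faces.append(np.column_stack([b, a, np.full(len(loop), cidx)]))
        closed += 1
    out = mesh_from_arrays(vertices, np.vstack(faces), weld=False)
    report = {
        "holes_closed": closed,
        "holes_skipped_too_large": skipped_large,
        "holes_skipped_nonmanifold": nonmanifold_skipped,
    }
    if skipped_large or nonmanifold_skipped:
        warnings.warn(f"close_small_holes: skipped holes {report}", stacklevel=2)
    return out, report


def segment_volume(grid: VoxelGrid, params: SegmentationParams | None = None) -> TriangleMesh:
    """Full CBCT-style bone extraction: threshold -> iso-surface -> close holes."""
    params = params or SegmentationParams()
    mask = threshold_mask(grid, params)
    mesh = extract_isosurface(mask)
    mesh, _ = close_small_holes(mesh, params.max_hole_boundary_edges)
    if params.decimation_fraction is not None:
        target = max(4, int(len(mesh.faces) * params.decimation_fraction))
        mesh = mesh.simplify_quadric_decimation(face_count=target)
    return mesh
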