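"""Two-stage rigid superimposition of the gingival model onto the bone model.

Stage 1 (``coarse_align``) is a least-squares rigid fit of named landmark
pairs (the digital stand-in for a rough manual alignment). Stage 2
(``icp_best_fit``) is local best-fit ICP restricted to the tooth surfaces:
masked source points are matched to their nearest points on the target
surface, outlier pairs beyond 3x the median distance are rejected, and the
rigid update is re-solved from the original points each iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .core import LandmarkSet, RigidTransform, TriangleMesh
from .errors import DegenerateConfigurationError, NonConvergenceError, ValidationError
from .proximity import MeshProximity


@dataclass
class RegistrationResult:
    """Outcome of the ICP stage."""

    transform: RigidTransform
    rms: float
    iterations: int
    converged: bool
    residual_trace: list = field(default_factory=list)


def kabsch(source: np.ndarray, target: np.ndarray, weights=None) -> RigidTransform:
    """Least-squares rigid transform mapping source points onto target points."""
    P = np.asarray(source, dtype=float)
    Q = np.asarray(target, dtype=float)
    if weights is None:
        weights = np.ones(len(P))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    cp = (w[:, None] * P).sum(axis=0)
    cq = (w[:, None] * Q).sum(axis=0)
    H = (w[:, None] * (P - cp)).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cq - R @ cp)


def coarse_align(source_landmarks: LandmarkSet, target_landmarks: LandmarkSet) -> RigidTransform:
    """Rigid least-squares alignment of landmarks matched by (name, side).

    Raises :class:`DegenerateConfigurationError` with fewer than 3 matched
    pairs or a collinear configuration.
    """
    src_pts, tgt_pts = [], []
    tgt_index = {}
    for i, p in enumerate(target_landmarks.points):
        tgt_index.setdefault((p.name, p.side), []).append(i)
    used = {k: 0 for k in tgt_index}
    for p in source_landmarks.points:
        key = (p.name, p.side)
        if key in tgt_index and used[key] < len(tgt_index[key]):
            q = target_landmarks.points[tgt_index[key][used[key]]]
            used[key] += 1
            src_pts.append(p.xyz)
            tgt_pts.append(q.xyz)
    src_pts = np.array(src_pts).reshape(-1, 3)
    tgt_pts = np.array(tgt_pts).reshape(-1, 3)
    if len(src_pts) < 3:
        raise DegenerateConfigurationError(
            f"need >= 3 matched landmark pairs, got {len(src_pts)}"
        )
    centered = src_pts - src_pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateConfigurationError("matched landmarks are collinear")
    return kabsch(src_pts, tgt_pts)


def select_tooth_mask(mesh: TriangleMesh, seeds: LandmarkSet, radius: float) -> np.ndarray:
    """Face indices within geodesic ``radius`` (over the face-adjacency graph) of any seed.

    Seed faces are the faces nearest to each ``tooth_seed`` landmark; graph
    edge weights are centroid-to-centroid distances. ``radius=0`` returns
    exactly the seed-nearest faces.
    """
    seed_pts = seeds.by_name("tooth_seed")
    if len(seed_pts) == 0 and len(seeds.points):
        seed_pts = np.vstack([p.xyz for p in seeds.points]).reshape(-1, 3)
    if len(seed_pts) == 0:
        raise ValidationError("no seed points provided")
    prox = MeshProximity(mesh)
    _, _, seed_faces = prox.query(seed_pts)
    seed_faces = np.unique(seed_faces)

    adj = mesh.face_adjacency
    centroids = mesh.triangles_center
    w = np.linalg.norm(centroids[adj[:, 0]] - centroids[adj[:, 1]], axis=1)
    n = len(mesh.faces)
    graph = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([adj[:, 0], adj[:, 1]]),
                                  np.concatenate([adj[:, 1], adj[:, 0]]))),
        shape=(n, n),
    ).tocsr()
    dist = dijkstra(graph, directed=False, indices=seed_faces, limit=radius + 1e-12)
    reach = (dist <= radius).any(axis=0)
    mask = np.flatnonzero(reach)
    if len(mask) == 0:
        raise ValidationError("empty tooth mask; increase the radius")
    return mask


def icp_best_fit(
    source: TriangleMesh,
    target: TriangleMesh,
    mask: np.ndarray,
    init: RigidTransform | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    reject_ratio: float = 3.0,
    sample_cap: int = 2000,
    seed: int = 0,
) -> RegistrationResult:
    """Local best-fit ICP of masked source points onto the target surface.

    Iterates nearest-point-on-surface correspondence and a rigid update
    (re-solved from the original points, so the best-seen transform is always
    available); stops when the RMS point-to-surface residual changes by less
    than ``tol`` mm. Pairs farther than ``reject_ratio`` times the median
    distance are rejected each iteration.
    """
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    mask = np.asarray(mask)
    if mask.dtype == bool:
        mask = np.flatnonzero(mask)
    if len(mask) == 0:
        raise ValidationError("empty source mask")
    vidx = np.unique(source.faces[mask].ravel())
    pts = source.vertices.view(np.ndarray)[vidx]
    if len(pts) > sample_cap:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), sample_cap, replace=False)]

    prox = MeshProximity(target)
    T = init or RigidTransform.identity()
    best_T, best_rms = T, np.inf
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        moved = T.apply(pts)
        foot, dist, _ = prox.query(moved)
        med = np.median(dist)
        keep = dist <= reject_ratio * med if med > 0 else np.ones(len(dist), bool)
        if not keep.any():
            raise NonConvergenceError(
                f"ICP correspondence collapse at iteration {it} "
                f"(median distance {med:.3g} mm)"
            )
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        trace.append(rms)
        if rms < best_rms:
            best_rms, best_T = rms, T
        if rms < tol or (len(trace) > 1 and abs(trace[-2] - rms) < tol):
            converged = True
            break
        T = kabsch(pts[keep], foot[keep])
    return RegistrationResult(best_T, best_rms, it, converged, trace)


def register(
    source: TriangleMesh,
    target: TriangleMesh,
    source_landmarks: LandmarkSet,
    target_landmarks: LandmarkSet,
    tooth_radius: float = 5.0,
    tol: float = 1e-4,
    max_iter: int = 100,
    seed: int = 0,
) -> RegistrationResult:
    """Coarse landmark alignment followed by tooth-masked local best-fit ICP."""
    T0 = coarse_align(source_landmarks, target_landmarks)
    mask = select_tooth_mask(source, source_landmarks, tooth_radius)
    return icp_best_fit(source, target, mask, init=T0, tol=tol, max_iter=max_iter, seed=seed)
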