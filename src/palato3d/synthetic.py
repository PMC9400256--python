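"""Synthetic palate generator with analytically known ground truth.

Emulates the data the analysis consumes: a bony palate (parametric vault +
alveolar ridge + simplified tooth crowns) as a height-field mesh, a gingival
surface obtained by offsetting the bone along its normals by a smooth
soft-tissue thickness field, the corresponding anatomical landmarks, an
optional Hounsfield-unit voxel phantom, and per-patient cohorts.

The thickness field increases anterior -> posterior through configurable
per-region target means and dips toward the midline (lateral modulation).
Ground truth (per-region true mean thickness, area, volume) is obtained by
refined numerical integration of the realized thickness field over the exact
analysis region (paramarginal offset measured as surface distance from the
sulcus curve, posterior border, band boundaries), so pipeline outputs can
be checked against it without circularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .core import LandmarkSet, RigidTransform, TriangleMesh, VoxelGrid, mesh_from_arrays
from .errors import ValidationError

ROI_KEYS = ("ROI1", "ROI2", "ROI3", "ROI4", "ROI5", "total")


# ---------------------------------------------------------------------------
# specification
# ---------------------------------------------------------------------------


@dataclass
class PalateSpec:
    """Geometry and statistical parameters of one synthetic palate.

    All lengths in mm. ``roi_means`` are the target mean soft-tissue
    thicknesses of the five anterior->posterior bands; ``lateral_dip`` is the
    relative thickness reduction at the midline (midpalatal tissue is thinner
    than lateral tissue). ``patient_effect_sd`` is the sd of a multiplicative
    log-normal patient effect with mean 1; ``thickness_noise_sd`` is iid
    per-node noise on the thickness field (clipped so the field stays
    positive wherever the noise-free field is positive); ``vertex_noise_sd``
    is iid positional noise on gingival mesh vertices. The same seed always
    reproduces the same palate bit-exactly.
    """

    arch_width: float = 36.0
    arch_length: float = 40.0
    dome_height: float = 7.0
    resolution: float = 0.5
    roi_means: tuple = (1.9, 2.4, 2.7, 2.9, 4.0)
    lateral_dip: float = 0.15
    patient_effect_sd: float = 0.22
    thickness_noise_sd: float = 0.05
    vertex_noise_sd: float = 0.0
    paramarginal_offset: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if min(self.arch_width, self.arch_length, self.dome_height, self.resolution) <= 0:
            raise ValidationError("all lengths must be > 0")
        if len(self.roi_means) != 5:
            raise ValidationError("roi_means must have 5 entries")
        band = min(np.diff(self.band_edges))
        if self.resolution > band / 3.0:
            raise ValidationError(
                f"resolution {self.resolution} too coarse to host 5 ROIs "
                f"(narrowest band {band:.1f} mm)"
            )

    # --- derived geometry -------------------------------------------------
    @property
    def x_sulcus(self) -> float:
        return self.arch_width / 2.0

    @property
    def y_anterior(self) -> float:
        return 6.0

    @property
    def y_posterior(self) -> float:
        return self.y_anterior + self.arch_length

    @property
    def boundary_y(self) -> np.ndarray:
        """Anterior->posterior positions of the four internal band boundaries."""
        fr = np.array([0.2, 0.375, 0.625, 0.8375])
        return self.y_anterior + fr * self.arch_length

    @property
    def band_edges(self) -> np.ndarray:
        return np.concatenate(
            [[self.y_anterior + self.paramarginal_offset], self.boundary_y, [self.y_posterior]]
        )

    @property
    def domain(self):
        xmax = self.x_sulcus + 8.0
        ymax = self.y_posterior + 6.0
        return (-xmax, xmax), (0.0, ymax)

    @property
    def crowns(self):
        """(cx, cy, height, sx, sy) of each tooth crown bump."""
        xs = self.x_sulcus
        ya = self.y_anterior
        L = self.arch_length
        xc = xs + 4.5
        rows = []
        for cy_off in (0.075 * L, 0.25 * L, 0.375 * L, 0.5625 * L, 0.775 * L):
            for sgn in (-1.0, 1.0):
                rows.append((sgn * xc, ya + cy_off, 4.0, 2.2, 2.8))
        # central incisors, anterior of the sulcus
        for sgn in (-1.0, 1.0):
            rows.append((sgn * 4.0, ya - 4.5, 3.0, 2.0, 2.2))
        return rows

    @property
    def tooth_centers_y(self) -> np.ndarray:
        """y of the lateral tooth row (canine, P1, P2, M1, M2)."""
        L = self.arch_length
        return self.y_anterior + np.array([0.075, 0.25, 0.375, 0.5625, 0.775]) * L


# ---------------------------------------------------------------------------
# analytic bone surface
# ---------------------------------------------------------------------------


def _bone_z(spec: PalateSpec, x, y):
    """Height field of the bone surface and its first partial derivatives."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xv = spec.x_sulcus + 1.0
    z = np.zeros(np.broadcast(x, y).shape)
    zx = np.zeros_like(z)
    zy = np.zeros_like(z)
    # vault: smooth valley, zero value/slope at |x| = xv
    inside = np.abs(x) < xv
    arg = np.pi * x / (2.0 * xv)
    c = np.cos(np.where(inside, arg, np.pi / 2))
    z = z - spec.dome_height * c**2
    zx = zx + spec.dome_height * (np.pi / (2 * xv)) * np.where(
        inside, np.sin(2 * arg), 0.0
    )
    # alveolar ridge on both sides
    xr, hr, wr = spec.x_sulcus + 3.5, 3.0, 2.5
    for sgn in (-1.0, 1.0):
        g = hr * np.exp(-(((x - sgn * xr) / wr) ** 2))
        z = z + g
        zx = zx - g * 2 * (x - sgn * xr) / wr**2
    # tooth crowns
    for cx, cy, h, sx, sy in spec.crowns:
        g = h * np.exp(-(((x - cx) / sx) ** 2) - ((y - cy) / sy) ** 2)
        z = z + g
        zx = zx - g * 2 * (x - cx) / sx**2
        zy = zy - g * 2 * (y - cy) / sy**2
    return z, zx, zy


def _normals(zx, zy):
    s = np.sqrt(1.0 + zx**2 + zy**2)
    return -zx / s, -zy / s, 1.0 / s


# ---------------------------------------------------------------------------
# thickness field
# ---------------------------------------------------------------------------


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _profile(spec: PalateSpec, y, half_width: float = 1.5):
    """Smooth monotone anterior->posterior thickness profile through the band means."""
    y = np.asarray(y, dtype=float)
    m = np.asarray(spec.roi_means, dtype=float)
    out = np.full(y.shape, m[0])
    for k, b in enumerate(spec.boundary_y):
        out = out + (m[k + 1] - m[k]) * _smoothstep((y - b + half_width) / (2 * half_width))
    return out


def _lateral_raw(spec: PalateSpec, x):
    return 1.0 - spec.lateral_dip * np.exp(-((np.asarray(x, dtype=float) / 6.0) ** 2))


def _lateral_norm_const(spec: PalateSpec) -> float:
    """Normalize the lateral modulation to unit mean under the gingival area measure."""
    ymid = spec.y_anterior + spec.arch_length / 2.0
    # nominal inclusion half-width from bone arc length
    xf = np.arange(-spec.x_sulcus, spec.x_sulcus + 1e-9, 0.02)
    _, zx, _ = _bone_z(spec, xf, ymid)
    ds = np.sqrt(1.0 + zx**2) * 0.02
    arc_from_right = np.concatenate([[0.0], np.cumsum(ds[::-1])])[::-1][: len(xf)]
    inc = arc_from_right >= spec.paramarginal_offset
    arc_from_left = np.concatenate([[0.0], np.cumsum(ds)])[: len(xf)]
    inc &= arc_from_left >= spec.paramarginal_offset
    xin = xf[inc]
    raw = _lateral_raw(spec, xin)
    tbar = float(np.mean(spec.roi_means))
    c = float(np.average(raw, weights=np.sqrt(1.0 + zx[inc] ** 2)))
    for _ in range(2):
        t_hat = tbar * raw / c
        z, zx_i, zy_i = _bone_z(spec, xin, ymid)
        nx, ny_, nz = _normals(zx_i, zy_i)
        gx = xin + t_hat * nx
        gz = z + t_hat * nz
        dens = np.sqrt(np.gradient(gx, xin) ** 2 + np.gradient(gz, xin) ** 2)
        c = float(np.average(raw, weights=dens))
    return c


def _thickness_field(spec: PalateSpec, X, Y, f_patient: float, rng) -> np.ndarray:
    """Realized mucosal thickness on the node grid (before crown exclusion)."""
    c = _lateral_norm_const(spec)
    clean = _profile(spec, Y) * (_lateral_raw(spec, X) / c) * f_patient
    t = clean.copy()
    if spec.thickness_noise_sd > 0:
        noise = rng.normal(0.0, spec.thickness_noise_sd, size=clean.shape)
        floor = np.minimum(clean, 0.2)
        t = np.maximum(clean + noise, floor)
    return np.where(clean <= 0.0, 0.0, t)


def _curvature_cap(spec: PalateSpec, X, Y, beta: float = 1.0) -> np.ndarray:
    """Focal-distance bound on the normal offset (beta / kappa_plus).

    A normal offset by t folds through itself where t * kappa >= 1 for the
    largest principal curvature kappa bending toward the offset side. This is
    the analytic part of the construction-validity cap; `_reach_cap` tightens
    it with the two-sided medial-axis reach.
    """
    eps = 1e-4
    _, zx0, zy0 = _bone_z(spec, X, Y)
    _, zx1, _ = _bone_z(spec, X + eps, Y)
    _, zxy, zy1 = _bone_z(spec, X, Y + eps)
    zxx = (zx1 - zx0) / eps
    zyy = (zy1 - zy0) / eps
    zxy = (zxy - zx0) / eps
    s2 = 1.0 + zx0**2 + zy0**2
    E, F, G = 1.0 + zx0**2, zx0 * zy0, 1.0 + zy0**2
    rs = np.sqrt(s2)
    L, M, N = zxx / rs, zxy / rs, zyy / rs
    det = E * G - F**2
    H = (E * N - 2 * F * M + G * L) / (2 * det)
    K = (L * N - M**2) / det
    disc = np.sqrt(np.maximum(H**2 - K, 0.0))
    k_plus = np.maximum(H + disc, 0.0)
    with np.errstate(divide="ignore"):
        return np.where(k_plus > 1e-9, beta / np.maximum(k_plus, 1e-9), np.inf)


def _reach_cap(spec: PalateSpec, X, Y, t_request: np.ndarray, beta: float = 0.8) -> np.ndarray:
    """Thickness bound making the offset gingiva geometrically consistent.

    The generated "thickness" is only the true surface-to-surface distance of
    the generated geometry while the offset point's nearest bone point is its
    own construction foot. That holds up to the bone's normal reach: the
    distance to the medial axis, which accounts for both focal folding (sharp
    ridge flanks) and the opposite wall of a concavity (the ridge/vault
    groove). The reach is found per node by bisection of
    ``dist(b + t*n, bone) >= t - slack`` against a half-resolution bone
    sampling; the returned cap is beta * reach (beta = 0.8 keeps a margin for
    surface noise and discretisation).
    """
    from scipy.spatial import cKDTree

    res = spec.resolution / 2.0
    (x0, x1), (y0, y1) = spec.domain
    fx = np.arange(x0, x1 + 1e-9, res)
    fy = np.arange(y0, y1 + 1e-9, res)
    FX, FY = np.meshgrid(fx, fy, indexing="ij")
    fz, _, _ = _bone_z(spec, FX, FY)
    tree = cKDTree(np.column_stack([FX.ravel(), FY.ravel(), fz.ravel()]))

    z, zx, zy = _bone_z(spec, X, Y)
    nx_, ny_, nz_ = _normals(zx, zy)
    b = np.stack([X, Y, z], axis=-1).reshape(-1, 3)
    n = np.stack([nx_, ny_, nz_], axis=-1).reshape(-1, 3)
    t_req = np.asarray(t_request, dtype=float).reshape(-1)
    slack = res  # point-sampling resolution of the bone cloud

    # search window: no cap needed beyond t_req / beta; never beyond the focus
    hi = np.minimum(t_req / beta, _curvature_cap(spec, X, Y).reshape(-1))
    hi = np.maximum(hi, 0.0)
    lo = np.zeros_like(hi)
    pos = hi > 0
    d_hi = np.full_like(hi, np.inf)
    d_hi[pos] = tree.query(b[pos] + hi[pos, None] * n[pos])[0]
    ok = d_hi >= hi - slack
    lo[ok] = hi[ok]
    active = np.flatnonzero(pos & ~ok)
    for _ in range(22):
        if len(active) == 0:
            break
        mid = 0.5 * (lo[active] + hi[active])
        d = tree.query(b[active] + mid[:, None] * n[active])[0]
        good = d >= mid - slack
        lo[active[good]] = mid[good]
        hi[active[~good]] = mid[~good]
        active = active[hi[active] - lo[active] > 1e-3]
    return (beta * lo).reshape(np.shape(X))


def _lipschitz_erode(spec: PalateSpec, X, Y, t: np.ndarray, slope: float = 1.0) -> np.ndarray:
    """Bound the thickness gradient along the bone surface (|grad t| <= slope).

    The reach cap can leave near-vertical steps in the thickness field; real
    mucosa varies smoothly and the measurement model (nearest-surface
    distances, 60 deg incidence filter) presumes tissue walls well away from
    vertical. Computes the erosion t(b) <- min_b' (t(b') + slope * dist(b, b'))
    over the 8-neighbour grid graph with 3D (on-bone) edge lengths, iterated
    to a fixed point. Only ever lowers the field.
    """
    z, _, _ = _bone_z(spec, X, Y)
    P = np.stack([X, Y, z], axis=-1)
    out = np.asarray(t, dtype=float).copy()
    pairs = []
    for dx, dy in ((1, 0), (0, 1), (1, 1), (1, -1)):
        sa = (slice(dx, None), slice(dy, None) if dy >= 0 else slice(None, dy))
        sb = (slice(None, -dx) if dx else slice(None), slice(None, -dy) if dy > 0 else (slice(-dy, None) if dy < 0 else slice(None)))
        e = slope * np.linalg.norm(P[sa] - P[sb], axis=-1)
        pairs.append((sa, sb, e))
    for _ in range(64):
        prev = out.copy()
        for sa, sb, e in pairs:
            np.minimum(out[sa], out[sb] + e, out=out[sa])
            np.minimum(out[sb], out[sa] + e, out=out[sb])
        if np.array_equal(out, prev):
            break
    return out


def _crown_weight(spec: PalateSpec, X, Y, r0: float = 4.0, r1: float = 7.0):
    """0 on tooth crowns (no mucosal offset), smooth ramp to 1 beyond r1."""
    w = np.ones(np.broadcast(X, Y).shape)
    for cx, cy, _, _, _ in spec.crowns:
        d = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2)
        w = np.minimum(w, _smoothstep((d - r0) / (r1 - r0)))
    return w


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Exact per-region quantities of one generated palate.

    ``per_roi`` maps ROI1..ROI5 and "total" to dicts with keys
    area_mm2 (gingival surface area of the region), mean_mm (area-weighted
    mean thickness on the gingival measure), min_mm, max_mm, vol_mm3 (volume
    of the normal-swept tissue solid) and ratio_mm (= vol/area).
    """

    per_roi: dict
    per_vertex_thickness: np.ndarray
    landmarks: LandmarkSet
    f_patient: float
    mucosa_total_vol_mm3: float = np.nan  # full tissue solid, whole domain
    applied_transform: RigidTransform | None = None
    refine: int = 4


def _tri_linear(grid_x, grid_y, F, Xq, Yq):
    """Interpolate node values over the same diagonal triangle split as the mesh."""
    hx = grid_x[1] - grid_x[0]
    hy = grid_y[1] - grid_y[0]
    u = (np.asarray(Xq, dtype=float) - grid_x[0]) / hx
    v = (np.asarray(Yq, dtype=float) - grid_y[0]) / hy
    i = np.clip(np.floor(u).astype(int), 0, len(grid_x) - 2)
    j = np.clip(np.floor(v).astype(int), 0, len(grid_y) - 2)
    fu = u - i
    fv = v - j
    f00, f10 = F[i, j], F[i + 1, j]
    f01, f11 = F[i, j + 1], F[i + 1, j + 1]
    lower = fv <= fu  # triangle A = (00, 10, 11); else B = (00, 11, 01)
    return np.where(
        lower,
        f00 + (f10 - f00) * fu + (f11 - f10) * fv,
        f00 + (f11 - f01) * fu + (f01 - f00) * fv,
    )


def _mucosa_total_volume(spec: PalateSpec, grid_x, grid_y, t_nodes, refine: int = 2) -> float:
    """Volume of the whole tissue solid (entire domain), by refined integration."""
    h = spec.resolution / refine
    xf = np.arange(grid_x[0], grid_x[-1] + 1e-9, h)
    yf = np.arange(grid_y[0], grid_y[-1] + 1e-9, h)
    X, Y = np.meshgrid(xf, yf, indexing="ij")
    T = _tri_linear(grid_x, grid_y, t_nodes, X, Y)
    z, zx, zy = _bone_z(spec, X, Y)
    nx, ny_, nz = _normals(zx, zy)
    B = np.stack([X, Y, z], axis=-1)
    TN = T[..., None] * np.stack([nx, ny_, nz], axis=-1)

    nxf, nyf = len(xf), len(yf)
    idx = np.arange(nxf * nyf).reshape(nxf, nyf)
    tris = np.vstack([
        np.column_stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(), idx[1:, 1:].ravel()]),
        np.column_stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()]),
    ])
    P0 = B.reshape(-1, 3)[tris]
    P2 = (B + TN).reshape(-1, 3)[tris]
    tn_c = TN.reshape(-1, 3)[tris].mean(axis=1)

    def tri_cross(P):
        return np.cross(P[:, 1] - P[:, 0], P[:, 2] - P[:, 0]) / 2.0

    det0 = np.einsum("ij,ij->i", tri_cross(P0), tn_c)
    det1 = np.einsum("ij,ij->i", tri_cross((P0 + P2) / 2.0), tn_c)
    det2 = np.einsum("ij,ij->i", tri_cross(P2), tn_c)
    return float(np.sum((det0 + 4.0 * det1 + det2) / 6.0))


def _surface_distance_to_sulcus(S2, i_s_l, i_s_r, limit: float) -> np.ndarray:
    """Surface distance from the sulcus curve over the fine gingival grid.

    Multi-source Dijkstra restricted to the palatal slab between the two
    lateral sulcus columns, over a 16-way stencil (axis, diagonal and knight
    chords) so the graph metric's direction anisotropy stays below ~0.5%.
    The curve (anterior row, both lateral columns) lies exactly on grid
    nodes, which become zero-distance sources.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import dijkstra

    sub = S2[i_s_l : i_s_r + 1]
    nx, ny = sub.shape[:2]
    idx = np.arange(nx * ny).reshape(nx, ny)
    rows, cols, vals = [], [], []
    for di, dj in ((1, 0), (0, 1), (1, 1), (1, -1), (1, 2), (2, 1), (1, -2), (2, -1)):
        i0, i1 = slice(0, nx - di), slice(di, nx)
        if dj >= 0:
            j0, j1 = slice(0, ny - dj), slice(dj, ny)
        else:
            j0, j1 = slice(-dj, ny), slice(0, ny + dj)
        a = idx[i0, j0].ravel()
        b = idx[i1, j1].ravel()
        w = np.linalg.norm(sub[i1, j1].reshape(-1, 3) - sub[i0, j0].reshape(-1, 3), axis=1)
        rows.append(a)
        cols.append(b)
        vals.append(w)
    graph = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nx * ny, nx * ny),
    ).tocsr()
    seeds = np.unique(np.concatenate([idx[0, :], idx[-1, :], idx[:, 0]]))
    d = dijkstra(graph, directed=False, indices=seeds, min_only=True, limit=limit)
    out = np.full(S2.shape[:2], np.inf)
    out[i_s_l : i_s_r + 1] = d.reshape(nx, ny)
    return out


def _integrate_ground_truth(spec: PalateSpec, grid_x, grid_y, t_nodes, refine: int = 4):
    """Refined numerical integration of area/mean/volume over the exact region.

    The realized thickness is interpolated over the mesh's own triangle split;
    area and volume are accumulated over fine triangles so the piecewise-linear
    geometry the pipeline measures is integrated consistently. The region is
    the paramarginal offset measured as surface distance from the sulcus
    curve, clipped at the posterior border, and subdivided at the band
    boundary positions.
    """
    h = spec.resolution / refine
    xf = np.arange(grid_x[0], grid_x[-1] + 1e-9, h)
    yf = np.arange(spec.y_anterior, spec.y_posterior + 1e-9, h)
    X, Y = np.meshgrid(xf, yf, indexing="ij")
    T = _tri_linear(grid_x, grid_y, t_nodes, X, Y)
    z, zx, zy = _bone_z(spec, X, Y)
    nx, ny_, nz = _normals(zx, zy)
    B = np.stack([X, Y, z], axis=-1)
    TN = T[..., None] * np.stack([nx, ny_, nz], axis=-1)
    S2 = B + TN

    # inclusion: surface (geodesic) distance from the sulcus curve (anterior
    # row plus both lateral columns) must reach the paramarginal offset. The
    # distance field is computed on the fine gingival surface with a 16-way
    # grid stencil (axis, diagonal and knight chords), whose direction
    # anisotropy is a few tenths of a percent — far below the mesh-resolution
    # effects this ground truth is used to bound.
    off = spec.paramarginal_offset
    i_s_r = int(np.argmin(np.abs(xf - spec.x_sulcus)))
    i_s_l = int(np.argmin(np.abs(xf + spec.x_sulcus)))
    dist = _surface_distance_to_sulcus(S2, i_s_l, i_s_r, limit=off + 1.0)
    inside = (dist >= off) & (np.abs(X) < spec.x_sulcus)

    # fine triangles (same diagonal orientation as the mesh)
    nxf, nyf = len(xf), len(yf)
    idx = np.arange(nxf * nyf).reshape(nxf, nyf)
    v00 = idx[:-1, :-1].ravel()
    v10 = idx[1:, :-1].ravel()
    v01 = idx[:-1, 1:].ravel()
    v11 = idx[1:, 1:].ravel()
    tris = np.vstack([
        np.column_stack([v00, v10, v11]),
        np.column_stack([v00, v11, v01]),
    ])
    flat = lambda A: A.reshape(-1, A.shape[-1]) if A.ndim == 3 else A.ravel()  # noqa: E731
    P2 = flat(S2)[tris]  # gingiva corners, (ntri, 3, 3)
    P0 = flat(B)[tris]
    TNf = flat(TN)[tris]
    tn_c = TNf.mean(axis=1)
    t_c = T.ravel()[tris].mean(axis=1)

    def tri_cross(P):
        return np.cross(P[:, 1] - P[:, 0], P[:, 2] - P[:, 0]) / 2.0

    area2 = np.linalg.norm(tri_cross(P2), axis=1)
    # Simpson over the offset coordinate: the integrand is quadratic in s
    det0 = np.einsum("ij,ij->i", tri_cross(P0), tn_c)
    det1 = np.einsum("ij,ij->i", tri_cross((P0 + P2) / 2.0), tn_c)
    det2 = np.einsum("ij,ij->i", tri_cross(P2), tn_c)
    vol_tri = (det0 + 4.0 * det1 + det2) / 6.0

    inc_c = inside.ravel()[tris].mean(axis=1) > 0.5
    y_c = Y.ravel()[tris].mean(axis=1)

    edges = spec.band_edges.copy()
    edges[0] = spec.y_anterior  # the anterior limit comes from the arc condition
    per_roi = {}
    tot = dict(area=0.0, vol=0.0, wsum=0.0, tsum=0.0, tmin=np.inf, tmax=-np.inf)
    for k in range(5):
        sel = inc_c & (y_c >= edges[k]) & (y_c < edges[k + 1])
        a = float(area2[sel].sum())
        v = float(vol_tri[sel].sum())
        w = area2[sel]
        tsel = t_c[sel]
        mean = float(np.sum(w * tsel) / np.sum(w)) if a > 0 else np.nan
        tmin = float(tsel.min()) if tsel.size else np.nan
        tmax = float(tsel.max()) if tsel.size else np.nan
        per_roi[f"ROI{k + 1}"] = dict(
            area_mm2=a, mean_mm=mean, min_mm=tmin, max_mm=tmax, vol_mm3=v,
            ratio_mm=v / a if a > 0 else np.nan,
        )
        tot["area"] += a
        tot["vol"] += v
        tot["wsum"] += float(np.sum(w))
        tot["tsum"] += float(np.sum(w * tsel))
        tot["tmin"] = min(tot["tmin"], tmin)
        tot["tmax"] = max(tot["tmax"], tmax)
    per_roi["total"] = dict(
        area_mm2=tot["area"],
        mean_mm=tot["tsum"] / tot["wsum"] if tot["wsum"] > 0 else np.nan,
        min_mm=tot["tmin"],
        max_mm=tot["tmax"],
        vol_mm3=tot["vol"],
        ratio_mm=tot["vol"] / tot["area"] if tot["area"] > 0 else np.nan,
    )
    return per_roi


# ---------------------------------------------------------------------------
# palate generation
# ---------------------------------------------------------------------------


@dataclass
class PalateSample:
    """One synthetic patient: meshes, landmarks and ground truth."""

    patient_id: str
    bone: TriangleMesh
    gingiva: TriangleMesh
    landmarks: LandmarkSet
    ground_truth: GroundTruth
    grid_x: np.ndarray = None
    grid_y: np.ndarray = None
    spec: PalateSpec = None


def _grid_mesh(vertices_grid) -> TriangleMesh:
    """Triangulate an (nx, ny, 3) vertex grid; vertex id = ix*ny + iy.

    Cell (ix, iy) produces faces 2*c and 2*c+1 with c = ix*(ny-1) + iy:
    triangle A = (v00, v10, v11), triangle B = (v00, v11, v01), both wound so
    normals point toward +z for a height field.
    """
    nx, ny = vertices_grid.shape[:2]
    idx = np.arange(nx * ny).reshape(nx, ny)
    v00 = idx[:-1, :-1].ravel()
    v10 = idx[1:, :-1].ravel()
    v01 = idx[:-1, 1:].ravel()
    v11 = idx[1:, 1:].ravel()
    tri_a = np.column_stack([v00, v10, v11])
    tri_b = np.column_stack([v00, v11, v01])
    faces = np.empty((2 * len(tri_a), 3), dtype=np.int64)
    faces[0::2] = tri_a
    faces[1::2] = tri_b
    return mesh_from_arrays(vertices_grid.reshape(-1, 3), faces, weld=False)


def _build_landmarks(spec: PalateSpec, t_interp) -> LandmarkSet:
    """Landmarks in the generation frame (shared by bone and gingiva)."""
    lms = LandmarkSet()
    z_occ = 5.0  # common occlusal level for the boundary landmarks
    names = (
        "mesial_first_premolar",
        "palatal_cusp_second_premolar",
        "distal_fissure_first_molar",
        "distal_fissure_second_molar",
    )
    xc = spec.x_sulcus + 4.5
    for name, yb in zip(names, spec.boundary_y):
        for side, sgn in (("L", -1.0), ("R", 1.0)):
            lms.add(name, side, (sgn * xc, yb, z_occ))
    lms.add("incisal_midpoint", "mid", (0.0, spec.y_anterior - 4.5, z_occ))

    def on_gingiva(x, y):
        xa = np.atleast_1d(np.asarray(x, dtype=float))
        ya = np.atleast_1d(np.asarray(y, dtype=float))
        z, zx, zy = _bone_z(spec, xa, ya)
        nx, ny_, nz = _normals(zx, zy)
        t = t_interp(np.stack([xa, ya], axis=-1))
        return np.stack([xa + t * nx, ya + t * ny_, z + t * nz], axis=-1)

    # sulcus curves: anterior segment + lateral run, ordered per side; both
    # sides share the midline point so the polyline has no midline gap
    for side, sgn in (("L", -1.0), ("R", 1.0)):
        xs_ant = np.linspace(0.0, sgn * spec.x_sulcus, 13)
        for x in xs_ant:
            lms.add("sulcus", side, on_gingiva(x, spec.y_anterior)[0])
        for y in np.linspace(spec.y_anterior, spec.y_posterior, 28)[1:]:
            lms.add("sulcus", side, on_gingiva(sgn * spec.x_sulcus, y)[0])
    # posterior hard-palate border on the gingiva
    for x in np.linspace(-spec.x_sulcus + 2.0, spec.x_sulcus - 2.0, 9):
        lms.add("posterior_border", "mid", on_gingiva(x, spec.y_posterior)[0])
    # tooth seeds at crown apexes (on the bone = gingiva surface there)
    xc_seed = spec.x_sulcus + 4.5
    for cy in spec.tooth_centers_y:
        for side, sgn in (("L", -1.0), ("R", 1.0)):
            z, _, _ = _bone_z(spec, np.array(sgn * xc_seed), np.array(cy))
            lms.add("tooth_seed", side, (sgn * xc_seed, cy, float(z)))
    lms.validate()
    return lms


def generate_palate(spec: PalateSpec, patient_id: str = "P000") -> PalateSample:
    """Generate one synthetic palate with ground truth.

    The bone mesh is the analytic height field sampled on a regular grid; the
    gingival mesh offsets each bone node along the bone normal by the realized
    thickness (zero on tooth crowns, so crowns are shared surface for
    registration). Same spec (incl. seed) -> bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    f_patient = (
        float(np.exp(rng.normal(0.0, spec.patient_effect_sd) - spec.patient_effect_sd**2 / 2))
        if spec.patient_effect_sd > 0
        else 1.0
    )
    (x0, x1), (y0, y1) = spec.domain
    gx = np.arange(x0, x1 + 1e-9, spec.resolution)
    gy = np.arange(y0, y1 + 1e-9, spec.resolution)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    t_mucosa = _thickness_field(spec, X, Y, f_patient, rng)
    t_eff = t_mucosa * _crown_weight(spec, X, Y)
    t_eff = np.minimum(t_eff, _reach_cap(spec, X, Y, t_eff))
    t_eff = _lipschitz_erode(spec, X, Y, t_eff)

    z, zx, zy = _bone_z(spec, X, Y)
    nx, ny_, nz = _normals(zx, zy)
    bone_v = np.stack([X, Y, z], axis=-1)
    ging_v = bone_v + t_eff[..., None] * np.stack([nx, ny_, nz], axis=-1)
    if spec.vertex_noise_sd > 0:
        ging_v = ging_v + rng.normal(0.0, spec.vertex_noise_sd, size=ging_v.shape)

    bone = _grid_mesh(bone_v)
    gingiva = _grid_mesh(ging_v)

    t_interp = RegularGridInterpolator(
        (gx, gy), t_eff, method="linear", bounds_error=False, fill_value=0.0
    )
    landmarks = _build_landmarks(spec, t_interp)
    per_roi = _integrate_ground_truth(spec, gx, gy, t_eff, refine=4)
    gt = GroundTruth(
        per_roi=per_roi,
        per_vertex_thickness=t_eff.reshape(-1),
        landmarks=landmarks,
        f_patient=f_patient,
        mucosa_total_vol_mm3=_mucosa_total_volume(spec, gx, gy, t_eff),
    )
    return PalateSample(patient_id, bone, gingiva, landmarks, gt, gx, gy, spec)


def perturb_pose(
    mesh: TriangleMesh,
    landmarks: LandmarkSet,
    max_rotation_deg: float,
    max_translation: float,
    seed: int = 0,
):
    """Apply a uniformly sampled rigid perturbation within the given bounds.

    Returns (perturbed mesh copy, perturbed landmarks, applied transform).
    """
    if max_rotation_deg < 0 or max_translation < 0:
        raise ValidationError("perturbation bounds must be >= 0")
    rng = np.random.default_rng(seed)
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rotation_deg))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = direction * rng.uniform(0.0, max_translation)
    T = RigidTransform(Rotation.from_rotvec(axis * angle).as_matrix(), t)
    moved = mesh_from_arrays(T.apply(mesh.vertices), mesh.faces.copy(), weld=False)
    return moved, landmarks.transform(T), T


def voxelize_phantom(
    bone: TriangleMesh,
    gingiva: TriangleMesh,
    spacing: float = 0.3,
    hu=(1200.0, 60.0, -1000.0),
    floor_depth: float = 3.0,
) -> VoxelGrid:
    """HU phantom: bone solid 1200 HU, soft tissue 60 HU, air -1000 HU.

    Both inputs are open relief (height-field) meshes; the bone solid extends
    ``floor_depth`` below the bone surface. Watertight inputs would be handled
    by containment tests, but the generator only produces relief sheets, so
    columns are rasterized from per-column surface heights (linear
    interpolation over each mesh's vertex footprint).
    """
    hu_bone, hu_tissue, hu_air = hu
    if bone is None or len(getattr(bone, "vertices", [])) == 0:
        data = np.full((8, 8, 8), hu_air)
        return VoxelGrid(data, (spacing,) * 3, (0.0, 0.0, 0.0))
    from scipy.interpolate import LinearNDInterpolator

    bv = bone.vertices.view(np.ndarray)
    gv = gingiva.vertices.view(np.ndarray) if gingiva is not None and len(gingiva.vertices) else bv
    zb_i = LinearNDInterpolator(bv[:, :2], bv[:, 2], fill_value=np.nan)
    zg_i = LinearNDInterpolator(gv[:, :2], gv[:, 2], fill_value=np.nan)
    lo = np.minimum(bv.min(axis=0), gv.min(axis=0)) - spacing
    hi = np.maximum(bv.max(axis=0), gv.max(axis=0)) + spacing
    lo[2] = bv[:, 2].min() - floor_depth - spacing
    xs = np.arange(lo[0], hi[0] + 1e-9, spacing)
    ys = np.arange(lo[1], hi[1] + 1e-9, spacing)
    zs = np.arange(lo[2], hi[2] + 1e-9, spacing)
    XX, YY = np.meshgrid(xs, ys, indexing="ij")
    cols = np.stack([XX.ravel(), YY.ravel()], axis=1)
    zb = zb_i(cols).reshape(XX.shape)
    zg = zg_i(cols).reshape(XX.shape)
    zfloor = np.where(np.isfinite(zb), zb - floor_depth, np.nan)
    data = np.full((len(xs), len(ys), len(zs)), hu_air, dtype=np.float32)
    Z = zs[None, None, :]
    zb3 = zb[..., None]
    in_bone = np.isfinite(zb3) & (Z >= zfloor[..., None]) & (Z <= zb3)
    zg3 = np.where(np.isfinite(zg), zg, -np.inf)[..., None]
    in_tissue = np.isfinite(zb3) & (Z > zb3) & (Z <= zg3)
    data[in_bone] = hu_bone
    data[in_tissue] = hu_tissue
    return VoxelGrid(data, (spacing,) * 3, lo)


def generate_cohort(n_patients: int, spec: PalateSpec, seed: int | None = None):
    """Independent per-patient draws; patient seeds derive from the master seed."""
    if n_patients < 1:
        raise ValidationError("n_patients must be >= 1")
    master = spec.seed if seed is None else seed
    rng = np.random.default_rng(master)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_patients)
    return [
        generate_palate(replace(spec, seed=int(s)), patient_id=f"P{i:03d}")
        for i, s in enumerate(child_seeds)
    ]
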