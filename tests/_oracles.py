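"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: brute-force enumeration
for the signed-rank test, a from-scratch ASCII STL parser, and a voxel-counting
volume oracle that rasterizes the tissue solid column by column.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy.stats import rankdata


def wilcoxon_brute_force(diffs: np.ndarray) -> tuple[float, float]:
    """Two-sided signed-rank p by literal enumeration of all 2^n sign vectors."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    sums = []
    for signs in product((0, 1), repeat=n):
        sums.append(np.sum(ranks[np.array(signs, dtype=bool)]))
    sums = np.array(sums)
    cdf = np.mean(sums <= w_plus + 1e-12)
    sf = np.mean(sums >= w_plus - 1e-12)
    p = min(1.0, 2.0 * min(cdf, sf))
    w = min(w_plus, ranks.sum() - w_plus)
    return float(w), float(p)


def parse_ascii_stl(path) -> np.ndarray:
    """Independent minimal ASCII STL reader: returns (n_tri, 3, 3) vertex array."""
    tris, cur = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts[:1] == ["vertex"]:
                cur.append([float(v) for v in parts[1:4]])
                if len(cur) == 3:
                    tris.append(cur)
                    cur = []
    return np.array(tris)


def canonical_vertex_set(triangles: np.ndarray, decimals: int = 5) -> set:
    pts = triangles.reshape(-1, 3)
    return {tuple(np.round(p, decimals)) for p in pts}


def voxel_volume_oracle(sample, labels, spacing: float = 0.1) -> dict:
    """Per-ROI volume by counting voxel centers between the two mesh surfaces.

    The tissue solid swept between a labelled gingival triangle and its bone
    correspondent has slanted side walls wherever the sweep direction tilts;
    an unbiased voxel footprint must place every wall at the sweep's
    mid-depth. The projection of the *mid-surface* triangle (vertex-wise mean
    of gingiva and bone positions, using the generator's exact vertex
    correspondence) is exactly that mid-depth footprint, in every wall
    orientation at once. So: each labelled face claims the voxel columns
    inside its projected mid-surface triangle, and each claimed column counts
    the voxel centers lying between the bone and gingiva height surfaces
    (both interpolated spatially, independent of the package's proximity and
    frustum code).
    """
    from scipy.interpolate import LinearNDInterpolator

    gx, gy = sample.grid_x, sample.grid_y
    nx, ny = len(gx), len(gy)
    bone_v = sample.bone.vertices.view(np.ndarray)
    ging_v = sample.gingiva.vertices.view(np.ndarray)
    lab = labels.labels
    faces = sample.gingiva.faces

    zb_itp = LinearNDInterpolator(bone_v[:, :2], bone_v[:, 2])
    zg_itp = LinearNDInterpolator(ging_v[:, :2], ging_v[:, 2])
    mid_v = 0.5 * (ging_v + bone_v)

    # global voxel-column lattice over the grid domain
    x0, y0 = gx[0], gy[0]
    ncx = int(np.ceil((gx[-1] - x0) / spacing))
    ncy = int(np.ceil((gy[-1] - y0) / spacing))
    owner = np.zeros((ncx, ncy), dtype=np.int8)  # 0 = unclaimed

    labelled = np.flatnonzero(lab > 0)
    tri_xy = mid_v[:, :2][faces[labelled]]  # (m, 3, 2)
    for f_idx, tri in zip(labelled, tri_xy):
        r = lab[f_idx]
        lo = tri.min(axis=0)
        hi = tri.max(axis=0)
        i0 = max(0, int(np.ceil((lo[0] - x0) / spacing - 0.5)))
        i1 = min(ncx - 1, int(np.floor((hi[0] - x0) / spacing - 0.5)))
        j0 = max(0, int(np.ceil((lo[1] - y0) / spacing - 0.5)))
        j1 = min(ncy - 1, int(np.floor((hi[1] - y0) / spacing - 0.5)))
        if i1 < i0 or j1 < j0:
            continue
        cx = x0 + (np.arange(i0, i1 + 1) + 0.5) * spacing
        cy = y0 + (np.arange(j0, j1 + 1) + 0.5) * spacing
        X, Y = np.meshgrid(cx, cy, indexing="ij")
        # barycentric point-in-triangle test
        a, b, c = tri
        d = (b[1] - c[1]) * (a[0] - c[0]) + (c[0] - b[0]) * (a[1] - c[1])
        if abs(d) < 1e-15:
            continue
        w0 = ((b[1] - c[1]) * (X - c[0]) + (c[0] - b[0]) * (Y - c[1])) / d
        w1 = ((c[1] - a[1]) * (X - c[0]) + (a[0] - c[0]) * (Y - c[1])) / d
        w2 = 1.0 - w0 - w1
        inside = (w0 >= -1e-12) & (w1 >= -1e-12) & (w2 >= -1e-12)
        block = owner[i0 : i1 + 1, j0 : j1 + 1]
        block[inside & (block == 0)] = r

    vols = {}
    claimed = np.argwhere(owner > 0)
    if len(claimed):
        pts = np.column_stack(
            [x0 + (claimed[:, 0] + 0.5) * spacing, y0 + (claimed[:, 1] + 0.5) * spacing]
        )
        zb = zb_itp(pts)
        zg = zg_itp(pts)
        ok = np.isfinite(zb) & np.isfinite(zg)
        counts = np.where(
            ok, np.floor(zg / spacing - 0.5) - np.floor(zb / spacing - 0.5), 0.0
        )
        counts = np.maximum(counts, 0)
        rois = owner[claimed[:, 0], claimed[:, 1]]
        for r in range(1, 6):
            vols[f"ROI{r}"] = float(counts[rois == r].sum()) * spacing**3
    else:
        vols = {f"ROI{r}": 0.0 for r in range(1, 6)}
    vols["total"] = sum(vols[f"ROI{r}"] for r in range(1, 6))
    return vols
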