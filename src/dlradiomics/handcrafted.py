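"""Handcrafted radiomics features behind a pluggable backend contract.

The pipeline delegates handcrafted (IBSI-style) feature computation to a
registered backend configured with a 25 HU bin width and 1 mm isotropic
resampling.  The catalogue is fixed: 107 features — 14 shape, 18 first-order
and 75 texture (GLCM 24, GLRLM 16, GLDM 14, GLSZM 16, NGTDM 5) — with
family-prefixed names.  The package ships a built-in numpy/scikit-image
backend implementing this catalogue; external extractors can be registered
under their own name and are used through the same contract.

Definitions follow the IBSI reference formulations: gray levels are obtained
by fixed-bin-width discretization anchored at the ROI minimum; GLCM and GLRLM
aggregate over the 13 unique 3D directions (feature-level averaging); GLSZM
zones and GLDM dependencies use 26-connectivity; the GLDM dependence index
counts the center voxel plus its dependent neighbors (so it is always >= 1).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .features import FeatureMatrix
from .imaging import CTVolume, PreprocessConfig, SegMask, resample_isotropic


class FeatureSetUnavailableError(RuntimeError):
    """Requested handcrafted backend is not registered/installed."""


FAMILY_COUNTS = {
    "shape": 14,
    "firstorder": 18,
    "glcm": 24,
    "glrlm": 16,
    "gldm": 14,
    "glszm": 16,
    "ngtdm": 5,
}
TEXTURE_FAMILIES = ("glcm", "glrlm", "gldm", "glszm", "ngtdm")

_EPS = np.spacing(1.0)

# 13 unique direction vectors of the 26-neighborhood (one per +/- pair)
_DIRECTIONS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def discretize(values: np.ndarray, bin_width: float = 25.0) -> np.ndarray:
    """Fixed-bin-width gray levels, 1-based, anchored at the ROI minimum."""
    v = np.asarray(values, dtype=float)
    return np.floor((v - v.min()) / bin_width).astype(int) + 1


# ---------------------------------------------------------------------------
# shape (14)

def _principal_moments(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    eig = np.linalg.eigvalsh(cov)[::-1]  # descending
    return np.clip(eig, 0.0, None)


def _max_pairwise(coords: np.ndarray) -> float:
    if coords.shape[0] < 2:
        return 0.0
    pts = coords
    if pts.shape[0] > 300:
        try:
            hull = ConvexHull(pts, qhull_options="QJ")
            pts = pts[hull.vertices]
        except Exception:
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _shape_features(mask: np.ndarray) -> dict[str, float]:
    from skimage.measure import marching_cubes, mesh_surface_area

    vox_count = int(mask.sum())
    voxel_volume = float(vox_count)  # 1 mm isotropic grid
    padded = np.pad(mask.astype(float), 2)
    # slight smoothing before meshing suppresses the staircase bias of
    # marching cubes on binary grids (volume change < 2% for ROIs >= ~100 vox)
    if vox_count >= 64:
        padded = ndimage.gaussian_filter(padded, 0.8)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    surface_area = float(mesh_surface_area(verts, faces))
    tri = verts[faces]
    mesh_volume = float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)

    coords = np.argwhere(mask > 0).astype(float)
    lam = _principal_moments(coords)
    major = 4.0 * np.sqrt(lam[0])
    minor = 4.0 * np.sqrt(lam[1])
    least = 4.0 * np.sqrt(lam[2])

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / surface_area

    # 2D maximum diameters per principal plane (max over the slices along the
    # omitted axis); axes follow the (x, y, z) array convention
    def diam2d(drop_axis: int) -> float:
        keep = [a for a in range(3) if a != drop_axis]
        best = 0.0
        for k in np.unique(coords[:, drop_axis]):
            pts = coords[coords[:, drop_axis] == k][:, keep]
            best = max(best, _max_pairwise(pts))
        return best

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume if mesh_volume > 0 else np.nan,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": _max_pairwise(coords),
        "Maximum2DDiameterSlice": diam2d(2),
        "Maximum2DDiameterColumn": diam2d(1),
        "Maximum2DDiameterRow": diam2d(0),
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "LeastAxisLength": float(least),
        "Elongation": float(np.sqrt(lam[1] / lam[0])) if lam[0] > 0 else np.nan,
        "Flatness": float(np.sqrt(lam[2] / lam[0])) if lam[0] > 0 else np.nan,
    }


# ---------------------------------------------------------------------------
# first-order (18)

def _firstorder_features(values: np.ndarray, bin_width: float) -> dict[str, float]:
    x = np.asarray(values, dtype=float)
    n = x.size
    levels = discretize(x, bin_width)
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / n
    mean = float(x.mean())
    var = float(x.var())  # population variance, matching the IBSI definition
    sd = np.sqrt(var)
    cm3 = float(((x - mean) ** 3).mean())
    cm4 = float(((x - mean) ** 4).mean())
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float((x**2).sum()),  # 1 mm^3 voxels: volume factor = 1
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(robust - robust.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": cm3 / sd**3 if sd > 0 else 0.0,
        "Kurtosis": cm4 / var**2 if var > 0 else 0.0,
        "Variance": var,
        "Uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# GLCM (24)

def _glcm_matrix(levels: np.ndarray, roi: np.ndarray, offset: tuple[int, int, int], ng: int) -> np.ndarray:
    sl_a, sl_b = [], []
    for d, size in zip(offset, levels.shape):
        if d >= 0:
            sl_a.append(slice(0, size - d))
            sl_b.append(slice(d, size))
        else:
            sl_a.append(slice(-d, size))
            sl_b.append(slice(0, size + d))
    a = levels[tuple(sl_a)]
    b = levels[tuple(sl_b)]
    valid = roi[tuple(sl_a)] & roi[tuple(sl_b)]
    ai, bi = a[valid] - 1, b[valid] - 1
    mat = np.zeros((ng, ng))
    np.add.at(mat, (ai, bi), 1.0)
    return mat + mat.T  # symmetric co-occurrence


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    p = p / p.sum()
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    ux = float((i * px).sum())
    sigx = float(np.sqrt(((i - ux) ** 2 * px).sum()))
    # diagonal/cross-diagonal distributions
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    hx = ent(px)
    hxy = ent(p.ravel())
    pxpy = np.outer(px, px)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())

    autocorr = float((ii * jj * p).sum())
    da = float((k_diff * p_diff).sum())
    # MCC: sqrt of the second-largest eigenvalue of Q_uv = sum_k p(u,k)p(v,k)/(px(u)py(k)),
    # computed on the gray levels actually present
    present = px > 0
    if present.sum() > 1:
        ps = p[np.ix_(present, present)]
        pxs = px[present]
        a_mat = ps / pxs[:, None]
        b_mat = ps / pxs[None, :]  # symmetric GLCM: py = px
        try:
            eigs = np.sort(np.abs(np.linalg.eigvals(a_mat @ b_mat.T)))
            mcc = float(np.sqrt(max(0.0, eigs[-2])))
        except np.linalg.LinAlgError:
            mcc = np.nan
    else:
        mcc = 1.0

    off_diag = ii != jj
    corr = ((autocorr - ux * ux) / sigx**2) if sigx > 0 else 1.0
    return {
        "Autocorrelation": autocorr,
        "ClusterProminence": float(((ii + jj - 2 * ux) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * ux) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * ux) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))),
        "InverseVariance": float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum()),
        "JointAverage": ux,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": sigx**2,
    }


def _glcm_features(levels: np.ndarray, roi: np.ndarray, ng: int) -> dict[str, float]:
    per_dir = []
    for off in _DIRECTIONS:
        mat = _glcm_matrix(levels, roi, off, ng)
        if mat.sum() > 0:
            per_dir.append(_glcm_features_single(mat))
    keys = per_dir[0].keys()
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


# ---------------------------------------------------------------------------
# GLRLM (16)

def _runs_for_direction(levels: np.ndarray, roi: np.ndarray, d: tuple[int, int, int]):
    """(gray, run_length) pairs of maximal same-gray runs along direction ``d``.

    Non-ROI voxels break runs.  Voxels are sorted into lines (constant
    transverse coordinate) and by step index along the direction, then runs
    are maximal segments with no line break, no gray change and no ROI gap.
    """
    dvec = np.asarray(d)
    coords = np.argwhere(np.ones(levels.shape, dtype=bool))
    t = coords @ dvec
    line = coords - t[:, None] * dvec[None, :]
    order = np.lexsort((t, line[:, 2], line[:, 1], line[:, 0]))
    line_s, t_s = line[order], t[order]
    gray = levels[tuple(coords[order].T)]
    valid = roi[tuple(coords[order].T)]
    n = gray.size
    brk = np.ones(n, dtype=bool)
    same_line = np.all(line_s[1:] == line_s[:-1], axis=1) & (t_s[1:] == t_s[:-1] + 1)
    brk[1:] = ~(same_line & (gray[1:] == gray[:-1]) & valid[1:] & valid[:-1])
    run_id = np.cumsum(brk) - 1
    lengths = np.bincount(run_id[valid], minlength=run_id[-1] + 1)
    starts = valid & brk
    return list(zip(gray[starts].tolist(), lengths[run_id[starts]].tolist()))


def _glrlm_features_single(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = P.sum()
    i = np.arange(1, P.shape[0] + 1)[:, None].astype(float)
    r = np.arange(1, P.shape[1] + 1)[None, :].astype(float)
    pg = P.sum(axis=1)
    pr = P.sum(axis=0)
    pnorm = P / nr
    mu_i = (i.ravel() * pg / nr).sum()
    mu_r = (r.ravel() * pr / nr).sum()
    ent = pnorm[pnorm > 0]
    return {
        "ShortRunEmphasis": float((P / r**2).sum() / nr),
        "LongRunEmphasis": float((P * r**2).sum() / nr),
        "GrayLevelNonUniformity": float((pg**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nr**2),
        "RunLengthNonUniformity": float((pr**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pr**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((pnorm * (i - mu_i) ** 2).sum()),
        "RunVariance": float((pnorm * (r - mu_r) ** 2).sum()),
        "RunEntropy": float(-(ent * np.log2(ent)).sum()),
        "LowGrayLevelRunEmphasis": float((P / i**2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((P * i**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((P / (i**2 * r**2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((P * i**2 / r**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((P * r**2 / i**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((P * i**2 * r**2).sum() / nr),
    }


def _glrlm_features(levels: np.ndarray, roi: np.ndarray, ng: int) -> dict[str, float]:
    n_voxels = int(roi.sum())
    max_run = max(levels.shape)
    per_dir = []
    for d in _DIRECTIONS:
        P = np.zeros((ng, max_run))
        for gray, rl in _runs_for_direction(levels, roi, d):
            P[gray - 1, rl - 1] += 1
        if P.sum() > 0:
            per_dir.append(_glrlm_features_single(P, n_voxels))
    keys = per_dir[0].keys()
    return {k: float(np.mean([d[k] for d in per_dir])) for k in keys}


# ---------------------------------------------------------------------------
# GLSZM (16)

def _glszm_features(levels: np.ndarray, roi: np.ndarray, ng: int) -> dict[str, float]:
    n_voxels = int(roi.sum())
    structure = np.ones((3, 3, 3), int)
    zones: list[tuple[int, int]] = []
    for g in range(1, ng + 1):
        m = (levels == g) & roi
        if not m.any():
            continue
        lab, ncomp = ndimage.label(m, structure=structure)
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, ncomp + 1))
        zones.extend((g, int(s)) for s in sizes)
    max_s = max(s for _, s in zones)
    P = np.zeros((ng, max_s))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    nz = P.sum()
    i = np.arange(1, ng + 1)[:, None].astype(float)
    s = np.arange(1, max_s + 1)[None, :].astype(float)
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    pnorm = P / nz
    mu_i = (i.ravel() * pg / nz).sum()
    mu_s = (s.ravel() * ps / nz).sum()
    ent = pnorm[pnorm > 0]
    return {
        "SmallAreaEmphasis": float((P / s**2).sum() / nz),
        "LargeAreaEmphasis": float((P * s**2).sum() / nz),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nz**2),
        "SizeZoneNonUniformity": float((ps**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum() / nz**2),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float((pnorm * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((pnorm * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": float(-(ent * np.log2(ent)).sum()),
        "LowGrayLevelZoneEmphasis": float((P / i**2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((P * i**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((P / (i**2 * s**2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((P * i**2 / s**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((P * s**2 / i**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((P * i**2 * s**2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# GLDM (14) and NGTDM (5) share the 26-neighborhood scan

def _neighbor_offsets():
    return [(dx, dy, dz)
            for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)]


def _gldm_features(levels: np.ndarray, roi: np.ndarray, ng: int, alpha: float = 0.0) -> dict[str, float]:
    dep = np.zeros(levels.shape, dtype=int)
    for off in _neighbor_offsets():
        shifted = np.full(levels.shape, -(10**9))
        sl_a, sl_b = [], []
        for d, size in zip(off, levels.shape):
            if d >= 0:
                sl_a.append(slice(0, size - d))
                sl_b.append(slice(d, size))
            else:
                sl_a.append(slice(-d, size))
                sl_b.append(slice(0, size + d))
        shifted[tuple(sl_a)] = np.where(roi[tuple(sl_b)], levels[tuple(sl_b)], -(10**9))
        dep += (np.abs(shifted - levels) <= alpha) & roi
    dep_idx = dep + 1  # center voxel counts itself: dependence index >= 1
    max_d = int(dep_idx[roi].max())
    P = np.zeros((ng, max_d))
    np.add.at(P, (levels[roi] - 1, dep_idx[roi] - 1), 1.0)
    nz = P.sum()
    i = np.arange(1, ng + 1)[:, None].astype(float)
    j = np.arange(1, max_d + 1)[None, :].astype(float)
    pg = P.sum(axis=1)
    pd_ = P.sum(axis=0)
    pnorm = P / nz
    mu_i = (i.ravel() * pg / nz).sum()
    mu_j = (j.ravel() * pd_ / nz).sum()
    ent = pnorm[pnorm > 0]
    return {
        "SmallDependenceEmphasis": float((P / j**2).sum() / nz),
        "LargeDependenceEmphasis": float((P * j**2).sum() / nz),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "DependenceNonUniformity": float((pd_**2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pd_**2).sum() / nz**2),
        "GrayLevelVariance": float((pnorm * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((pnorm * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(ent * np.log2(ent)).sum()),
        "LowGrayLevelEmphasis": float((P / i**2).sum() / nz),
        "HighGrayLevelEmphasis": float((P * i**2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * j**2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * i**2 / j**2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * j**2 / i**2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * i**2 * j**2).sum() / nz),
    }


def _ngtdm_features(levels: np.ndarray, roi: np.ndarray, ng: int) -> dict[str, float]:
    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=float)
    for off in _neighbor_offsets():
        sl_a, sl_b = [], []
        for d, size in zip(off, levels.shape):
            if d >= 0:
                sl_a.append(slice(0, size - d))
                sl_b.append(slice(d, size))
            else:
                sl_a.append(slice(-d, size))
                sl_b.append(slice(0, size + d))
        nb_sum[tuple(sl_a)] += np.where(roi[tuple(sl_b)], levels[tuple(sl_b)], 0.0)
        nb_cnt[tuple(sl_a)] += roi[tuple(sl_b)]
    has_nb = roi & (nb_cnt > 0)
    nbar = np.zeros(levels.shape)
    nbar[has_nb] = nb_sum[has_nb] / nb_cnt[has_nb]
    nv = int(has_nb.sum())
    s = np.zeros(ng)
    n = np.zeros(ng)
    for g in range(1, ng + 1):
        sel = has_nb & (levels == g)
        n[g - 1] = sel.sum()
        s[g - 1] = np.abs(g - nbar[sel]).sum()
    p = n / nv
    present = p > 0
    ngp = int(present.sum())
    i = np.arange(1, ng + 1).astype(float)
    ip, pp, sp = i[present], p[present], s[present]
    coarse_den = float((pp * sp).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        pij = pp[:, None] * pp[None, :]
        contrast = (pij * di**2).sum() / (ngp * (ngp - 1)) * (s.sum() / nv)
        busy_den = np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum()
        busyness = coarse_den / busy_den if busy_den > 0 else 0.0
        ps_i = (pp * sp)[:, None]
        complexity = (np.abs(di) * (ps_i + ps_i.T) / (pp[:, None] + pp[None, :])).sum() / nv
        strength_num = ((pp[:, None] + pp[None, :]) * di**2).sum()
        strength = strength_num / s.sum() if s.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }


# ---------------------------------------------------------------------------
# backend contract

class BuiltinRadiomicsBackend:
    """Built-in IBSI-style extractor (bin width 25 HU, 1 mm resampling)."""

    name = "builtin"

    def __init__(self, bin_width: float = 25.0):
        self.bin_width = bin_width

    def extract(self, vol: CTVolume, mask: SegMask) -> dict[str, float]:
        rvol, rmask = resample_isotropic(vol, mask, PreprocessConfig())
        roi_mask = rmask.voxels.astype(bool)
        if not roi_mask.any():
            raise ValueError("empty mask after resampling")
        # crop to the ROI bounding box (plus 1-voxel margin) for speed
        idx = np.argwhere(roi_mask)
        lo = np.maximum(idx.min(axis=0) - 1, 0)
        hi = np.minimum(idx.max(axis=0) + 2, roi_mask.shape)
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        roi = roi_mask[box]
        img = rvol.voxels[box]
        vals = img[roi]
        levels = np.zeros(img.shape, dtype=int)
        levels[roi] = discretize(vals, self.bin_width)
        ng = int(levels.max())

        out: dict[str, float] = {}
        for fam, d in [
            ("shape", _shape_features(roi.astype(np.uint8))),
            ("firstorder", _firstorder_features(vals, self.bin_width)),
            ("glcm", _glcm_features(levels, roi, ng)),
            ("glrlm", _glrlm_features(levels, roi, ng)),
            ("gldm", _gldm_features(levels, roi, ng)),
            ("glszm", _glszm_features(levels, roi, ng)),
            ("ngtdm", _ngtdm_features(levels, roi, ng)),
        ]:
            assert len(d) == FAMILY_COUNTS[fam], (fam, len(d))
            for k, v in d.items():
                out[f"{fam}_{k}"] = float(v)
        assert len(out) == 107
        return out


_HANDCRAFTED_BACKENDS: dict[str, object] = {"builtin": BuiltinRadiomicsBackend()}


def register_handcrafted_backend(name: str, backend) -> None:
    _HANDCRAFTED_BACKENDS[name] = backend


def handcrafted_features(vol: CTVolume, mask: SegMask, backend: str = "builtin",
                         sample_id: str = "sample_0") -> FeatureMatrix:
    """One 107-feature row for a tumor, via the configured backend."""
    if backend not in _HANDCRAFTED_BACKENDS:
        raise FeatureSetUnavailableError(
            f"handcrafted backend {backend!r} unavailable; registered: "
            f"{sorted(_HANDCRAFTED_BACKENDS)}. The pipeline can still run in "
            "deep-feature-only mode."
        )
    feats = _HANDCRAFTED_BACKENDS[backend].extract(vol, mask)
    names = list(feats)
    values = np.array([[feats[k] for k in names]])
    # degenerate geometry can yield NaN ratios; keep the matrix finite
    values = np.nan_to_num(values, nan=0.0)
    return FeatureMatrix(values, names, [sample_id],
                         provenance={"backbone": f"handcrafted:{backend}"})
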