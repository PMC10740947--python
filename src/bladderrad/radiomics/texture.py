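"""Gray-level texture-matrix feature families.

All families operate on a 1-based integer level grid (0 outside the mask)
produced by :func:`bladderrad.radiomics.discretize.discretize`:

* GLCM  — co-occurrence at distance 1 over the 13 unique 3D directions,
  symmetric accumulation, per-direction normalization, features averaged
  over directions (24 features).
* GLRLM — run-length matrices over the same 13 directions, out-of-mask
  voxels break runs, per-direction features averaged (16 features).
* GLSZM — size-zone matrix from 26-connected equal-level zones,
  direction-free (16 features).
* GLDM  — dependence matrix over the 26-neighbourhood with tolerance
  alpha; dependence *size* is the dependent-neighbour count + 1
  (14 features).
* NGTDM — neighbourhood gray-tone difference matrix over the
  26-neighbourhood (5 features).

Degenerate single-level regions follow the usual limit conventions
(correlation and MCC -> 1, NGTDM contrast -> 0, coarseness capped).
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import ndimage

_EPS = np.spacing(1.0)

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "MCC", "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)
GLRLM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)
GLSZM_NAMES = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)
GLDM_NAMES = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)
NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")


def directions_13() -> list:
    """The 13 unique 3D offsets (first non-zero component positive)."""
    out = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        nz = next(c for c in d if c != 0)
        if nz > 0:
            out.append(d)
    assert len(out) == 13
    return out


_ALL_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _shift_slices(shape, d):
    """Paired slices (src, dst) so that src voxels pair with src+d voxels."""
    src, dst = [], []
    for size, step in zip(shape, d):
        if step == 0:
            src.append(slice(None)); dst.append(slice(None))
        elif step > 0:
            src.append(slice(0, size - step)); dst.append(slice(step, size))
        else:
            src.append(slice(-step, size)); dst.append(slice(0, size + step))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrices(levels: np.ndarray, n_levels: int, distance: int = 1):
    """Per-direction normalized symmetric co-occurrence matrices."""
    mask = levels > 0
    mats = []
    for d in directions_13():
        dd = tuple(distance * c for c in d)
        src, dst = _shift_slices(levels.shape, dd)
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        a = levels[src][valid] - 1
        b = levels[dst][valid] - 1
        counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
        p = counts.reshape(n_levels, n_levels).astype(float)
        p = p + p.T
        mats.append(p / p.sum())
    return mats


def glcm_features(levels, n_levels, distance: int = 1) -> dict:
    """24 co-occurrence features, computed per direction then averaged.

    The per-direction computation is vectorized over the stacked matrices;
    only the MCC eigen-decompositions remain per-direction (batched).
    """
    mats = glcm_matrices(levels, n_levels, distance)
    if not mats:  # single isolated voxel: fall back to the trivial matrix
        mats = [np.ones((1, 1))]
    return _glcm_feats_batch(np.stack(mats))


def _glcm_feats_batch(P: np.ndarray) -> dict:
    """Feature means over a (D, Ng, Ng) stack of normalized matrices."""
    d, ng, _ = P.shape
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=2)                      # (D, Ng)
    mu = (i * px).sum(axis=1)               # (D,)
    sigma2 = ((i[None, :] - mu[:, None]) ** 2 * px).sum(axis=1)

    # sum / difference distributions
    sum_idx = (ii + jj).astype(int) - 2     # 0 .. 2Ng-2
    diff_idx = np.abs(ii - jj).astype(int)  # 0 .. Ng-1
    psum = np.zeros((d, 2 * ng - 1))
    pdiff = np.zeros((d, ng))
    for dd in range(d):
        np.add.at(psum[dd], sum_idx.ravel(), P[dd].ravel())
        np.add.at(pdiff[dd], diff_idx.ravel(), P[dd].ravel())
    kd = np.arange(ng, dtype=float)
    ks = np.arange(2, 2 * ng + 1, dtype=float)
    da = (kd * pdiff).sum(axis=1)

    def _ent(p):
        return -np.sum(np.where(p > 0, p * np.log2(np.maximum(p, _EPS)), 0.0),
                       axis=tuple(range(1, p.ndim)))

    hxy = _ent(P)
    pxj = px[:, :, None] * px[:, None, :]
    hxy1 = -np.sum(P * np.log2(pxj + _EPS), axis=(1, 2))
    hxy2 = -np.sum(pxj * np.log2(pxj + _EPS), axis=(1, 2))
    hx = _ent(px)

    corr = np.where(
        sigma2 > 0,
        (np.sum(ii * jj * P, axis=(1, 2)) - mu * mu)
        / np.where(sigma2 > 0, sigma2, 1.0),
        1.0)

    if ng == 1:
        mcc = np.ones(d)
    else:
        safe_px = np.maximum(px, _EPS)
        q = np.einsum("dik,djk,dk->dij", P / safe_px[:, :, None], P,
                      1.0 / safe_px)
        ev = np.sort(np.abs(np.linalg.eigvals(q)), axis=1)[:, ::-1]
        mcc = np.sqrt(np.clip(ev[:, 1], 0.0, 1.0))

    off = ii != jj
    inv_var = (P[:, off] / ((ii - jj)[off] ** 2)).sum(axis=1) if ng > 1 \
        else np.zeros(d)
    imc1 = np.where(hx > 0, (hxy - hxy1) / np.maximum(hx, _EPS), 0.0)
    imc2 = np.where(hxy2 >= hxy,
                    np.sqrt(np.clip(1 - np.exp(-2.0 * (hxy2 - hxy)), 0, None)),
                    0.0)

    center = ii + jj
    feats = {
        "Autocorrelation": np.sum(ii * jj * P, axis=(1, 2)),
        "ClusterProminence": np.sum(
            (center[None] - 2 * mu[:, None, None]) ** 4 * P, axis=(1, 2)),
        "ClusterShade": np.sum(
            (center[None] - 2 * mu[:, None, None]) ** 3 * P, axis=(1, 2)),
        "ClusterTendency": np.sum(
            (center[None] - 2 * mu[:, None, None]) ** 2 * P, axis=(1, 2)),
        "Contrast": np.sum((ii - jj) ** 2 * P, axis=(1, 2)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": _ent(pdiff),
        "DifferenceVariance": ((kd[None, :] - da[:, None]) ** 2 * pdiff).sum(axis=1),
        "Id": np.sum(P / (1.0 + np.abs(ii - jj)), axis=(1, 2)),
        "Idm": np.sum(P / (1.0 + (ii - jj) ** 2), axis=(1, 2)),
        "Idmn": np.sum(P / (1.0 + ((ii - jj) / ng) ** 2), axis=(1, 2)),
        "Idn": np.sum(P / (1.0 + np.abs(ii - jj) / ng), axis=(1, 2)),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu,
        "JointEnergy": np.sum(P**2, axis=(1, 2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": P.max(axis=(1, 2)),
        "SumAverage": (ks * psum).sum(axis=1),
        "SumEntropy": _ent(psum),
        "SumSquares": sigma2,
    }
    return {k: float(np.mean(feats[k])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_runs(levels: np.ndarray, direction) -> tuple:
    """Enumerate maximal equal-level runs along one direction.

    Returns ``(run_levels, run_lengths)`` over in-mask voxels; out-of-mask
    voxels (level 0) break runs.
    """
    mask = levels > 0
    coords = np.argwhere(mask)
    if coords.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    lev = levels[mask]
    d = np.asarray(direction)
    k = int((d**2).sum())
    t = coords @ d
    line_key = coords * k - t[:, None] * d  # constant along each line
    order = np.lexsort((t, line_key[:, 2], line_key[:, 1], line_key[:, 0]))
    t_s = t[order]
    key_s = line_key[order]
    lev_s = lev[order]
    same_line = np.all(key_s[1:] == key_s[:-1], axis=1)
    contiguous = (t_s[1:] - t_s[:-1]) == k
    same_run = same_line & contiguous & (lev_s[1:] == lev_s[:-1])
    starts = np.flatnonzero(np.concatenate([[True], ~same_run]))
    lengths = np.diff(np.concatenate([starts, [lev_s.size]]))
    return lev_s[starts], lengths


def _weighted_feats_rl(run_lev, run_len, n_levels, n_vox) -> dict:
    nr = run_len.size
    i = run_lev.astype(float)
    j = run_len.astype(float)
    p = 1.0 / nr  # each run has weight 1/Nr

    row = np.bincount(run_lev - 1, minlength=n_levels).astype(float)
    col = np.bincount(run_len - 1).astype(float)
    # joint probabilities for entropy / variance
    maxlen = int(run_len.max())
    joint = np.zeros((n_levels, maxlen))
    np.add.at(joint, (run_lev - 1, run_len - 1), 1.0)
    pj = joint / nr
    pj_nz = pj[pj > 0]
    mu_i = float(np.sum(i) * p)
    mu_j = float(np.sum(j) * p)

    return {
        "GrayLevelNonUniformity": float(np.sum(row**2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(row**2) / nr**2),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2) * p),
        "HighGrayLevelRunEmphasis": float(np.sum(i**2) / nr),
        "LongRunEmphasis": float(np.sum(j**2) / nr),
        "LongRunHighGrayLevelEmphasis": float(np.sum(i**2 * j**2) / nr),
        "LongRunLowGrayLevelEmphasis": float(np.sum(j**2 / i**2) / nr),
        "LowGrayLevelRunEmphasis": float(np.sum(1.0 / i**2) / nr),
        "RunEntropy": float(-np.sum(pj_nz * np.log2(pj_nz))),
        "RunLengthNonUniformity": float(np.sum(col**2) / nr),
        "RunLengthNonUniformityNormalized": float(np.sum(col**2) / nr**2),
        "RunPercentage": float(nr / n_vox),
        "RunVariance": float(np.sum((j - mu_j) ** 2) * p),
        "ShortRunEmphasis": float(np.sum(1.0 / j**2) / nr),
        "ShortRunHighGrayLevelEmphasis": float(np.sum(i**2 / j**2) / nr),
        "ShortRunLowGrayLevelEmphasis": float(np.sum(1.0 / (i**2 * j**2)) / nr),
    }


def glrlm_features(levels, n_levels) -> dict:
    """16 run-length features averaged over the 13 directions."""
    n_vox = int((levels > 0).sum())
    if n_vox == 0:
        raise ValueError("mask is empty")
    per_dir = []
    for d in directions_13():
        run_lev, run_len = glrlm_runs(levels, d)
        per_dir.append(_weighted_feats_rl(run_lev, run_len, n_levels, n_vox))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_zones(levels: np.ndarray, n_levels: int) -> tuple:
    """26-connected equal-level zones; returns ``(zone_levels, zone_sizes)``."""
    structure = np.ones((3, 3, 3), dtype=int)
    zl, zs = [], []
    for lv in range(1, n_levels + 1):
        lab, n = ndimage.label(levels == lv, structure=structure)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zl.extend([lv] * n)
        zs.extend(sizes.tolist())
    return np.asarray(zl, dtype=int), np.asarray(zs, dtype=int)


def glszm_features(levels, n_levels) -> dict:
    """16 size-zone features (direction-free)."""
    n_vox = int((levels > 0).sum())
    if n_vox == 0:
        raise ValueError("mask is empty")
    zl, zs = glszm_zones(levels, n_levels)
    nz = zl.size
    i = zl.astype(float)
    s = zs.astype(float)
    p = 1.0 / nz
    row = np.bincount(zl - 1, minlength=n_levels).astype(float)
    col = np.bincount(zs - 1).astype(float)
    joint = np.zeros((n_levels, int(zs.max())))
    np.add.at(joint, (zl - 1, zs - 1), 1.0)
    pj = joint / nz
    pj_nz = pj[pj > 0]
    mu_i = float(np.sum(i) * p)
    mu_s = float(np.sum(s) * p)
    return {
        "GrayLevelNonUniformity": float(np.sum(row**2) / nz),
        "GrayLevelNonUniformityNormalized": float(np.sum(row**2) / nz**2),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2) * p),
        "HighGrayLevelZoneEmphasis": float(np.sum(i**2) / nz),
        "LargeAreaEmphasis": float(np.sum(s**2) / nz),
        "LargeAreaHighGrayLevelEmphasis": float(np.sum(i**2 * s**2) / nz),
        "LargeAreaLowGrayLevelEmphasis": float(np.sum(s**2 / i**2) / nz),
        "LowGrayLevelZoneEmphasis": float(np.sum(1.0 / i**2) / nz),
        "SizeZoneNonUniformity": float(np.sum(col**2) / nz),
        "SizeZoneNonUniformityNormalized": float(np.sum(col**2) / nz**2),
        "SmallAreaEmphasis": float(np.sum(1.0 / s**2) / nz),
        "SmallAreaHighGrayLevelEmphasis": float(np.sum(i**2 / s**2) / nz),
        "SmallAreaLowGrayLevelEmphasis": float(np.sum(1.0 / (i**2 * s**2)) / nz),
        "ZoneEntropy": float(-np.sum(pj_nz * np.log2(pj_nz))),
        "ZonePercentage": float(nz / n_vox),
        "ZoneVariance": float(np.sum((s - mu_s) ** 2) * p),
    }


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_dependence(levels: np.ndarray, alpha: int = 0) -> tuple:
    """Per-voxel dependent-neighbour count over the 26-neighbourhood.

    Returns ``(voxel_levels, dependence_counts)`` for in-mask voxels.
    """
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in _ALL_26:
        src, dst = _shift_slices(levels.shape, d)
        both = mask[src] & mask[dst]
        close = np.abs(levels[src] - levels[dst]) <= alpha
        contrib = np.zeros_like(dep)
        contrib[src] = (both & close).astype(np.int64)
        dep += contrib
    return levels[mask], dep[mask]


def gldm_features(levels, n_levels, alpha: int = 0) -> dict:
    """14 dependence features; dependence size = dependent count + 1."""
    lv, dep = gldm_dependence(levels, alpha)
    nz = lv.size
    if nz == 0:
        raise ValueError("mask is empty")
    i = lv.astype(float)
    d = dep.astype(float) + 1.0  # size (j + 1) convention
    p = 1.0 / nz
    row = np.bincount(lv - 1, minlength=n_levels).astype(float)
    col = np.bincount(dep).astype(float)
    joint = np.zeros((n_levels, int(dep.max()) + 1))
    np.add.at(joint, (lv - 1, dep), 1.0)
    pj = joint / nz
    pj_nz = pj[pj > 0]
    mu_d = float(np.sum(d) * p)
    mu_i = float(np.sum(i) * p)
    return {
        "DependenceEntropy": float(-np.sum(pj_nz * np.log2(pj_nz))),
        "DependenceNonUniformity": float(np.sum(col**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(col**2) / nz**2),
        "DependenceVariance": float(np.sum((d - mu_d) ** 2) * p),
        "GrayLevelNonUniformity": float(np.sum(row**2) / nz),
        "GrayLevelVariance": float(np.sum((i - mu_i) ** 2) * p),
        "HighGrayLevelEmphasis": float(np.sum(i**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(d**2) / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(i**2 * d**2) / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(d**2 / i**2) / nz),
        "LowGrayLevelEmphasis": float(np.sum(1.0 / i**2) / nz),
        "SmallDependenceEmphasis": float(np.sum(1.0 / d**2) / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(i**2 / d**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(1.0 / (i**2 * d**2)) / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_table(levels: np.ndarray, n_levels: int) -> tuple:
    """Per-level occurrence counts n_i and absolute-difference sums s_i."""
    mask = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=float)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for d in _ALL_26:
        src, dst = _shift_slices(levels.shape, d)
        valid = mask[dst]
        add_s = np.zeros_like(nb_sum)
        add_c = np.zeros_like(nb_cnt)
        add_s[src] = np.where(valid, levels[dst], 0).astype(float)
        add_c[src] = valid.astype(np.int64)
        nb_sum += add_s
        nb_cnt += add_c
    has_nb = mask & (nb_cnt > 0)
    lv = levels[has_nb]
    diff = np.abs(lv - nb_sum[has_nb] / nb_cnt[has_nb])
    n_i = np.bincount(levels[mask] - 1, minlength=n_levels).astype(float)
    s_i = np.zeros(n_levels)
    np.add.at(s_i, lv - 1, diff)
    return n_i, s_i


def ngtdm_features(levels, n_levels) -> dict:
    """The 5 neighbourhood gray-tone difference features."""
    n_i, s_i = ngtdm_table(levels, n_levels)
    n_vox = n_i.sum()
    if n_vox == 0:
        raise ValueError("mask is empty")
    p_i = n_i / n_vox
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, n_levels + 1, dtype=float)

    ip = i[present]
    pp = p_i[present]
    sp = s_i[present]

    # Coarseness (capped when the denominator vanishes)
    denom_c = float(np.sum(pp * sp))
    coarseness = 1.0 / denom_c if denom_c > 0 else 1e6

    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        contrast = (
            float(np.sum(pp[:, None] * pp[None, :] * di**2)) / (ngp * (ngp - 1))
        ) * (float(np.sum(sp)) / n_vox)
        busy_den = float(np.sum(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :])))
        busyness = denom_c / busy_den if busy_den > 0 else 0.0
        pisi = pp * sp
        complexity = float(
            np.sum(np.abs(di) * (pisi[:, None] + pisi[None, :]) / (pp[:, None] + pp[None, :]))
        ) / n_vox
        s_tot = float(np.sum(sp))
        strength = (
            float(np.sum((pp[:, None] + pp[None, :]) * di**2)) / s_tot if s_tot > 0 else 0.0
        )
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
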