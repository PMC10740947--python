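"""Independent brute-force oracles used to validate the vectorized code.

Everything here is deliberately written as plain Python loops over voxels,
pairs and runs, kept independent of the package's implementations.
"""

from __future__ import annotations

import itertools

import numpy as np

DIRECTIONS_13 = [d for d in itertools.product((-1, 0, 1), repeat=3)
                 if d != (0, 0, 0) and next(c for c in d if c != 0) > 0]
ALL_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _inside(shape, v):
    return all(0 <= v[a] < shape[a] for a in range(3))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix_oracle(levels, ng, direction, distance=1):
    p = np.zeros((ng, ng))
    d = tuple(distance * c for c in direction)
    for v in np.argwhere(levels > 0):
        w = tuple(v + d)
        if _inside(levels.shape, w) and levels[w] > 0:
            i, j = levels[tuple(v)] - 1, levels[w] - 1
            p[i, j] += 1
            p[j, i] += 1
    return p


def glcm_features_oracle(levels, ng, distance=1):
    per_dir = []
    for d in DIRECTIONS_13:
        raw = glcm_matrix_oracle(levels, ng, d, distance)
        if raw.sum() == 0:
            continue
        p = raw / raw.sum()
        per_dir.append(_glcm_feats_from_matrix(p))
    keys = per_dir[0].keys()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in keys}


def _glcm_feats_from_matrix(p):
    ng = p.shape[0]
    eps = np.spacing(1.0)
    out = {}
    mu = sum((i + 1) * p[i, j] for i in range(ng) for j in range(ng))
    sigma2 = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(ng) for j in range(ng))
    out["Autocorrelation"] = sum((i + 1) * (j + 1) * p[i, j]
                                 for i in range(ng) for j in range(ng))
    for name, power in (("ClusterTendency", 2), ("ClusterShade", 3),
                        ("ClusterProminence", 4)):
        out[name] = sum((i + 1 + j + 1 - 2 * mu) ** power * p[i, j]
                        for i in range(ng) for j in range(ng))
    out["Contrast"] = sum((i - j) ** 2 * p[i, j]
                          for i in range(ng) for j in range(ng))
    out["Correlation"] = (
        (out["Autocorrelation"] - mu * mu) / sigma2 if sigma2 > 0 else 1.0)
    pd_ = np.zeros(ng)
    ps = np.zeros(2 * ng - 1)
    for i in range(ng):
        for j in range(ng):
            pd_[abs(i - j)] += p[i, j]
            ps[i + j] += p[i, j]
    da = sum(k * pd_[k] for k in range(ng))
    out["DifferenceAverage"] = da
    out["DifferenceEntropy"] = -sum(v * np.log2(v) for v in pd_ if v > 0)
    out["DifferenceVariance"] = sum((k - da) ** 2 * pd_[k] for k in range(ng))
    out["Id"] = sum(p[i, j] / (1 + abs(i - j))
                    for i in range(ng) for j in range(ng))
    out["Idm"] = sum(p[i, j] / (1 + (i - j) ** 2)
                     for i in range(ng) for j in range(ng))
    out["Idmn"] = sum(p[i, j] / (1 + ((i - j) / ng) ** 2)
                      for i in range(ng) for j in range(ng))
    out["Idn"] = sum(p[i, j] / (1 + abs(i - j) / ng)
                     for i in range(ng) for j in range(ng))
    px = p.sum(axis=1)
    hxy = -sum(v * np.log2(v) for v in p.ravel() if v > 0)
    hx = -sum(v * np.log2(v) for v in px if v > 0)
    hxy1 = -sum(p[i, j] * np.log2(px[i] * px[j] + eps)
                for i in range(ng) for j in range(ng))
    hxy2 = -sum(px[i] * px[j] * np.log2(px[i] * px[j] + eps)
                for i in range(ng) for j in range(ng))
    out["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    out["Imc2"] = (np.sqrt(1 - np.exp(-2 * (hxy2 - hxy)))
                   if hxy2 >= hxy else 0.0)
    out["InverseVariance"] = sum(p[i, j] / (i - j) ** 2
                                 for i in range(ng) for j in range(ng) if i != j)
    out["JointAverage"] = mu
    out["JointEnergy"] = float((p ** 2).sum())
    out["JointEntropy"] = hxy
    if ng == 1:
        out["MCC"] = 1.0
    else:
        q = np.zeros((ng, ng))
        for i in range(ng):
            for j in range(ng):
                for k in range(ng):
                    if px[i] > 0 and px[k] > 0:
                        q[i, j] += p[i, k] * p[j, k] / (px[i] * px[k])
        ev = sorted(np.abs(np.linalg.eigvals(q)), reverse=True)
        out["MCC"] = float(np.sqrt(min(max(ev[1], 0.0), 1.0)))
    out["MaximumProbability"] = float(p.max())
    out["SumAverage"] = sum((k + 2) * ps[k] for k in range(2 * ng - 1))
    out["SumEntropy"] = -sum(v * np.log2(v) for v in ps if v > 0)
    out["SumSquares"] = sigma2
    return out


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_runs_oracle(levels, direction):
    """Walk every line in the direction, emitting (level, run_length)."""
    shape = levels.shape
    d = np.asarray(direction)
    runs = []
    for start in np.ndindex(shape):
        prev = tuple(np.asarray(start) - d)
        if _inside(shape, prev):
            continue  # not a line start
        v = np.asarray(start)
        cur_level, cur_len = 0, 0
        while _inside(shape, v):
            lv = levels[tuple(v)]
            if lv > 0 and lv == cur_level:
                cur_len += 1
            else:
                if cur_level > 0:
                    runs.append((cur_level, cur_len))
                cur_level, cur_len = lv, (1 if lv > 0 else 0)
            v = v + d
        if cur_level > 0:
            runs.append((cur_level, cur_len))
    return runs


def glrlm_features_oracle(levels, ng):
    n_vox = int((levels > 0).sum())
    per_dir = []
    for d in DIRECTIONS_13:
        runs = glrlm_runs_oracle(levels, d)
        per_dir.append(_rl_feats(runs, ng, n_vox))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def _rl_feats(pairs, ng, n_vox):
    nr = len(pairs)
    maxlen = max(j for _, j in pairs)
    P = np.zeros((ng, maxlen))
    for i, j in pairs:
        P[i - 1, j - 1] += 1
    pnorm = P / nr
    iv = np.arange(1, ng + 1, dtype=float)
    jv = np.arange(1, maxlen + 1, dtype=float)
    mu_i = sum(iv[i] * pnorm[i, j] for i in range(ng) for j in range(maxlen))
    mu_j = sum(jv[j] * pnorm[i, j] for i in range(ng) for j in range(maxlen))
    return {
        "GrayLevelNonUniformity": (P.sum(1) ** 2).sum() / nr,
        "GrayLevelNonUniformityNormalized": (P.sum(1) ** 2).sum() / nr**2,
        "GrayLevelVariance": sum((iv[i] - mu_i) ** 2 * pnorm[i, j]
                                 for i in range(ng) for j in range(maxlen)),
        "HighGrayLevelRunEmphasis": sum(iv[i] ** 2 * P[i, j] for i in range(ng)
                                        for j in range(maxlen)) / nr,
        "LongRunEmphasis": sum(jv[j] ** 2 * P[i, j] for i in range(ng)
                               for j in range(maxlen)) / nr,
        "LongRunHighGrayLevelEmphasis": sum(iv[i] ** 2 * jv[j] ** 2 * P[i, j]
                                            for i in range(ng)
                                            for j in range(maxlen)) / nr,
        "LongRunLowGrayLevelEmphasis": sum(jv[j] ** 2 / iv[i] ** 2 * P[i, j]
                                           for i in range(ng)
                                           for j in range(maxlen)) / nr,
        "LowGrayLevelRunEmphasis": sum(P[i, j] / iv[i] ** 2 for i in range(ng)
                                       for j in range(maxlen)) / nr,
        "RunEntropy": -sum(v * np.log2(v) for v in pnorm.ravel() if v > 0),
        "RunLengthNonUniformity": (P.sum(0) ** 2).sum() / nr,
        "RunLengthNonUniformityNormalized": (P.sum(0) ** 2).sum() / nr**2,
        "RunPercentage": nr / n_vox,
        "RunVariance": sum((jv[j] - mu_j) ** 2 * pnorm[i, j]
                           for i in range(ng) for j in range(maxlen)),
        "ShortRunEmphasis": sum(P[i, j] / jv[j] ** 2 for i in range(ng)
                                for j in range(maxlen)) / nr,
        "ShortRunHighGrayLevelEmphasis": sum(iv[i] ** 2 / jv[j] ** 2 * P[i, j]
                                             for i in range(ng)
                                             for j in range(maxlen)) / nr,
        "ShortRunLowGrayLevelEmphasis": sum(P[i, j] / (iv[i] ** 2 * jv[j] ** 2)
                                            for i in range(ng)
                                            for j in range(maxlen)) / nr,
    }


# ---------------------------------------------------------------------------
# GLSZM (flood fill), GLDM, NGTDM
# ---------------------------------------------------------------------------

def glszm_zones_oracle(levels, ng):
    seen = np.zeros(levels.shape, dtype=bool)
    zones = []
    for v0 in np.argwhere(levels > 0):
        v0 = tuple(v0)
        if seen[v0]:
            continue
        lv = levels[v0]
        stack, size = [v0], 0
        seen[v0] = True
        while stack:
            v = stack.pop()
            size += 1
            for d in ALL_26:
                w = tuple(np.asarray(v) + d)
                if (_inside(levels.shape, w) and not seen[w]
                        and levels[w] == lv):
                    seen[w] = True
                    stack.append(w)
        zones.append((int(lv), size))
    return zones


def glszm_features_oracle(levels, ng):
    zones = glszm_zones_oracle(levels, ng)
    n_vox = int((levels > 0).sum())
    nz = len(zones)
    iv = np.array([z[0] for z in zones], float)
    sv = np.array([z[1] for z in zones], float)
    row = np.zeros(ng)
    for lv, _ in zones:
        row[lv - 1] += 1
    col = np.zeros(int(sv.max()))
    for _, s in zones:
        col[s - 1] += 1
    joint = np.zeros((ng, int(sv.max())))
    for lv, s in zones:
        joint[lv - 1, s - 1] += 1
    pj = joint / nz
    return {
        "GrayLevelNonUniformity": (row**2).sum() / nz,
        "GrayLevelNonUniformityNormalized": (row**2).sum() / nz**2,
        "GrayLevelVariance": float(np.mean((iv - iv.mean()) ** 2)),
        "HighGrayLevelZoneEmphasis": float((iv**2).mean()),
        "LargeAreaEmphasis": float((sv**2).mean()),
        "LargeAreaHighGrayLevelEmphasis": float((iv**2 * sv**2).mean()),
        "LargeAreaLowGrayLevelEmphasis": float((sv**2 / iv**2).mean()),
        "LowGrayLevelZoneEmphasis": float((1 / iv**2).mean()),
        "SizeZoneNonUniformity": (col**2).sum() / nz,
        "SizeZoneNonUniformityNormalized": (col**2).sum() / nz**2,
        "SmallAreaEmphasis": float((1 / sv**2).mean()),
        "SmallAreaHighGrayLevelEmphasis": float((iv**2 / sv**2).mean()),
        "SmallAreaLowGrayLevelEmphasis": float((1 / (iv**2 * sv**2)).mean()),
        "ZoneEntropy": -sum(v * np.log2(v) for v in pj.ravel() if v > 0),
        "ZonePercentage": nz / n_vox,
        "ZoneVariance": float(np.mean((sv - sv.mean()) ** 2)),
    }


def gldm_features_oracle(levels, ng, alpha=0):
    pairs = []
    for v in np.argwhere(levels > 0):
        dep = 0
        for d in ALL_26:
            w = tuple(np.asarray(v) + d)
            if (_inside(levels.shape, w) and levels[w] > 0
                    and abs(int(levels[tuple(v)]) - int(levels[w])) <= alpha):
                dep += 1
        pairs.append((int(levels[tuple(v)]), dep))
    nz = len(pairs)
    iv = np.array([p[0] for p in pairs], float)
    dv = np.array([p[1] + 1 for p in pairs], float)  # size = count + 1
    row = np.zeros(ng)
    for lv, _ in pairs:
        row[lv - 1] += 1
    maxd = max(p[1] for p in pairs) + 1
    col = np.zeros(maxd)
    joint = np.zeros((ng, maxd))
    for lv, dep in pairs:
        col[dep] += 1
        joint[lv - 1, dep] += 1
    pj = joint / nz
    return {
        "DependenceEntropy": -sum(v * np.log2(v) for v in pj.ravel() if v > 0),
        "DependenceNonUniformity": (col**2).sum() / nz,
        "DependenceNonUniformityNormalized": (col**2).sum() / nz**2,
        "DependenceVariance": float(np.mean((dv - dv.mean()) ** 2)),
        "GrayLevelNonUniformity": (row**2).sum() / nz,
        "GrayLevelVariance": float(np.mean((iv - iv.mean()) ** 2)),
        "HighGrayLevelEmphasis": float((iv**2).mean()),
        "LargeDependenceEmphasis": float((dv**2).mean()),
        "LargeDependenceHighGrayLevelEmphasis": float((iv**2 * dv**2).mean()),
        "LargeDependenceLowGrayLevelEmphasis": float((dv**2 / iv**2).mean()),
        "LowGrayLevelEmphasis": float((1 / iv**2).mean()),
        "SmallDependenceEmphasis": float((1 / dv**2).mean()),
        "SmallDependenceHighGrayLevelEmphasis": float((iv**2 / dv**2).mean()),
        "SmallDependenceLowGrayLevelEmphasis": float((1 / (iv**2 * dv**2)).mean()),
    }


def ngtdm_features_oracle(levels, ng):
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    n_vox = 0
    for v in np.argwhere(levels > 0):
        lv = int(levels[tuple(v)])
        n_vox += 1
        n_i[lv - 1] += 1
        nb = []
        for d in ALL_26:
            w = tuple(np.asarray(v) + d)
            if _inside(levels.shape, w) and levels[w] > 0:
                nb.append(int(levels[w]))
        if nb:
            s_i[lv - 1] += abs(lv - np.mean(nb))
    p_i = n_i / n_vox
    present = np.flatnonzero(p_i > 0)
    ngp = len(present)
    denom = float(sum(p_i[i] * s_i[i] for i in present))
    coarseness = 1.0 / denom if denom > 0 else 1e6
    if ngp > 1:
        contrast = (sum(p_i[i] * p_i[j] * (i - j) ** 2
                        for i in present for j in present)
                    / (ngp * (ngp - 1))) * (s_i.sum() / n_vox)
        busy_den = sum(abs((i + 1) * p_i[i] - (j + 1) * p_i[j])
                       for i in present for j in present)
        busyness = denom / busy_den if busy_den > 0 else 0.0
        complexity = sum(abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j])
                         / (p_i[i] + p_i[j])
                         for i in present for j in present) / n_vox
        strength = (sum((p_i[i] + p_i[j]) * (i - j) ** 2
                        for i in present for j in present) / s_i.sum()
                    if s_i.sum() > 0 else 0.0)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"Busyness": busyness, "Coarseness": coarseness,
            "Complexity": complexity, "Contrast": contrast,
            "Strength": strength}


# ---------------------------------------------------------------------------
# ROC helpers
# ---------------------------------------------------------------------------

def auc_pair_count(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, labels):
    best = -np.inf
    for t in np.unique(np.concatenate([scores - 1e-9, scores + 1e-9])):
        pred = scores >= t
        tp = np.sum(pred & (labels == 1))
        fn = np.sum(~pred & (labels == 1))
        tn = np.sum(~pred & (labels == 0))
        fp = np.sum(pred & (labels == 0))
        j = tp / (tp + fn) + tn / (tn + fp) - 1
        best = max(best, j)
    return best


def bootstrap_paired_auc_var(scores_a, scores_b, labels, n_boot=2000, seed=0):
    """Stratified bootstrap variance of the paired AUC difference."""
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([rng.choice(pos, pos.size),
                              rng.choice(neg, neg.size)])
        y = labels[idx]
        diffs[b] = (auc_fast(scores_a[idx], y) - auc_fast(scores_b[idx], y))
    return float(np.var(diffs, ddof=1))


def auc_fast(scores, labels):
    from scipy.stats import rankdata

    pos = scores[labels == 1]
    neg = scores[labels == 0]
    r = rankdata(np.concatenate([pos, neg]))
    return (r[:pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)


def random_levels_grid(rng, shape=(5, 6, 4), ng=4, density=0.8):
    """Random discretized grid with a random mask (0 = outside)."""
    levels = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) < density
    if not mask.any():
        mask.flat[0] = True
    return np.where(mask, levels, 0)
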