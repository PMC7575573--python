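"""Independent brute-force oracles used by the test suite.

Everything here is written as plain per-voxel / per-entry Python loops,
deliberately sharing no code with the package implementation: texture
matrices are built by exhaustive pair/run/zone/neighborhood enumeration and
features are computed by direct sums over matrix entries.
"""

import math
from itertools import product

import numpy as np

OFFSETS_13 = [d for d in product((-1, 0, 1), repeat=3) if d > (0, 0, 0)]
OFFSETS_26 = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _inb(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


# ---------------------------------------------------------------------------
# Matrix construction by exhaustive enumeration
# ---------------------------------------------------------------------------

def glcm_oracle(levels):
    """Per-direction symmetric normalized GLCM via double loop over voxels."""
    shape = levels.shape
    nb = int(levels.max())
    mats = []
    for off in OFFSETS_13:
        mat = np.zeros((nb, nb))
        for p in product(*map(range, shape)):
            if levels[p] == 0:
                continue
            q = tuple(c + o for c, o in zip(p, off))
            if _inb(shape, q) and levels[q] > 0:
                mat[levels[p] - 1, levels[q] - 1] += 1
                mat[levels[q] - 1, levels[p] - 1] += 1
        mats.append(mat)
    return mats


def glrlm_oracle(levels):
    """Per-direction run-length matrix via naive line scanning."""
    shape = levels.shape
    nb = int(levels.max())
    max_len = max(shape)
    mats = []
    for off in OFFSETS_13:
        mat = np.zeros((nb, max_len))
        for p in product(*map(range, shape)):
            if levels[p] == 0:
                continue
            prev = tuple(c - o for c, o in zip(p, off))
            if _inb(shape, prev) and levels[prev] == levels[p]:
                continue  # not a run start
            length = 1
            q = tuple(c + o for c, o in zip(p, off))
            while _inb(shape, q) and levels[q] == levels[p]:
                length += 1
                q = tuple(c + o for c, o in zip(q, off))
            mat[levels[p] - 1, length - 1] += 1
        mats.append(mat)
    return mats


def glszm_oracle(levels):
    """Size-zone matrix via flood fill over 26-connected same-level zones."""
    shape = levels.shape
    nb = int(levels.max())
    n_vox = int((levels > 0).sum())
    mat = np.zeros((nb, n_vox))
    seen = np.zeros(shape, dtype=bool)
    for p in product(*map(range, shape)):
        if levels[p] == 0 or seen[p]:
            continue
        stack, zone = [p], []
        seen[p] = True
        while stack:
            c = stack.pop()
            zone.append(c)
            for off in OFFSETS_26:
                q = tuple(a + o for a, o in zip(c, off))
                if _inb(shape, q) and not seen[q] and levels[q] == levels[p]:
                    seen[q] = True
                    stack.append(q)
        mat[levels[p] - 1, len(zone) - 1] += 1
    return mat


def ngtdm_oracle(levels):
    """(n_i, s_i, N) via per-voxel neighborhood enumeration."""
    shape = levels.shape
    nb = int(levels.max())
    n_i = np.zeros(nb)
    s_i = np.zeros(nb)
    for p in product(*map(range, shape)):
        if levels[p] == 0:
            continue
        neigh = []
        for off in OFFSETS_26:
            q = tuple(a + o for a, o in zip(p, off))
            if _inb(shape, q) and levels[q] > 0:
                neigh.append(levels[q])
        if not neigh:
            continue
        n_i[levels[p] - 1] += 1
        s_i[levels[p] - 1] += abs(levels[p] - sum(neigh) / len(neigh))
    return n_i, s_i, n_i.sum()


def ngldm_oracle(levels):
    """Dependence matrix via per-voxel neighborhood enumeration."""
    shape = levels.shape
    nb = int(levels.max())
    mat = np.zeros((nb, 27))
    for p in product(*map(range, shape)):
        if levels[p] == 0:
            continue
        dep = 1
        for off in OFFSETS_26:
            q = tuple(a + o for a, o in zip(p, off))
            if _inb(shape, q) and levels[q] == levels[p]:
                dep += 1
        mat[levels[p] - 1, dep - 1] += 1
    return mat


# ---------------------------------------------------------------------------
# Features from matrices, by direct sums over entries
# ---------------------------------------------------------------------------

def glcm_features_oracle(levels):
    acc = {}
    n_used = 0
    for mat in glcm_oracle(levels):
        tot = mat.sum()
        if tot == 0:
            continue
        P = mat / tot
        nb = P.shape[0]
        px = [sum(P[i][j] for j in range(nb)) for i in range(nb)]
        py = [sum(P[i][j] for i in range(nb)) for j in range(nb)]
        mux = sum((i + 1) * px[i] for i in range(nb))
        muy = sum((j + 1) * py[j] for j in range(nb))
        sx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(nb)))
        sy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(nb)))
        pdiff = [0.0] * nb
        psum = [0.0] * (2 * nb - 1)
        for i in range(nb):
            for j in range(nb):
                pdiff[abs(i - j)] += P[i][j]
                psum[i + j] += P[i][j]
        da = sum(k * pdiff[k] for k in range(nb))
        sa = sum((k + 2) * psum[k] for k in range(2 * nb - 1))
        hxy = -sum(P[i][j] * math.log2(P[i][j])
                   for i in range(nb) for j in range(nb) if P[i][j] > 0)
        hxy1 = -sum(P[i][j] * math.log2(px[i] * py[j])
                    for i in range(nb) for j in range(nb)
                    if P[i][j] > 0 and px[i] * py[j] > 0)
        hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                    for i in range(nb) for j in range(nb) if px[i] * py[j] > 0)
        hx = -sum(p * math.log2(p) for p in px if p > 0)
        hy = -sum(p * math.log2(p) for p in py if p > 0)
        hmax = max(hx, hy)
        f = {
            "autocorrelation": sum((i + 1) * (j + 1) * P[i][j]
                                   for i in range(nb) for j in range(nb)),
            "joint_average": mux,
            "joint_variance": sum((i + 1 - mux) ** 2 * P[i][j]
                                  for i in range(nb) for j in range(nb)),
            "cluster_prominence": sum((i + j + 2 - mux - muy) ** 4 * P[i][j]
                                      for i in range(nb) for j in range(nb)),
            "cluster_shade": sum((i + j + 2 - mux - muy) ** 3 * P[i][j]
                                 for i in range(nb) for j in range(nb)),
            "cluster_tendency": sum((i + j + 2 - mux - muy) ** 2 * P[i][j]
                                    for i in range(nb) for j in range(nb)),
            "contrast": sum((i - j) ** 2 * P[i][j]
                            for i in range(nb) for j in range(nb)),
            "correlation": ((sum((i + 1) * (j + 1) * P[i][j]
                                 for i in range(nb) for j in range(nb))
                             - mux * muy) / (sx * sy)
                            if sx > 0 and sy > 0 else 0.0),
            "difference_average": da,
            "difference_entropy": -sum(p * math.log2(p) for p in pdiff if p > 0),
            "difference_variance": sum((k - da) ** 2 * pdiff[k]
                                       for k in range(nb)),
            "joint_energy": sum(P[i][j] ** 2
                                for i in range(nb) for j in range(nb)),
            "joint_entropy": hxy,
            "inverse_difference": sum(P[i][j] / (1 + abs(i - j))
                                      for i in range(nb) for j in range(nb)),
            "inverse_difference_moment": sum(P[i][j] / (1 + (i - j) ** 2)
                                             for i in range(nb)
                                             for j in range(nb)),
            "idmn": sum(P[i][j] / (1 + ((i - j) / nb) ** 2)
                        for i in range(nb) for j in range(nb)),
            "idn": sum(P[i][j] / (1 + abs(i - j) / nb)
                       for i in range(nb) for j in range(nb)),
            "imc1": (hxy - hxy1) / hmax if hmax > 0 else 0.0,
            "imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))),
            "inverse_variance": sum(P[i][j] / (i - j) ** 2
                                    for i in range(nb) for j in range(nb)
                                    if i != j),
            "maximum_probability": max(P[i][j] for i in range(nb)
                                       for j in range(nb)),
            "sum_average": sa,
            "sum_entropy": -sum(p * math.log2(p) for p in psum if p > 0),
            "sum_variance": sum((k + 2 - sa) ** 2 * psum[k]
                                for k in range(2 * nb - 1)),
        }
        for k, v in f.items():
            acc[k] = acc.get(k, 0.0) + v
        n_used += 1
    return {k: v / n_used for k, v in acc.items()}


def _rl_sz_features(mat, n_vox, kind):
    """Shared run-length / size-zone formulas from a (level x size) matrix."""
    nr = mat.sum()
    ng, nl = mat.shape
    ri = [sum(mat[i][j] for j in range(nl)) for i in range(ng)]
    rj = [sum(mat[i][j] for i in range(ng)) for j in range(nl)]
    mu_g = sum((i + 1) * mat[i][j] for i in range(ng) for j in range(nl)) / nr
    mu_l = sum((j + 1) * mat[i][j] for i in range(ng) for j in range(nl)) / nr
    ent = -sum(mat[i][j] / nr * math.log2(mat[i][j] / nr)
               for i in range(ng) for j in range(nl) if mat[i][j] > 0)
    vals = [
        sum(rj[j] / (j + 1) ** 2 for j in range(nl)) / nr,
        sum(rj[j] * (j + 1) ** 2 for j in range(nl)) / nr,
        sum(r ** 2 for r in ri) / nr,
        sum(r ** 2 for r in ri) / nr ** 2,
        sum(r ** 2 for r in rj) / nr,
        sum(r ** 2 for r in rj) / nr ** 2,
        nr / n_vox,
        sum((i + 1 - mu_g) ** 2 * mat[i][j] for i in range(ng)
            for j in range(nl)) / nr,
        sum((j + 1 - mu_l) ** 2 * mat[i][j] for i in range(ng)
            for j in range(nl)) / nr,
        ent,
        sum(ri[i] / (i + 1) ** 2 for i in range(ng)) / nr,
        sum(ri[i] * (i + 1) ** 2 for i in range(ng)) / nr,
        sum(mat[i][j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng)
            for j in range(nl)) / nr,
        sum(mat[i][j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng)
            for j in range(nl)) / nr,
        sum(mat[i][j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng)
            for j in range(nl)) / nr,
        sum(mat[i][j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng)
            for j in range(nl)) / nr,
    ]
    if kind == "rlm":
        names = ["short_run_emphasis", "long_run_emphasis",
                 "gray_level_nonuniformity",
                 "gray_level_nonuniformity_normalized",
                 "run_length_nonuniformity",
                 "run_length_nonuniformity_normalized", "run_percentage",
                 "gray_level_variance", "run_length_variance", "run_entropy",
                 "low_gray_level_run_emphasis", "high_gray_level_run_emphasis",
                 "short_run_low_gray_level_emphasis",
                 "short_run_high_gray_level_emphasis",
                 "long_run_low_gray_level_emphasis",
                 "long_run_high_gray_level_emphasis"]
    else:
        names = ["small_area_emphasis", "large_area_emphasis",
                 "gray_level_nonuniformity",
                 "gray_level_nonuniformity_normalized",
                 "size_zone_nonuniformity",
                 "size_zone_nonuniformity_normalized", "zone_percentage",
                 "gray_level_variance", "zone_variance", "zone_entropy",
                 "low_gray_level_zone_emphasis", "high_gray_level_zone_emphasis",
                 "small_area_low_gray_level_emphasis",
                 "small_area_high_gray_level_emphasis",
                 "large_area_low_gray_level_emphasis",
                 "large_area_high_gray_level_emphasis"]
    return dict(zip(names, vals))


def glrlm_features_oracle(levels):
    n_vox = int((levels > 0).sum())
    mats = glrlm_oracle(levels)
    acc = {}
    for mat in mats:
        f = _rl_sz_features(mat, n_vox, "rlm")
        for k, v in f.items():
            acc[k] = acc.get(k, 0.0) + v
    return {k: v / len(mats) for k, v in acc.items()}


def glszm_features_oracle(levels):
    n_vox = int((levels > 0).sum())
    return _rl_sz_features(glszm_oracle(levels), n_vox, "szm")


def ngtdm_features_oracle(levels, degenerate_coarseness=1.0e6):
    n_i, s_i, N = ngtdm_oracle(levels)
    nb = len(n_i)
    p = n_i / N
    present = [i for i in range(nb) if p[i] > 0]
    ngp = len(present)
    denom = sum(p[i] * s_i[i] for i in range(nb))
    coarse = 1 / denom if denom > 0 else degenerate_coarseness
    if ngp > 1:
        contrast = (sum(p[i] * p[j] * (i - j) ** 2
                        for i in present for j in present)
                    / (ngp * (ngp - 1)) * s_i.sum() / N)
    else:
        contrast = 0.0
    busy_den = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                   for i in present for j in present)
    busy = denom / busy_den if busy_den > 0 else 0.0
    cplx = sum(abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
               for i in present for j in present) / N
    strength = (sum((p[i] + p[j]) * (i - j) ** 2
                    for i in present for j in present) / s_i.sum()
                if s_i.sum() > 0 else 0.0)
    return {"coarseness": coarse, "contrast": contrast, "busyness": busy,
            "complexity": cplx, "strength": strength}


def ngldm_features_oracle(levels):
    mat = ngldm_oracle(levels)
    ns = mat.sum()
    ng, nd = mat.shape
    mi = [sum(mat[i][j] for j in range(nd)) for i in range(ng)]
    mj = [sum(mat[i][j] for i in range(ng)) for j in range(nd)]
    mu_g = sum((i + 1) * mat[i][j] for i in range(ng) for j in range(nd)) / ns
    mu_d = sum((j + 1) * mat[i][j] for i in range(ng) for j in range(nd)) / ns
    ent = -sum(mat[i][j] / ns * math.log2(mat[i][j] / ns)
               for i in range(ng) for j in range(nd) if mat[i][j] > 0)
    return {
        "small_dependence_emphasis":
            sum(mj[j] / (j + 1) ** 2 for j in range(nd)) / ns,
        "large_dependence_emphasis":
            sum(mj[j] * (j + 1) ** 2 for j in range(nd)) / ns,
        "gray_level_nonuniformity": sum(m ** 2 for m in mi) / ns,
        "dependence_nonuniformity": sum(m ** 2 for m in mj) / ns,
        "dependence_nonuniformity_normalized":
            sum(m ** 2 for m in mj) / ns ** 2,
        "gray_level_variance":
            sum((i + 1 - mu_g) ** 2 * mat[i][j]
                for i in range(ng) for j in range(nd)) / ns,
        "dependence_variance":
            sum((j + 1 - mu_d) ** 2 * mat[i][j]
                for i in range(ng) for j in range(nd)) / ns,
        "dependence_entropy": ent,
        "low_gray_level_emphasis":
            sum(mi[i] / (i + 1) ** 2 for i in range(ng)) / ns,
        "high_gray_level_emphasis":
            sum(mi[i] * (i + 1) ** 2 for i in range(ng)) / ns,
        "small_dependence_low_gray_level_emphasis":
            sum(mat[i][j] / ((i + 1) ** 2 * (j + 1) ** 2)
                for i in range(ng) for j in range(nd)) / ns,
        "small_dependence_high_gray_level_emphasis":
            sum(mat[i][j] * (i + 1) ** 2 / (j + 1) ** 2
                for i in range(ng) for j in range(nd)) / ns,
    }


FAMILY_ORACLES = {
    "glcm": glcm_features_oracle,
    "glrlm": glrlm_features_oracle,
    "glszm": glszm_features_oracle,
    "ngtdm": ngtdm_features_oracle,
    "ngldm": ngldm_features_oracle,
}


# ---------------------------------------------------------------------------
# Geometry oracles
# ---------------------------------------------------------------------------

def lattice_ball_count(radius_mm, spacing=(1.0, 1.0, 1.0)):
    """Number of lattice points with ||x * spacing|| <= radius."""
    nmax = [int(math.floor(radius_mm / s)) for s in spacing]
    count = 0
    for x in range(-nmax[0], nmax[0] + 1):
        for y in range(-nmax[1], nmax[1] + 1):
            for z in range(-nmax[2], nmax[2] + 1):
                d2 = (x * spacing[0]) ** 2 + (y * spacing[1]) ** 2 \
                     + (z * spacing[2]) ** 2
                if d2 <= radius_mm ** 2 + 1e-9:
                    count += 1
    return count


def dilate_oracle(mask, margin_mm, spacing=(1.0, 1.0, 1.0)):
    """Brute-force metric dilation: all-pairs distance check."""
    fg = np.argwhere(mask > 0).astype(float) * np.asarray(spacing)
    out = np.zeros_like(mask, dtype=np.uint8)
    for p in product(*map(range, mask.shape)):
        pw = np.asarray(p, float) * np.asarray(spacing)
        d2 = np.sum((fg - pw) ** 2, axis=1).min()
        if d2 <= margin_mm ** 2 + 1e-9:
            out[p] = 1
    return out


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------

def delong_variance_oracle(scores, labels):
    """Placement-value covariance formula computed with explicit loops."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos = [v for v, t in zip(s, y) if t == 1]
    neg = [v for v, t in zip(s, y) if t == 0]
    m, n = len(pos), len(neg)

    def psi(a, b):
        return 1.0 if a > b else (0.5 if a == b else 0.0)

    v10 = [sum(psi(a, b) for b in neg) / n for a in pos]
    v01 = [sum(psi(a, b) for a in pos) / m for b in neg]
    mean10 = sum(v10) / m
    mean01 = sum(v01) / n
    s10 = sum((v - mean10) ** 2 for v in v10) / (m - 1) if m > 1 else 0.0
    s01 = sum((v - mean01) ** 2 for v in v01) / (n - 1) if n > 1 else 0.0
    return s10 / m + s01 / n


def bh_adjust_oracle(pvals):
    """Step-up FDR adjustment: p_(i) * m / i with cumulative minima."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj
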