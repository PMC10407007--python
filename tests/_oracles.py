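"""Independent brute-force reference implementations used only by the tests.

Everything here is written as plain nested loops over tiny arrays, on
purpose: these oracles share no code with the package's vectorized
implementations, so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import math

import numpy as np

# 13 direction offsets, same canonical set as the package advertises
OFFSETS_3D = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


def quantize_fbn(arr, mask, L):
    vals = arr[mask]
    lo, hi = vals.min(), vals.max()
    lev = np.zeros(arr.shape, dtype=int)
    if hi == lo:
        lev[mask] = 1
        return lev
    for idx in np.ndindex(arr.shape):
        if mask[idx]:
            lev[idx] = min(int(L * (arr[idx] - lo) / (hi - lo)) + 1, L)
    return lev


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix_2d(lev, offset, symmetric=True):
    """Pair counts by explicit loop over every pixel."""
    L = int(lev.max())
    H, W = lev.shape
    dr, dc = offset
    M = np.zeros((L, L))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                M[lev[r, c] - 1, lev[r2, c2] - 1] += 1
    if symmetric:
        M = M + M.T
    return M


def glcm_matrix_3d(lev, mask, offset, L):
    M = np.zeros((L, L))
    for idx in np.ndindex(lev.shape):
        if not mask[idx]:
            continue
        jdx = tuple(i + o for i, o in zip(idx, offset))
        if all(0 <= j < s for j, s in zip(jdx, lev.shape)) and mask[jdx]:
            M[lev[idx] - 1, lev[jdx] - 1] += 1
    return M + M.T


def haralick_oracle(P):
    """Textbook double-loop Haralick-14 on a normalized symmetric matrix
    (natural log), matching the package's published roster."""
    L = P.shape[0]
    px = [sum(P[i][j] for j in range(L)) for i in range(L)]
    py = [sum(P[i][j] for i in range(L)) for j in range(L)]
    mu_x = sum((i + 1) * px[i] for i in range(L))
    mu_y = sum((j + 1) * py[j] for j in range(L))
    var_x = sum(px[i] * (i + 1 - mu_x) ** 2 for i in range(L))
    var_y = sum(py[j] * (j + 1 - mu_y) ** 2 for j in range(L))
    energy = sum(P[i][j] ** 2 for i in range(L) for j in range(L))
    contrast = sum(P[i][j] * (i - j) ** 2 for i in range(L) for j in range(L))
    cov = sum(P[i][j] * (i + 1) * (j + 1) for i in range(L) for j in range(L)) \
        - mu_x * mu_y
    sd = math.sqrt(var_x * var_y)
    correlation = cov / sd if sd > 1e-12 else 1.0
    variance = sum(P[i][j] * (i + 1 - mu_x) ** 2
                   for i in range(L) for j in range(L))
    idm = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    p_sum = [0.0] * (2 * L + 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j + 2] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]

    def ent(ps):
        return -sum(p * math.log(p) for p in ps if p > 0)

    sum_avg = sum(k * p_sum[k] for k in range(2, 2 * L + 1))
    sum_var = sum(p_sum[k] * (k - sum_avg) ** 2 for k in range(2, 2 * L + 1))
    diff_avg = sum(k * p_diff[k] for k in range(L))
    diff_var = sum(p_diff[k] * (k - diff_avg) ** 2 for k in range(L))
    entropy = ent([P[i][j] for i in range(L) for j in range(L)])
    hx, hy = ent(px), ent(py)
    hxy1 = -sum(P[i][j] * math.log(px[i] * py[j])
                for i in range(L) for j in range(L)
                if P[i][j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log(px[i] * py[j])
                for i in range(L) for j in range(L) if px[i] * py[j] > 0)
    hmax = max(hx, hy)
    imc1 = (entropy - hxy1) / hmax if hmax > 1e-12 else 0.0
    imc2 = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - entropy))))
    return {
        "Energy": energy, "Contrast": contrast, "Correlation": correlation,
        "Variance": variance, "IDM": idm, "SumAvg": sum_avg, "SumVar": sum_var,
        "SumEntropy": ent(p_sum), "Entropy": entropy, "DiffAvg": diff_avg,
        "DiffVar": diff_var, "DiffEntropy": ent(p_diff),
        "IMC1": imc1, "IMC2": imc2,
    }


def glcm25_oracle(M):
    """Loop-based IBSI 25-feature set from a (possibly unnormalized) symmetric
    co-occurrence count matrix; log base 2."""
    total = M.sum()
    L = M.shape[0]
    P = M / total
    px = [sum(P[i][j] for j in range(L)) for i in range(L)]
    mu = sum((i + 1) * px[i] for i in range(L))
    sig2 = sum(px[i] * (i + 1 - mu) ** 2 for i in range(L))
    p_sum = [0.0] * (2 * L + 1)
    p_diff = [0.0] * L
    for i in range(L):
        for j in range(L):
            p_sum[i + j + 2] += P[i][j]
            p_diff[abs(i - j)] += P[i][j]

    def ent2(ps):
        return -sum(p * math.log2(p) for p in ps if p > 0)

    diff_avg = sum(k * p_diff[k] for k in range(L))
    sum_avg = sum(k * p_sum[k] for k in range(2, 2 * L + 1))
    joint_entropy = ent2([P[i][j] for i in range(L) for j in range(L)])
    hx = ent2(px)
    hxy1 = -sum(P[i][j] * math.log2(px[i] * px[j])
                for i in range(L) for j in range(L)
                if P[i][j] > 0 and px[i] * px[j] > 0)
    hxy2 = -sum(px[i] * px[j] * math.log2(px[i] * px[j])
                for i in range(L) for j in range(L) if px[i] * px[j] > 0)
    corr = (sum(P[i][j] * (i + 1) * (j + 1) for i in range(L) for j in range(L))
            - mu * mu) / sig2 if sig2 > 0 else 1.0
    out = {
        "JointMax": max(P[i][j] for i in range(L) for j in range(L)),
        "JointAvg": sum(P[i][j] * (i + 1) for i in range(L) for j in range(L)),
        "JointVar": sum(P[i][j] * (i + 1 - mu) ** 2
                        for i in range(L) for j in range(L)),
        "JointEntropy": joint_entropy,
        "DiffAvg": diff_avg,
        "DiffVar": sum(p_diff[k] * (k - diff_avg) ** 2 for k in range(L)),
        "DiffEntropy": ent2(p_diff),
        "SumAvg": sum_avg,
        "SumVar": sum(p_sum[k] * (k - sum_avg) ** 2
                      for k in range(2, 2 * L + 1)),
        "SumEntropy": ent2(p_sum),
        "Energy": sum(P[i][j] ** 2 for i in range(L) for j in range(L)),
        "Contrast": sum(P[i][j] * (i - j) ** 2
                        for i in range(L) for j in range(L)),
        "Dissimilarity": sum(P[i][j] * abs(i - j)
                             for i in range(L) for j in range(L)),
        "InvDiff": sum(P[i][j] / (1 + abs(i - j))
                       for i in range(L) for j in range(L)),
        "InvDiffNorm": sum(P[i][j] / (1 + abs(i - j) / L)
                           for i in range(L) for j in range(L)),
        "InvDiffMom": sum(P[i][j] / (1 + (i - j) ** 2)
                          for i in range(L) for j in range(L)),
        "InvDiffMomNorm": sum(P[i][j] / (1 + (i - j) ** 2 / L ** 2)
                              for i in range(L) for j in range(L)),
        "InvVariance": sum(P[i][j] / (i - j) ** 2
                           for i in range(L) for j in range(L) if i != j),
        "Correlation": corr,
        "Autocorrelation": sum(P[i][j] * (i + 1) * (j + 1)
                               for i in range(L) for j in range(L)),
        "ClusterTendency": sum(P[i][j] * (i + j + 2 - 2 * mu) ** 2
                               for i in range(L) for j in range(L)),
        "ClusterShade": sum(P[i][j] * (i + j + 2 - 2 * mu) ** 3
                            for i in range(L) for j in range(L)),
        "ClusterProminence": sum(P[i][j] * (i + j + 2 - 2 * mu) ** 4
                                 for i in range(L) for j in range(L)),
        "IMC1": (joint_entropy - hxy1) / hx if hx > 0 else 0.0,
        "IMC2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - joint_entropy)))),
    }
    return out


# ---------------------------------------------------------------------------
# Run / zone / dependence matrices
# ---------------------------------------------------------------------------

def run_matrix_oracle(lev, mask, offset, L):
    """Run lengths by explicitly walking every maximal line of the grid."""
    shape = lev.shape
    runs = []
    starts = []
    for idx in np.ndindex(shape):
        prev = tuple(i - o for i, o in zip(idx, offset))
        if not all(0 <= p < s for p, s in zip(prev, shape)):
            starts.append(idx)
    for start in starts:
        line = []
        idx = start
        while all(0 <= i < s for i, s in zip(idx, shape)):
            line.append(idx)
            idx = tuple(i + o for i, o in zip(idx, offset))
        current_level, length = None, 0
        for pos in line:
            if mask[pos]:
                g = lev[pos]
                if g == current_level:
                    length += 1
                else:
                    if current_level is not None:
                        runs.append((current_level, length))
                    current_level, length = g, 1
            else:
                if current_level is not None:
                    runs.append((current_level, length))
                current_level, length = None, 0
        if current_level is not None:
            runs.append((current_level, length))
    max_len = max((l for _, l in runs), default=1)
    M = np.zeros((L, max_len))
    for g, l in runs:
        M[g - 1, l - 1] += 1
    return M


def zones_oracle(lev, mask, connectivity_full=True):
    """Connected equal-level zones by breadth-first search (26/8-conn)."""
    nd = lev.ndim
    neigh = [off for off in np.ndindex(*(3,) * nd)
             if any(o != 1 for o in off)]
    neigh = [tuple(o - 1 for o in off) for off in neigh]
    seen = np.zeros(lev.shape, bool)
    zones = []
    for idx in np.ndindex(lev.shape):
        if mask[idx] and not seen[idx]:
            g = lev[idx]
            stack, members = [idx], []
            seen[idx] = True
            while stack:
                cur = stack.pop()
                members.append(cur)
                for off in neigh:
                    nxt = tuple(c + o for c, o in zip(cur, off))
                    if all(0 <= v < s for v, s in zip(nxt, lev.shape)) \
                            and mask[nxt] and not seen[nxt] and lev[nxt] == g:
                        seen[nxt] = True
                        stack.append(nxt)
            zones.append((int(g), members))
    return zones


def szm_oracle(lev, mask, L):
    zones = zones_oracle(lev, mask)
    max_size = max((len(m) for _, m in zones), default=1)
    M = np.zeros((L, max_size))
    for g, members in zones:
        M[g - 1, len(members) - 1] += 1
    return M


def dzm_oracle(lev, mask, L):
    """Distance-zone matrix with per-voxel Chebyshev border distance computed
    by brute-force search over all outside positions (including the virtual
    border just outside the grid)."""
    shape = lev.shape

    def border_distance(idx):
        best = min(min(i + 1, s - i) for i, s in zip(idx, shape))
        for jdx in np.ndindex(shape):
            if not mask[jdx]:
                d = max(abs(a - b) for a, b in zip(idx, jdx))
                best = min(best, d)
        return best

    zones = zones_oracle(lev, mask)
    dists = [min(border_distance(m) for m in members) for _, members in zones]
    M = np.zeros((L, max(max(dists, default=1), 1)))
    for (g, _), d in zip(zones, dists):
        M[g - 1, d - 1] += 1
    return M


def ngtdm_oracle(lev, mask, L):
    """(n_i, s_i, n_valid) by per-voxel neighbour loops."""
    nd = lev.ndim
    neigh = [tuple(o - 1 for o in off) for off in np.ndindex(*(3,) * nd)
             if any(o != 1 for o in off)]
    n = np.zeros(L)
    s = np.zeros(L)
    nvc = 0
    for idx in np.ndindex(lev.shape):
        if not mask[idx]:
            continue
        vals = []
        for off in neigh:
            jdx = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= v < sz for v, sz in zip(jdx, lev.shape)) and mask[jdx]:
                vals.append(lev[jdx])
        if not vals:
            continue
        nvc += 1
        g = lev[idx]
        n[g - 1] += 1
        s[g - 1] += abs(g - sum(vals) / len(vals))
    return n, s, nvc


def ngldm_oracle(lev, mask, L, alpha=0):
    nd = lev.ndim
    neigh = [tuple(o - 1 for o in off) for off in np.ndindex(*(3,) * nd)
             if any(o != 1 for o in off)]
    entries = []
    for idx in np.ndindex(lev.shape):
        if not mask[idx]:
            continue
        k = 0
        for off in neigh:
            jdx = tuple(i + o for i, o in zip(idx, off))
            if all(0 <= v < sz for v, sz in zip(jdx, lev.shape)) and mask[jdx] \
                    and abs(int(lev[jdx]) - int(lev[idx])) <= alpha:
                k += 1
        entries.append((int(lev[idx]), k))
    kmax = max(k for _, k in entries)
    M = np.zeros((L, kmax + 1))
    for g, k in entries:
        M[g - 1, k] += 1
    return M


def matrix_stats_oracle(M, cols, n_voxels, names):
    """The shared 16 distribution-matrix statistics as plain loops."""
    L, W = M.shape
    Ns = M.sum()
    out = {}
    vals = []
    vals.append(sum(M[i][j] / cols[j] ** 2 for i in range(L) for j in range(W)) / Ns)
    vals.append(sum(M[i][j] * cols[j] ** 2 for i in range(L) for j in range(W)) / Ns)
    vals.append(sum(M[i][j] / (i + 1) ** 2 for i in range(L) for j in range(W)) / Ns)
    vals.append(sum(M[i][j] * (i + 1) ** 2 for i in range(L) for j in range(W)) / Ns)
    vals.append(sum(M[i][j] / ((i + 1) ** 2 * cols[j] ** 2)
                    for i in range(L) for j in range(W)) / Ns)
    vals.append(sum(M[i][j] * cols[j] ** 2 / (i + 1) ** 2
                    for i in range(L) for j in range(W)) / Ns)
    vals.append(sum(M[i][j] * (i + 1) ** 2 / cols[j] ** 2
                    for i in range(L) for j in range(W)) / Ns)
    vals.append(sum(M[i][j] * (i + 1) ** 2 * cols[j] ** 2
                    for i in range(L) for j in range(W)) / Ns)
    row_sums = [sum(M[i][j] for j in range(W)) for i in range(L)]
    col_sums = [sum(M[i][j] for i in range(L)) for j in range(W)]
    vals.append(sum(r ** 2 for r in row_sums) / Ns)
    vals.append(sum(r ** 2 for r in row_sums) / Ns ** 2)
    vals.append(sum(c ** 2 for c in col_sums) / Ns)
    vals.append(sum(c ** 2 for c in col_sums) / Ns ** 2)
    vals.append(Ns / n_voxels)
    mu_i = sum(M[i][j] / Ns * (i + 1) for i in range(L) for j in range(W))
    mu_j = sum(M[i][j] / Ns * cols[j] for i in range(L) for j in range(W))
    vals.append(sum(M[i][j] / Ns * (i + 1 - mu_i) ** 2
                    for i in range(L) for j in range(W)))
    vals.append(sum(M[i][j] / Ns * (cols[j] - mu_j) ** 2
                    for i in range(L) for j in range(W)))
    vals.append(-sum(M[i][j] / Ns * math.log2(M[i][j] / Ns)
                     for i in range(L) for j in range(W) if M[i][j] > 0))
    return dict(zip(names, vals))


def ngtdm_stats_oracle(n, s, nvc, eps=1e-12):
    L = len(n)
    p = [ni / nvc for ni in n]
    present = [i for i in range(L) if p[i] > 0]
    ng = len(present)
    coarseness = 1.0 / (sum(p[i] * s[i] for i in range(L)) + eps)
    if ng > 1:
        contrast = sum(p[i] * p[j] * (i - j) ** 2
                       for i in present for j in present) \
            / (ng * (ng - 1)) * sum(s) / nvc
        den = sum(abs((i + 1) * p[i] - (j + 1) * p[j])
                  for i in present for j in present)
        busyness = sum(p[i] * s[i] for i in range(L)) / den if den > 0 else 0.0
        complexity = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                         for i in present for j in present) / nvc
        strength = sum((p[i] + p[j]) * (i - j) ** 2
                       for i in present for j in present) / (sum(s) + eps)
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "NGTDM_Coarseness": coarseness, "NGTDM_Contrast": contrast,
        "NGTDM_Busyness": busyness, "NGTDM_Complexity": complexity,
        "NGTDM_Strength": strength,
    }
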