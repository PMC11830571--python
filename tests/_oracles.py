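"""Independent brute-force oracles.

Every function here recomputes a metric or statistic by direct,
unoptimized enumeration — per-cell loops, explicit rank tables,
explicit Gower centering — so the main implementations can be checked
against code that shares none of their structure.
"""

import itertools
import math

import numpy as np


# ------------------------------------------------------------- canopy

def quantile_linear(values, q):
    """Linear-interpolation quantile via explicit order statistics."""
    v = sorted(values)
    n = len(v)
    pos = q * (n - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def pop_sd(values):
    v = list(values)
    m = sum(v) / len(v)
    return math.sqrt(sum((x - m) ** 2 for x in v) / len(v))


def entropy_bins(heights, dz=1.0, min_height=0.5):
    """-sum p ln p over dz bins of vegetated heights, by dict counting."""
    veg = [h for h in heights if h >= min_height]
    if not veg:
        return 0.0, 0
    counts = {}
    for h in veg:
        counts[int((h - min_height) // dz)] = counts.get(int((h - min_height) // dz), 0) + 1
    n_bins = max(counts) + 1
    total = sum(counts.values())
    e = -sum((c / total) * math.log(c / total) for c in counts.values())
    return e, n_bins


def vai_slices(heights, dz=1.0, k=0.5):
    """Slice-by-slice occupancy attenuation, scalar loop."""
    hs = list(heights)
    if not hs or max(hs) <= 0:
        return 0.0
    n_slices = int(math.ceil(max(hs) / dz - 1e-12))
    total = 0.0
    for s in range(n_slices):
        z = s * dz
        occ = sum(1 for h in hs if h > z) / len(hs)
        total += -math.log(1.0 - occ * (1.0 - math.exp(-k * dz))) / (k * dz)
    return total


def triangle_area_3d(a, b, c):
    ab = [b[i] - a[i] for i in range(3)]
    ac = [c[i] - a[i] for i in range(3)]
    cx = ab[1] * ac[2] - ab[2] * ac[1]
    cy = ab[2] * ac[0] - ab[0] * ac[2]
    cz = ab[0] * ac[1] - ab[1] * ac[0]
    return 0.5 * math.sqrt(cx * cx + cy * cy + cz * cz)


def rumple_surface(z, cell):
    """Triangulated surface / ground area with explicit per-square loop,
    diagonal from (i, j) to (i+1, j+1)."""
    nr, nc = z.shape
    surface = 0.0
    for i in range(nr - 1):
        for j in range(nc - 1):
            p00 = (j * cell, i * cell, z[i, j])
            p01 = ((j + 1) * cell, i * cell, z[i, j + 1])
            p10 = (j * cell, (i + 1) * cell, z[i + 1, j])
            p11 = ((j + 1) * cell, (i + 1) * cell, z[i + 1, j + 1])
            surface += triangle_area_3d(p00, p10, p11)
            surface += triangle_area_3d(p00, p01, p11)
    return surface / ((nr - 1) * (nc - 1) * cell * cell)


# ------------------------------------------------------------- terrain

def horn_slope_mean(z, cell):
    """Mean Horn slope (deg) with an explicit per-window loop."""
    nr, nc = z.shape
    slopes = []
    for i in range(1, nr - 1):
        for j in range(1, nc - 1):
            w = z[i - 1 : i + 2, j - 1 : j + 2]
            dzdx = ((w[0, 2] + 2 * w[1, 2] + w[2, 2]) - (w[0, 0] + 2 * w[1, 0] + w[2, 0])) / (8 * cell)
            dzdy = ((w[2, 0] + 2 * w[2, 1] + w[2, 2]) - (w[0, 0] + 2 * w[0, 1] + w[0, 2])) / (8 * cell)
            slopes.append(math.degrees(math.atan(math.hypot(dzdx, dzdy))))
    return sum(slopes) / len(slopes)


def tri_mean_abs(z):
    nr, nc = z.shape
    vals = []
    for i in range(1, nr - 1):
        for j in range(1, nc - 1):
            diffs = [
                abs(z[i, j] - z[i + di, j + dj])
                for di in (-1, 0, 1)
                for dj in (-1, 0, 1)
                if (di, dj) != (0, 0)
            ]
            vals.append(sum(diffs) / 8.0)
    return sum(vals) / len(vals)


def roughness_range(z):
    nr, nc = z.shape
    vals = []
    for i in range(1, nr - 1):
        for j in range(1, nc - 1):
            w = [z[i + di, j + dj] for di in (-1, 0, 1) for dj in (-1, 0, 1)]
            vals.append(max(w) - min(w))
    return sum(vals) / len(vals)


# ----------------------------------------------------------- statistics

def rank_midranks(x):
    """Mid-ranks with explicit tie averaging."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def spearman_rho(x, y):
    return pearson(rank_midranks(list(x)), rank_midranks(list(y)))


def bray_curtis_pair(x, y):
    shared = sum(min(a, b) for a, b in zip(x, y))
    return 1.0 - 2.0 * shared / (sum(x) + sum(y))


def anosim_r(dist, groups):
    """Clarke's R from explicit pair lists."""
    n = len(groups)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dvals = [dist[i][j] for i, j in pairs]
    ranks = rank_midranks(dvals)
    within = [r for r, (i, j) in zip(ranks, pairs) if groups[i] == groups[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if groups[i] != groups[j]]
    M = len(pairs)
    return (sum(between) / len(between) - sum(within) / len(within)) / (M / 2.0)


def permanova_f_gower(dist, groups):
    """Pseudo-F via explicit Gower centering of -0.5 D^2 and hat-matrix
    projection onto group indicators."""
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    labels = list(dict.fromkeys(groups))
    X = np.zeros((n, len(labels)))
    for i, g in enumerate(groups):
        X[i, labels.index(g)] = 1.0
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    sst = np.trace(G)
    ssb = np.trace(H @ G @ H)
    ssw = sst - ssb
    a = len(labels)
    return (ssb / (a - 1)) / (ssw / (n - a)), ssb / sst


def exhaustive_label_stats(stat, groups):
    """Statistic under every distinct relabeling of the group multiset."""
    seen = set()
    out = []
    for perm in itertools.permutations(groups):
        if perm in seen:
            continue
        seen.add(perm)
        out.append(stat(list(perm)))
    return out
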