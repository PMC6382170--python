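"""Independent brute-force reference implementations used only by the tests.

Everything here is written as plain loops over voxels, sharing no code with
the package: texture matrices by exhaustive pair/run/zone enumeration, spatial
statistics by O(N^2) double sums, distances by breadth-first search.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def glcm_pairs(levels: np.ndarray, offset: tuple[int, int, int], ng: int) -> np.ndarray:
    """Symmetrized co-occurrence counts by exhaustive voxel enumeration."""
    nz, ny, nx = levels.shape
    oz, oy, ox = offset
    counts = np.zeros((ng, ng))
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                a = levels[k, j, i]
                if a == 0:
                    continue
                k2, j2, i2 = k + oz, j + oy, i + ox
                if 0 <= k2 < nz and 0 <= j2 < ny and 0 <= i2 < nx:
                    b = levels[k2, j2, i2]
                    if b > 0:
                        counts[a - 1, b - 1] += 1
                        counts[b - 1, a - 1] += 1
    return counts


def run_lengths(levels: np.ndarray, offset: tuple[int, int, int], ng: int) -> np.ndarray:
    """Maximal-run counts: a run starts wherever the predecessor differs."""
    nz, ny, nx = levels.shape
    oz, oy, ox = offset
    runs: list[tuple[int, int]] = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                g = levels[k, j, i]
                if g == 0:
                    continue
                pk, pj, pi = k - oz, j - oy, i - ox
                if 0 <= pk < nz and 0 <= pj < ny and 0 <= pi < nx and levels[pk, pj, pi] == g:
                    continue  # not a run start
                length = 0
                ck, cj, ci = k, j, i
                while 0 <= ck < nz and 0 <= cj < ny and 0 <= ci < nx and levels[ck, cj, ci] == g:
                    length += 1
                    ck, cj, ci = ck + oz, cj + oy, ci + ox
                runs.append((g, length))
    max_len = max((l for _, l in runs), default=1)
    counts = np.zeros((ng, max_len))
    for g, l in runs:
        counts[g - 1, l - 1] += 1
    return counts


def _neighbours(shape, k, j, i, offsets):
    for oz, oy, ox in offsets:
        k2, j2, i2 = k + oz, j + oy, i + ox
        if 0 <= k2 < shape[0] and 0 <= j2 < shape[1] and 0 <= i2 < shape[2]:
            yield k2, j2, i2


def _offsets(two_d: bool, face_only: bool):
    rng = (0,) if two_d else (-1, 0, 1)
    out = []
    for oz in rng:
        for oy in (-1, 0, 1):
            for ox in (-1, 0, 1):
                if (oz, oy, ox) == (0, 0, 0):
                    continue
                if face_only and abs(oz) + abs(oy) + abs(ox) != 1:
                    continue
                out.append((oz, oy, ox))
    return out


def flood_zones(levels: np.ndarray, two_d: bool) -> list[tuple[int, list[tuple[int, int, int]]]]:
    """Connected equal-level zones by breadth-first flood fill
    (8-connectivity in-plane, 26-connectivity in 3D)."""
    offs = _offsets(two_d, face_only=False)
    seen = np.zeros(levels.shape, dtype=bool)
    zones = []
    for k in range(levels.shape[0]):
        for j in range(levels.shape[1]):
            for i in range(levels.shape[2]):
                g = levels[k, j, i]
                if g == 0 or seen[k, j, i]:
                    continue
                queue = deque([(k, j, i)])
                seen[k, j, i] = True
                voxels = []
                while queue:
                    cur = queue.popleft()
                    voxels.append(cur)
                    for nb in _neighbours(levels.shape, *cur, offs):
                        if not seen[nb] and levels[nb] == g:
                            seen[nb] = True
                            queue.append(nb)
                zones.append((int(g), voxels))
    return zones


def border_distance_bfs(morph: np.ndarray, two_d: bool) -> np.ndarray:
    """City-block steps to outside the mask via multi-source BFS; boundary = 1."""
    offs = _offsets(two_d, face_only=True)
    dist = np.full(morph.shape, -1, dtype=int)
    queue = deque()
    for k in range(morph.shape[0]):
        for j in range(morph.shape[1]):
            for i in range(morph.shape[2]):
                if not morph[k, j, i]:
                    continue
                on_border = False
                for oz, oy, ox in offs:
                    k2, j2, i2 = k + oz, j + oy, i + ox
                    inside = (
                        0 <= k2 < morph.shape[0]
                        and 0 <= j2 < morph.shape[1]
                        and 0 <= i2 < morph.shape[2]
                    )
                    if not inside or not morph[k2, j2, i2]:
                        on_border = True
                        break
                if on_border:
                    dist[k, j, i] = 1
                    queue.append((k, j, i))
    while queue:
        cur = queue.popleft()
        for nb in _neighbours(morph.shape, *cur, offs):
            if morph[nb] and dist[nb] < 0:
                dist[nb] = dist[cur] + 1
                queue.append(nb)
    return dist


def ngtdm_table(levels: np.ndarray, ng: int, two_d: bool) -> np.ndarray:
    """[n_i, s_i] rows via per-voxel neighbourhood-mean loops."""
    offs = _offsets(two_d, face_only=False)
    out = np.zeros((ng, 2))
    for k in range(levels.shape[0]):
        for j in range(levels.shape[1]):
            for i in range(levels.shape[2]):
                g = levels[k, j, i]
                if g == 0:
                    continue
                vals = [levels[nb] for nb in _neighbours(levels.shape, k, j, i, offs) if levels[nb] > 0]
                if not vals:
                    continue
                out[g - 1, 0] += 1
                out[g - 1, 1] += abs(g - sum(vals) / len(vals))
    return out


def ngldm_table(levels: np.ndarray, ng: int, two_d: bool, alpha: int = 0) -> np.ndarray:
    """(level, dependence count + 1) counts via per-voxel neighbour loops."""
    offs = _offsets(two_d, face_only=False)
    entries = []
    for k in range(levels.shape[0]):
        for j in range(levels.shape[1]):
            for i in range(levels.shape[2]):
                g = levels[k, j, i]
                if g == 0:
                    continue
                dep = sum(
                    1
                    for nb in _neighbours(levels.shape, k, j, i, offs)
                    if levels[nb] > 0 and abs(int(levels[nb]) - int(g)) <= alpha
                )
                entries.append((int(g), dep))
    kmax = max((d for _, d in entries), default=0)
    counts = np.zeros((ng, kmax + 1))
    for g, d in entries:
        counts[g - 1, d] += 1
    return counts


def moran_geary(points: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Double-sum Moran's I / Geary's C with w_ij = 1/d_ij."""
    n = len(values)
    mu = values.mean()
    num_i = num_c = wsum = 0.0
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            d = math.dist(points[a], points[b])
            w = 1.0 / d
            wsum += w
            num_i += w * (values[a] - mu) * (values[b] - mu)
            num_c += w * (values[a] - values[b]) ** 2
    ss = float(np.sum((values - mu) ** 2))
    return (n / wsum) * num_i / ss, ((n - 1) / (2 * wsum)) * num_c / ss


def merge_counts(matrices: list[np.ndarray]) -> np.ndarray:
    rows = max(m.shape[0] for m in matrices)
    cols = max(m.shape[1] for m in matrices)
    out = np.zeros((rows, cols))
    for m in matrices:
        out[: m.shape[0], : m.shape[1]] += m
    return out


def neighbourhood_mean(image: np.ndarray, center, spacing, radius: float) -> float:
    """Mean over image voxels whose centers lie within `radius` mm of `center`."""
    dx, dy, dz = spacing
    ck, cj, ci = center
    total = count = 0
    for k in range(image.shape[0]):
        for j in range(image.shape[1]):
            for i in range(image.shape[2]):
                d2 = ((i - ci) * dx) ** 2 + ((j - cj) * dy) ** 2 + ((k - ck) * dz) ** 2
                if d2 <= radius**2 + 1e-9:
                    total += image[k, j, i]
                    count += 1
    return total / count
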