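"""Independent brute-force oracles used to verify the image primitives.

Everything here is deliberately naive -- explicit loops, BFS flood fills --
and shares no code with the package implementation beyond numpy.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def conv2d_brute(plane: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Dense same-size 2D convolution with symmetric (edge-repeat) padding."""
    s = kernel.shape[0]
    lo, hi = (s - 1) // 2, s // 2
    padded = np.pad(plane.astype(np.float64), ((lo, hi), (lo, hi)), mode="symmetric")
    out = np.empty_like(plane, dtype=np.float64)
    flipped = kernel[::-1, ::-1]
    for y in range(plane.shape[0]):
        for x in range(plane.shape[1]):
            out[y, x] = np.sum(padded[y : y + s, x : x + s] * flipped)
    return out


def convolve_planewise_brute(volume: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.stack([conv2d_brute(p, kernel) for p in volume])


def gaussian_kernel_brute(size: int, sd: float) -> np.ndarray:
    offsets = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(offsets**2) / (2.0 * sd**2))
    k = np.outer(g, g)
    return k / k.sum()


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def erosion_brute(plane: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale erosion with a disk, symmetric padding."""
    padded = np.pad(plane.astype(np.float64), radius, mode="symmetric")
    offs = disk_offsets(radius)
    out = np.empty_like(plane, dtype=np.float64)
    for y in range(plane.shape[0]):
        for x in range(plane.shape[1]):
            out[y, x] = min(padded[y + radius + dy, x + radius + dx] for dy, dx in offs)
    return out


def dilation_brute(plane: np.ndarray, radius: int) -> np.ndarray:
    padded = np.pad(plane.astype(np.float64), radius, mode="symmetric")
    offs = disk_offsets(radius)
    out = np.empty_like(plane, dtype=np.float64)
    for y in range(plane.shape[0]):
        for x in range(plane.shape[1]):
            out[y, x] = max(padded[y + radius + dy, x + radius + dx] for dy, dx in offs)
    return out


def tophat_brute(plane: np.ndarray, radius: int) -> np.ndarray:
    """White top-hat: image minus (dilation of erosion)."""
    return plane - dilation_brute(erosion_brute(plane, radius), radius)


def _neighbours(idx, shape, connectivity):
    z, y, x = idx
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                nz, ny, nx = z + dz, y + dy, x + dx
                if 0 <= nz < shape[0] and 0 <= ny < shape[1] and 0 <= nx < shape[2]:
                    yield nz, ny, nx


def label_brute(mask: np.ndarray, connectivity: int = 26):
    """BFS connected-component labelling of a 3D boolean volume."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    current = 0
    for idx in zip(*np.nonzero(mask)):
        if labels[idx]:
            continue
        current += 1
        queue = deque([idx])
        labels[idx] = current
        while queue:
            p = queue.popleft()
            for q in _neighbours(p, mask.shape, connectivity):
                if mask[q] and not labels[q]:
                    labels[q] = current
                    queue.append(q)
    return labels, current


def threshold_components_brute(image, comparator, value, min_size, max_size,
                               connectivity=26):
    ops = {">": np.greater, "<": np.less, ">=": np.greater_equal, "<=": np.less_equal}
    mask = ops[comparator](np.asarray(image, dtype=np.float64), value)
    labels, n = label_brute(mask, connectivity)
    out = np.zeros_like(mask)
    for i in range(1, n + 1):
        comp = labels == i
        if min_size <= comp.sum() <= max_size:
            out |= comp
    return out


def reconstruct_brute(seed, limit, connectivity=26):
    """Flood fill through ``limit`` starting from ``seed & limit``."""
    seed = np.asarray(seed, dtype=bool) & np.asarray(limit, dtype=bool)
    limit = np.asarray(limit, dtype=bool)
    out = np.zeros_like(limit)
    queue = deque(zip(*np.nonzero(seed)))
    for idx in zip(*np.nonzero(seed)):
        out[idx] = True
    while queue:
        p = queue.popleft()
        for q in _neighbours(p, limit.shape, connectivity):
            if limit[q] and not out[q]:
                out[q] = True
                queue.append(q)
    return out


def _neighbours_2d(idx, shape, connectivity):
    y, x = idx
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == dx == 0:
                continue
            if connectivity == 4 and abs(dy) + abs(dx) > 1:
                continue
            ny, nx = y + dy, x + dx
            if 0 <= ny < shape[0] and 0 <= nx < shape[1]:
                yield ny, nx


def label_2d_brute(mask: np.ndarray, connectivity: int = 8):
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    current = 0
    for idx in zip(*np.nonzero(mask)):
        if labels[idx]:
            continue
        current += 1
        queue = deque([idx])
        labels[idx] = current
        while queue:
            p = queue.popleft()
            for q in _neighbours_2d(p, mask.shape, connectivity):
                if mask[q] and not labels[q]:
                    labels[q] = current
                    queue.append(q)
    return labels, current


def count_holes_brute(component: np.ndarray) -> int:
    """Holes of one connected 2D component: enclosed 4-connected background
    regions (flood fill of the padded complement from the border)."""
    comp = np.pad(np.asarray(component, dtype=bool), 1)
    background = ~comp
    reach = np.zeros_like(background)
    h, w = background.shape
    queue = deque()
    for y in range(h):
        for x in (0, w - 1):
            if background[y, x] and not reach[y, x]:
                reach[y, x] = True
                queue.append((y, x))
    for x in range(w):
        for y in (0, h - 1):
            if background[y, x] and not reach[y, x]:
                reach[y, x] = True
                queue.append((y, x))
    while queue:
        p = queue.popleft()
        for q in _neighbours_2d(p, background.shape, 4):
            if background[q] and not reach[q]:
                reach[q] = True
                queue.append(q)
    enclosed = background & ~reach
    _, n_holes = label_2d_brute(enclosed, 4)
    return n_holes


def classify_oracle(f: dict) -> str:
    """Straight-line transcription of the staging predicates.

    Kept deliberately flat (no shared helpers, no config object) as an
    independent second implementation of the decision tree.
    """
    if f["overlap_autophagosome"] > 0 and f["overlap_noncircular"] == 0:
        return "autophagosome"
    phago_case1 = (
        f["overlap_phluorin"] >= 0.25
        and f["overlap_dsred"] >= 0.25
        and f["median_ratio"] > 2.0
        and f["overlap_autolyso"] == 0
    )
    phago_case2 = f["q3_green"] > 7500.0 and f["q3_red"] > 4000.0
    phago_case3 = f["center_green"] >= 1.25 * f["surface_green"]
    if phago_case1 or phago_case2 or phago_case3:
        return "phagophore"
    late_case1 = f["overlap_dsred"] >= 0.25 and (
        f["overlap_phluorin"] < 0.10 or f["median_ratio"] <= 2.0
    )
    late_case2 = f["center_green"] < f["surface_green"]
    if late_case1 or late_case2:
        return "late_autolysosome"
    if (
        f["overlap_dsred"] >= 0.25 and f["overlap_phluorin"] <= 0.25
    ) or f["overlap_autolyso"] > 0:
        return "early_autolysosome"
    return "unclassified"


def random_feature_tuples(rng, n: int) -> list[dict]:
    """Feature draws with point masses at the tree's equality boundaries."""
    tuples = []
    for _ in range(n):
        def overlap():
            u = rng.uniform()
            if u < 0.3:
                return 0.0
            if u < 0.4:
                return float(rng.choice([0.10, 0.25]))
            return float(rng.uniform(0, 1))

        surface = float(rng.uniform(100, 8000))
        tuples.append(
            {
                "overlap_autophagosome": overlap(),
                "overlap_noncircular": overlap(),
                "overlap_phluorin": overlap(),
                "overlap_dsred": overlap(),
                "overlap_autolyso": overlap(),
                "median_ratio": float(rng.uniform(0, 5)),
                "q3_green": float(rng.uniform(0, 16000)),
                "q3_red": float(rng.uniform(0, 8000)),
                "center_green": surface * float(rng.uniform(0.5, 2.0)),
                "surface_green": surface,
            }
        )
    return tuples
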