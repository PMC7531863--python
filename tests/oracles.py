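"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an operation from its definition with no shared
code: sliding-window convolution by explicit padding and shifting,
distance thresholding by all-pairs Euclidean distances, connected
components by breadth-first flood fill, and confusion counts by a literal
per-pixel comparison loop.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def brute_convolve_replicated(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct sliding-window convolution with edge-replicated borders."""
    image = np.asarray(image, dtype=np.float64)
    k = kernel.shape[0]
    r = k // 2
    padded = np.pad(image, r, mode="edge")
    out = np.zeros_like(image)
    for dy in range(k):
        for dx in range(k):
            # correlation with a symmetric kernel equals convolution
            out += kernel[dy, dx] * padded[dy : dy + image.shape[0], dx : dx + image.shape[1]]
    return out


def brute_distance_threshold(edges: np.ndarray, distance: float) -> np.ndarray:
    """All-pairs Euclidean distance thresholding around edge pixels."""
    edges = np.asarray(edges, dtype=bool)
    pts = np.argwhere(edges)
    if pts.size == 0:
        return np.zeros_like(edges)
    h, w = edges.shape
    yy, xx = np.mgrid[0:h, 0:w]
    grid = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(np.float64)
    d2 = ((grid[:, None, :] - pts[None, :, :].astype(np.float64)) ** 2).sum(axis=2)
    return (d2.min(axis=1) <= distance**2 + 1e-12).reshape(h, w)


def flood_fill_labels(free: np.ndarray) -> np.ndarray:
    """8-connected component labels of the True pixels, by BFS flood fill.

    Labels are assigned in raster-scan order of each component's first
    pixel, starting at 1; False pixels get 0.
    """
    free = np.asarray(free, dtype=bool)
    h, w = free.shape
    labels = np.zeros((h, w), dtype=np.int64)
    nxt = 0
    for sy in range(h):
        for sx in range(w):
            if not free[sy, sx] or labels[sy, sx]:
                continue
            nxt += 1
            queue = deque([(sy, sx)])
            labels[sy, sx] = nxt
            while queue:
                y, x = queue.popleft()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx_ = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx_ < w and free[ny, nx_] and not labels[ny, nx_]:
                            labels[ny, nx_] = nxt
                            queue.append((ny, nx_))
    return labels


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Renumber labels by first appearance in raster order (0 stays 0)."""
    labels = np.asarray(labels)
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    nxt = 0
    flat_in = labels.ravel()
    flat_out = out.ravel()
    for i, v in enumerate(flat_in):
        if v == 0:
            continue
        if v not in mapping:
            nxt += 1
            mapping[v] = nxt
        flat_out[i] = mapping[v]
    return out


def per_pixel_confusion(pred: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """Literal per-pixel TP/TN/FP/FN tally."""
    tp = tn = fp = fn = 0
    for p, t in zip(np.asarray(pred, dtype=bool).ravel(), np.asarray(truth, dtype=bool).ravel()):
        if p and t:
            tp += 1
        elif not p and not t:
            tn += 1
        elif p and not t:
            fp += 1
        else:
            fn += 1
    return tp, tn, fp, fn
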