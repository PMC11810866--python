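"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the vectorised/k-d-tree code paths of the package:
the flood fill is an explicit FIFO breadth-first queue, the Hausdorff
oracle is the O(n^2) max-min over all pairs.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def flood_fill_labels(slice_2d: np.ndarray, iso_value: float) -> np.ndarray:
    """Breadth-first background growing on one slice.

    Labels start at 2.  Corner pixels below the iso-value seed a FIFO
    queue; a dequeued pixel below the iso-value becomes 0 and its
    4-neighbours are enqueued, a pixel at/above it becomes 1 and growth
    stops there.  Each pixel is evaluated at most once.
    """
    h, w = slice_2d.shape
    labels = np.full((h, w), 2, dtype=np.uint8)
    visited = np.zeros((h, w), dtype=bool)
    queue: deque[tuple[int, int]] = deque()
    for r, c in ((0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1)):
        if slice_2d[r, c] < iso_value and not visited[r, c]:
            visited[r, c] = True
            queue.append((r, c))
    if not queue:
        raise RuntimeError("no background corner seed")
    while queue:
        r, c = queue.popleft()
        if slice_2d[r, c] < iso_value:
            labels[r, c] = 0
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not visited[rr, cc]:
                    visited[rr, cc] = True
                    queue.append((rr, cc))
        else:
            labels[r, c] = 1
    return labels


def brute_directed_hausdorff(X1: np.ndarray, X2: np.ndarray) -> float:
    """O(n^2) max over X1 of min distance to X2."""
    d = np.linalg.norm(X1[:, None, :] - X2[None, :, :], axis=2)
    return float(d.min(axis=1).max())


def brute_hausdorff(X1: np.ndarray, X2: np.ndarray) -> float:
    return max(brute_directed_hausdorff(X1, X2), brute_directed_hausdorff(X2, X1))
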