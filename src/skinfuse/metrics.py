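"""Co-registration error metrics: Hausdorff distance, per-vertex error maps, TRE.

The co-registration error between the segmented skin surface X1 and the
camera-acquired surface X2 is quantified with the Hausdorff distance

    d(X1, X2) = max{ d_X1(X2), d_X2(X1) },
    d_X1(X2)  = max_{x in X1} min_{y in X2} ||x - y||_2,

where distances are vertex-to-vertex and the inner minimum is resolved
through a k-d tree.  For visual inspection the per-vertex distance field is
mapped linearly to RGB: 0 mm is pure blue, ``cap`` mm (default 5) and above
is pure red, shades in between.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .mesh import TriangleMesh

__all__ = [
    "ErrorMap",
    "directed_hausdorff",
    "hausdorff",
    "per_vertex_distance",
    "colormap",
    "tre",
]


def _points(x) -> np.ndarray:
    if isinstance(x, TriangleMesh):
        x = x.vertices
    pts = np.asarray(x, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise ValueError("point set is empty")
    return pts


@dataclass
class ErrorMap:
    """Per-vertex distance field (mm) with its RGB rendering.

    Distances at or above ``cap`` are exactly red (255, 0, 0); a zero
    distance is exactly blue (0, 0, 255).
    """

    distances: np.ndarray
    colors: np.ndarray
    cap: float = 5.0

    @property
    def max(self) -> float:
        return float(self.distances.max())

    @property
    def mean(self) -> float:
        return float(self.distances.mean())


def directed_hausdorff(X1, X2) -> float:
    """max over X1 of the min Euclidean distance to X2 (k-d tree accelerated)."""
    p1, p2 = _points(X1), _points(X2)
    d, _ = cKDTree(p2).query(p1)
    return float(d.max())


def hausdorff(X1, X2) -> float:
    """Symmetric Hausdorff distance: max of the two directed distances."""
    return max(directed_hausdorff(X1, X2), directed_hausdorff(X2, X1))


def colormap(distances, cap: float = 5.0) -> np.ndarray:
    """Map non-negative distances (mm) to (N, 3) uint8 RGB.

    0 -> (0, 0, 255); >= cap -> (255, 0, 0); linear in between with
    integer rounding.  Negative distances are rejected.
    """
    d = np.asarray(distances, dtype=float).reshape(-1)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if cap <= 0:
        raise ValueError("cap must be > 0")
    frac = np.clip(d / cap, 0.0, 1.0)
    rgb = np.zeros((len(d), 3), dtype=np.uint8)
    rgb[:, 0] = np.rint(255.0 * frac).astype(np.uint8)
    rgb[:, 2] = np.rint(255.0 * (1.0 - frac)).astype(np.uint8)
    return rgb


def per_vertex_distance(surface: TriangleMesh, other, cap: float = 5.0) -> ErrorMap:
    """Distance of every vertex of ``surface`` to the vertex set of ``other``.

    The maximum of the field equals ``directed_hausdorff(surface, other)``.
    """
    p = _points(surface)
    q = _points(other)
    d, _ = cKDTree(q).query(p)
    return ErrorMap(distances=d, colors=colormap(d, cap), cap=cap)


def tre(registered_landmarks, target_landmarks) -> float:
    """Target registration error: mean Euclidean distance between
    corresponding landmark lists (mm).  The usual protocol uses N=1, a
    single anatomical target visible in both modalities."""
    a = np.asarray(registered_landmarks, dtype=float).reshape(-1, 3)
    b = np.asarray(target_landmarks, dtype=float).reshape(-1, 3)
    if len(a) == 0 or len(a) != len(b):
        raise ValueError(
            f"landmark lists must be equal-length and non-empty, got {len(a)} and {len(b)}"
        )
    return float(np.linalg.norm(a - b, axis=1).mean())
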