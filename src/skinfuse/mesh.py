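"""Triangle meshes, rigid transforms, and the mesh operations feeding registration.

The mesh container is deliberately light: vertices in world mm, triangle
index array, optional unit normals, optional per-vertex scalar field (e.g.
distance to the other surface) and optional per-vertex RGB colour.  File
I/O (PLY/STL/OBJ) is delegated to :mod:`trimesh`; point clouds (meshes
without triangles, such as simulated depth-camera acquisitions) round-trip
through PLY as well.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "TriangleMesh",
    "RigidTransform",
    "read_mesh",
    "write_mesh",
    "vertex_normals",
    "select_front",
    "crop_roi",
    "apply_transform",
    "rotation_angle_deg",
]

_RIGID_TOL = 1e-8


@dataclass
class TriangleMesh:
    """Vertices (N, 3) in mm, triangles (M, 3) vertex indices, optional extras."""

    vertices: np.ndarray
    triangles: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    normals: np.ndarray | None = None
    scalar: np.ndarray | None = None
    colors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        n = len(self.vertices)
        if self.triangles.size and (self.triangles.min() < 0 or self.triangles.max() >= n):
            raise ValueError("triangle indices out of range")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if len(self.normals) != n:
                raise ValueError("normals must be per-vertex")
        if self.scalar is not None:
            self.scalar = np.asarray(self.scalar, dtype=float).reshape(-1)
            if len(self.scalar) != n:
                raise ValueError("scalar field must be per-vertex")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=np.uint8).reshape(-1, 3)
            if len(self.colors) != n:
                raise ValueError("colors must be per-vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def to_trimesh(self):
        import trimesh

        if self.n_triangles == 0:
            cloud = trimesh.PointCloud(self.vertices)
            if self.colors is not None:
                cloud.colors = np.column_stack(
                    [self.colors, np.full(self.n_vertices, 255, dtype=np.uint8)]
                )
            return cloud
        tm = trimesh.Trimesh(vertices=self.vertices, faces=self.triangles, process=False)
        if self.colors is not None:
            tm.visual.vertex_colors = np.column_stack(
                [self.colors, np.full(self.n_vertices, 255, dtype=np.uint8)]
            )
        return tm


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation matrix + mm translation)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(
        cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        ax = np.asarray(axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * ax).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float).reshape(4, 4)
        return cls(M[:3, :3], M[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix (row-major)."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def angle_deg(self) -> float:
        """Rotation angle of the transform, in degrees."""
        return rotation_angle_deg(self.rotation)


def rotation_angle_deg(R: np.ndarray, other: np.ndarray | None = None) -> float:
    """Angle (deg) of rotation ``R``, or of the relative rotation ``R other^T``."""
    M = np.asarray(R, dtype=float)
    if other is not None:
        M = M @ np.asarray(other, dtype=float).T
    c = (np.trace(M) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_MESH_FORMATS = ("ply", "stl", "obj")


def write_mesh(mesh: TriangleMesh, path: str | os.PathLike, format: str | None = None) -> None:
    """Write PLY/STL/OBJ.  PLY carries per-vertex RGB when colours are set."""
    fmt = (format or Path(path).suffix.lstrip(".")).lower()
    if fmt not in _MESH_FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected one of {_MESH_FORMATS}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    mesh.to_trimesh().export(str(path), file_type=fmt)


def read_mesh(path: str | os.PathLike) -> TriangleMesh:
    import trimesh

    obj = trimesh.load(str(path), process=False)
    if isinstance(obj, trimesh.PointCloud):
        colors = None
        if obj.colors is not None and len(obj.colors):
            colors = np.asarray(obj.colors)[:, :3].astype(np.uint8)
        return TriangleMesh(vertices=np.asarray(obj.vertices), colors=colors)
    if isinstance(obj, trimesh.Scene):
        obj = obj.to_mesh()
    colors = None
    try:
        vc = obj.visual.vertex_colors
        if vc is not None and len(vc) == len(obj.vertices):
            colors = np.asarray(vc)[:, :3].astype(np.uint8)
    except Exception:
        pass
    return TriangleMesh(
        vertices=np.asarray(obj.vertices), triangles=np.asarray(obj.faces), colors=colors
    )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def vertex_normals(mesh: TriangleMesh) -> TriangleMesh:
    """Attach per-vertex normals: normalized area-weighted mean of incident
    face normals.  Outward for watertight meshes with outward winding.
    Isolated vertices get a zero normal.
    """
    if mesh.n_triangles == 0:
        raise ValueError("cannot compute vertex normals without triangles")
    v = mesh.vertices
    tri = mesh.triangles
    # cross product of edge vectors = 2 * area * unit face normal
    fn = np.cross(v[tri[:, 1]] - v[tri[:, 0]], v[tri[:, 2]] - v[tri[:, 0]])
    acc = np.zeros_like(v)
    for c in range(3):
        np.add.at(acc, tri[:, c], fn)
    norms = np.linalg.norm(acc, axis=1)
    nz = norms > 0
    acc[nz] /= norms[nz, None]
    return TriangleMesh(
        vertices=v, triangles=tri, normals=acc, scalar=mesh.scalar, colors=mesh.colors
    )


def _submesh(mesh: TriangleMesh, keep: np.ndarray) -> tuple[TriangleMesh, np.ndarray]:
    """Restrict to vertices where ``keep`` is True; keep triangles whose three
    vertices all survive.  Returns (submesh, original vertex indices)."""
    idx = np.flatnonzero(keep)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    tri = mesh.triangles
    tkeep = keep[tri].all(axis=1) if tri.size else np.zeros(0, dtype=bool)
    sub = TriangleMesh(
        vertices=mesh.vertices[idx],
        triangles=remap[tri[tkeep]] if tri.size else tri,
        normals=None if mesh.normals is None else mesh.normals[idx],
        scalar=None if mesh.scalar is None else mesh.scalar[idx],
        colors=None if mesh.colors is None else mesh.colors[idx],
    )
    return sub, idx


def select_front(mesh: TriangleMesh, anterior) -> TriangleMesh:
    """Keep the front-facing part of a skin surface.

    A vertex is front-facing when the angle between its normal and the
    anterior direction is below 90 deg, i.e. ``normal . anterior > 0``
    (strict: boundary vertices at exactly 90 deg are dropped).  Triangles
    survive only if all three vertices do.
    """
    a = np.asarray(anterior, dtype=float).reshape(3)
    a = a / np.linalg.norm(a)
    m = mesh if mesh.normals is not None else vertex_normals(mesh)
    keep = m.normals @ a > 0
    if not keep.any():
        raise ValueError("no front-facing vertices for the given anterior direction")
    sub, _ = _submesh(m, keep)
    return sub


def crop_roi(mesh: TriangleMesh, center, radius: float) -> TriangleMesh:
    """Keep vertices within Euclidean ``radius`` mm of ``center``."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    c = np.asarray(center, dtype=float).reshape(3)
    keep = np.linalg.norm(mesh.vertices - c, axis=1) <= radius
    if not keep.any():
        raise ValueError("ROI crop selected no vertices")
    sub, _ = _submesh(mesh, keep)
    return sub


def apply_transform(mesh: TriangleMesh, T: RigidTransform) -> TriangleMesh:
    """Move a mesh by a rigid transform (vertices ``v -> R v + t``, normals rotated)."""
    return TriangleMesh(
        vertices=T.apply(mesh.vertices),
        triangles=mesh.triangles,
        normals=None if mesh.normals is None else mesh.normals @ T.rotation.T,
        scalar=mesh.scalar,
        colors=mesh.colors,
    )
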