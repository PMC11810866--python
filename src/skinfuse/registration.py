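"""Rigid co-registration of the segmented skin surface to a depth-camera surface.

Pipeline (the registration moves the segmented surface X1 into the frame of
the camera surface X2, which shares the tracking reference system with the
US probe):

1. cut X1 to its front-facing part (normal within 90 deg of the anterior
   direction) — only the part of the body the camera can see matters;
2. coarse orientation adjustment by PCA: rotate X1's principal axes onto
   X2's (both surfaces must be consistently oriented head-feet / left-right,
   otherwise body symmetries make the sign choice ambiguous);
3. translation pinning one operator-selected virtual landmark on X1 exactly
   onto its counterpart on X2;
4. both surfaces are cropped to a spherical region of interest around the
   camera landmark, and two ICP refinement stages run: a full (untrimmed)
   stage, then a trimmed stage that keeps the 80% of closest-pair
   correspondences each iteration to reject points without a true
   counterpart (partial camera coverage, acquisition noise);
5. the final roto-translation is applied to the volume header (pose update
   only, no resampling), putting the CT/MR in the camera/US frame.

Registration is rigid throughout: the two surfaces differ in connectivity,
vertex count and noise, and a deformable model would invent deformations
the anatomy does not have.

Two implementation choices matter on smooth, feature-poor skin patches
(abdomen, symmetric phantoms):

* inside the pipeline, ICP correspondences run camera -> segmented: every
  camera point has a true counterpart on the segmented front, whereas
  segmented points outside the camera's partial coverage do not, and
  matching them would bias the fit.  The returned transform still maps the
  segmented surface into the camera frame.
* the pipeline's default error metric is point-to-plane against the
  segmented mesh normals, which converges reliably where point-to-point
  ICP slides on near-symmetric dome-like patches.  The classic closed-form
  point-to-point update remains available (and is the default of the bare
  :func:`icp` routine).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import (
    RigidTransform,
    TriangleMesh,
    crop_roi,
    select_front,
    vertex_normals,
)
from .metrics import ErrorMap, per_vertex_distance
from .volume import VolumetricImage

__all__ = [
    "LandmarkPair",
    "RegistrationConfig",
    "RegistrationResult",
    "snap_to_surface",
    "pca_align",
    "landmark_translate",
    "icp",
    "coregister",
    "apply_to_volume",
    "best_rigid",
]


@dataclass
class LandmarkPair:
    """One corresponding virtual landmark on each surface (mm)."""

    on_segmented: np.ndarray
    on_camera: np.ndarray

    def __post_init__(self) -> None:
        self.on_segmented = np.asarray(self.on_segmented, dtype=float).reshape(3)
        self.on_camera = np.asarray(self.on_camera, dtype=float).reshape(3)


@dataclass
class RegistrationConfig:
    """Tunables of the co-registration pipeline.

    roi_radius:
        Radius (mm) of the spherical region of interest around the camera
        landmark used by both ICP stages.  Default 100 mm.
    trim_fraction:
        Fraction of closest correspondences kept each iteration of the
        refinement ICP stage.  Default 0.8.
    max_iterations / convergence_tol:
        Per-stage ICP iteration cap and RMS-change stopping threshold (mm).
    anterior:
        Unit vector of the patient's anterior direction in the segmented
        surface's frame, used for the front cut.  Default +y.
    metric:
        ICP error metric used by the pipeline stages: ``"point_to_plane"``
        (default; needs destination normals, robust on smooth skin) or
        ``"point_to_point"`` (classic closed-form SVD update).
    """

    roi_radius: float = 100.0
    trim_fraction: float = 0.8
    max_iterations: int = 50
    convergence_tol: float = 1e-4
    anterior: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    metric: str = "point_to_plane"

    def __post_init__(self) -> None:
        if not (0.0 < self.trim_fraction <= 1.0):
            raise ValueError("trim_fraction must be in (0, 1]")
        if self.roi_radius <= 0:
            raise ValueError("roi_radius must be > 0")
        if self.metric not in ("point_to_point", "point_to_plane"):
            raise ValueError(f"unknown ICP metric {self.metric!r}")
        self.anterior = np.asarray(self.anterior, dtype=float).reshape(3)
        n = np.linalg.norm(self.anterior)
        if n == 0:
            raise ValueError("anterior direction must be non-zero")
        self.anterior = self.anterior / n


@dataclass
class RegistrationResult:
    """Outcome of :func:`coregister`.

    ``transform`` maps segmented-surface coordinates into the camera frame.
    ``per_stage_rms`` holds the final RMS (mm) of each pipeline stage in
    order (landmark init, ICP stage 1, ICP stage 2); ``rms_history`` the
    full per-iteration trimmed-RMS traces of the two ICP stages.
    """

    transform: RigidTransform
    per_stage_rms: list[float]
    hausdorff: float
    error_map_segmented: ErrorMap
    error_map_camera: ErrorMap
    iterations_used: list[int]
    rms_history: list[list[float]]
    roi_segmented: TriangleMesh | None = None
    roi_normals: np.ndarray | None = None


def snap_to_surface(point, mesh: TriangleMesh) -> np.ndarray:
    """Nearest mesh vertex to ``point`` — used to put landmarks on-surface."""
    p = np.asarray(point, dtype=float).reshape(3)
    i = int(np.argmin(np.linalg.norm(mesh.vertices - p, axis=1)))
    return mesh.vertices[i].copy()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvectors (columns, descending eigenvalue) of the point covariance."""
    c = points - points.mean(axis=0)
    cov = c.T @ c / len(c)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], V[:, order]


def pca_align(src: TriangleMesh, dst: TriangleMesh) -> RigidTransform:
    """Coarse alignment rotating ``src``'s principal axes onto ``dst``'s.

    Axis signs are chosen per axis so the rotated source axis has positive
    dot product with the corresponding destination axis; this is only valid
    when the surfaces are consistently oriented (head-feet, right-left).
    A near-degenerate covariance (relative eigenvalue gap below 1%) is
    rejected as ambiguous.  The translation maps centroid to centroid.
    """
    ps, pd = src.vertices, dst.vertices
    ws, U = _principal_axes(ps)
    wd, V = _principal_axes(pd)
    for w, who in ((ws, "source"), (wd, "destination")):
        rel = -np.diff(w) / np.maximum(w[:-1], 1e-30)  # (w[i] - w[i+1]) / w[i]
        if np.any(rel < 0.01):
            raise ValueError(
                f"ambiguous principal axes on {who} surface: "
                f"covariance eigenvalues {w} are nearly tied"
            )
    signs = np.ones(3)
    dots = np.einsum("ij,ij->j", U, V)
    signs[dots < 0] = -1.0
    if np.any(np.abs(dots) < 1e-12):
        raise ValueError("ambiguous principal-axis sign (orthogonal axis pair)")
    R = (V * signs) @ U.T
    if np.linalg.det(R) < 0:
        # flip the weakest-agreement axis to restore a proper rotation
        i = int(np.argmin(np.abs(dots)))
        signs[i] *= -1.0
        R = (V * signs) @ U.T
    t = pd.mean(axis=0) - R @ ps.mean(axis=0)
    return RigidTransform(R, t)


def landmark_translate(
    src: TriangleMesh, pair: LandmarkPair, R: RigidTransform
) -> RigidTransform:
    """Replace the translation of ``R`` so the rotated segmented-surface
    landmark lands exactly on the camera-surface landmark."""
    t = pair.on_camera - R.rotation @ pair.on_segmented
    return RigidTransform(R.rotation, t)


def best_rigid(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Closed-form (SVD) least-squares rigid transform mapping points P onto Q."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, cq - R @ cp)


def _trimmed_rms(T: RigidTransform, src: np.ndarray, tree: cKDTree, m: int) -> float:
    d, _ = tree.query(T.apply(src))
    return float(np.sqrt(np.mean(np.sort(d)[:m] ** 2)))


def _trimmed_plane_rms(
    T: RigidTransform, src: np.ndarray, dstp: np.ndarray,
    dst_normals: np.ndarray, tree: cKDTree, m: int,
) -> float:
    moved = T.apply(src)
    d, idx = tree.query(moved)
    keep = np.argsort(d)[:m]
    r = np.einsum("ij,ij->i", moved[keep] - dstp[idx[keep]], dst_normals[idx[keep]])
    return float(np.sqrt(np.mean(r**2)))


def icp(
    src_points,
    dst,
    init: RigidTransform | None = None,
    trim_fraction: float = 1.0,
    cfg: RegistrationConfig | None = None,
    metric: str = "point_to_point",
    dst_normals: np.ndarray | None = None,
) -> tuple[RigidTransform, list[float]]:
    """Trimmed iterative-closest-point rigid registration.

    Each iteration: nearest-neighbour correspondences from the moved source
    points to the destination vertices (k-d tree); keep the ``trim_fraction``
    of pairs with smallest distances; rigid update fitted on the kept pairs;
    stop when the trimmed RMS changes by less than ``cfg.convergence_tol``
    mm or after ``cfg.max_iterations``.

    ``metric="point_to_point"`` (default) uses the closed-form SVD update
    and reports the trimmed Euclidean RMS.  ``metric="point_to_plane"``
    linearises the distance to the destination tangent planes (requires
    destination normals, taken from ``dst`` when it is a mesh with normals
    or from ``dst_normals``) and reports the trimmed RMS of the plane
    residuals; its Gauss-Newton step is halved until that residual does not
    increase.  Either way the returned per-iteration trimmed-RMS trace is
    non-increasing.

    Returns the accumulated absolute transform and the trimmed-RMS trace (mm).
    """
    cfg = cfg or RegistrationConfig()
    src = np.asarray(
        src_points.vertices if isinstance(src_points, TriangleMesh) else src_points,
        dtype=float,
    ).reshape(-1, 3)
    if isinstance(dst, TriangleMesh):
        dstp = dst.vertices
        if dst_normals is None:
            dst_normals = dst.normals
    else:
        dstp = np.asarray(dst, dtype=float).reshape(-1, 3)
    if len(src) < 10:
        raise ValueError(f"ICP needs >= 10 source points, got {len(src)}")
    if not (0.0 < trim_fraction <= 1.0):
        raise ValueError("trim_fraction must be in (0, 1]")
    if metric not in ("point_to_point", "point_to_plane"):
        raise ValueError(f"unknown ICP metric {metric!r}")
    if metric == "point_to_plane" and dst_normals is None:
        raise ValueError("point_to_plane ICP needs destination normals")
    T = init or RigidTransform.identity()
    tree = cKDTree(dstp)
    m = int(round(trim_fraction * len(src)))
    if m < 3:
        raise ValueError(f"trimming keeps only {m} correspondences; need at least 3")
    history: list[float] = []
    for _ in range(cfg.max_iterations):
        d, idx = tree.query(T.apply(src))
        keep = np.argsort(d)[:m]
        if metric == "point_to_point":
            T = best_rigid(src[keep], dstp[idx[keep]])
            rms = _trimmed_rms(T, src, tree, m)
        else:
            T, rms = _point_to_plane_step(
                T, src, dstp, np.asarray(dst_normals, dtype=float), idx, keep,
                tree, m, prev=history[-1] if history else None,
            )
        history.append(rms)
        if rms <= cfg.convergence_tol:
            break
        if len(history) >= 2 and abs(history[-2] - rms) < cfg.convergence_tol:
            break
    return T, history


def _point_to_plane_step(
    T: RigidTransform,
    src: np.ndarray,
    dstp: np.ndarray,
    dst_normals: np.ndarray,
    idx: np.ndarray,
    keep: np.ndarray,
    tree: cKDTree,
    m: int,
    prev: float | None,
) -> tuple[RigidTransform, float]:
    """One Gauss-Newton point-to-plane update with step halving so the
    trimmed plane-residual RMS never increases."""
    from scipy.spatial.transform import Rotation

    p = T.apply(src[keep])
    q = dstp[idx[keep]]
    n = dst_normals[idx[keep]]
    b = -np.einsum("ij,ij->i", p - q, n)
    A = np.column_stack([np.cross(p, n), n])
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    if prev is None:
        prev = _trimmed_plane_rms(T, src, dstp, dst_normals, tree, m)
    scale = 1.0
    for _ in range(12):
        dR = Rotation.from_rotvec(scale * x[:3]).as_matrix()
        cand = RigidTransform(dR, scale * x[3:]).compose(T)
        rms = _trimmed_plane_rms(cand, src, dstp, dst_normals, tree, m)
        if rms <= prev:
            return cand, rms
        scale *= 0.5
    return T, prev  # no productive step; report unchanged transform


def coregister(
    segmented: TriangleMesh,
    camera: TriangleMesh,
    pair: LandmarkPair,
    cfg: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Full co-registration pipeline from segmented skin to camera surface.

    Front cut -> PCA orientation -> landmark translation -> ROI crop around
    the camera landmark -> untrimmed ICP -> trimmed (default 80%) ICP.
    The returned transform maps segmented-surface mm coordinates into the
    camera frame; error maps and the Hausdorff distance are evaluated on
    the ROI surfaces after registration.
    """
    cfg = cfg or RegistrationConfig()

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"co-registration stage '{name}' failed: {exc}") from exc

    seg = segmented if segmented.normals is not None else _stage(
        "vertex normals", vertex_normals, segmented
    )
    front = _stage("front cut", select_front, seg, cfg.anterior)

    # coarse orientation: PCA between the camera surface and an
    # extent-matched patch of the front around the segmented landmark, so
    # both covariances describe comparable regions.  Under partial coverage
    # the principal axes of the camera window can still be unreliable, so
    # the identity rotation (valid thanks to the consistent-orientation
    # precondition) is always kept as a second starting point and the two
    # ICP outcomes are arbitrated by their final trimmed RMS.
    r_cam = float(np.linalg.norm(camera.vertices - pair.on_camera, axis=1).max())
    patch = _stage("pca patch crop", crop_roi, front, pair.on_segmented, r_cam)
    rotations = [RigidTransform.identity()]
    try:
        rotations.insert(0, pca_align(patch, camera))
    except ValueError as exc:
        warnings.warn(
            f"PCA orientation skipped ({exc}); relying on consistent "
            "orientation and the landmark translation",
            stacklevel=2,
        )

    cam_roi = _stage("roi crop", crop_roi, camera, pair.on_camera, cfg.roi_radius)
    metric = cfg.metric

    # The virtual landmark is operator-placed and its dominant error mode is
    # a tangential slip on the skin, which drags ICP into a nearby local
    # basin on smooth surfaces.  Each rotation init is therefore tried with
    # the landmark translation as given and with +-15 mm corrections along
    # the landmark's tangent plane; the branch with the lowest final trimmed
    # point-to-point RMS wins.
    i_lm = int(np.argmin(np.linalg.norm(front.vertices - pair.on_segmented, axis=1)))
    n_lm = front.normals[i_lm] if front.normals is not None else cfg.anterior
    u = np.cross(n_lm, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(n_lm, [1.0, 0.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(n_lm, u)
    slip = 15.0
    offsets = [np.zeros(3), slip * u, -slip * u, slip * v, -slip * v]

    best = None
    for R0 in rotations:
        T_lm = _stage("landmark translation", landmark_translate, front, pair, R0)
        for off in offsets:
            T = RigidTransform(T_lm.rotation, T_lm.translation + R0.rotation @ off)
            src_keep = (
                np.linalg.norm(T.apply(front.vertices) - pair.on_camera, axis=1)
                <= cfg.roi_radius
            )
            if not src_keep.any():
                continue
            seg_pts = front.vertices[src_keep]
            normals = front.normals[src_keep] if metric == "point_to_plane" else None

            # stage-0 diagnostic in the same direction as the ICP traces
            d0, _ = cKDTree(T.apply(seg_pts)).query(cam_roi.vertices)
            rms0 = float(np.sqrt(np.mean(d0**2)))

            # refinement matches camera -> segmented (every camera point has
            # a true counterpart on the segmented front); result inverted.
            T1i, hist1 = _stage(
                "icp stage 1", icp, cam_roi.vertices, seg_pts, T.inverse(),
                1.0, cfg, metric, normals,
            )
            T2i, hist2 = _stage(
                "icp stage 2", icp, cam_roi.vertices, seg_pts, T1i,
                cfg.trim_fraction, cfg, metric, normals,
            )
            m = int(round(cfg.trim_fraction * cam_roi.n_vertices))
            score = _trimmed_rms(T2i, cam_roi.vertices, cKDTree(seg_pts), max(3, m))
            if best is None or score < best[0]:
                best = (score, T2i.inverse(), rms0, hist1, hist2, seg_pts, normals)
    if best is None:
        raise RuntimeError(
            "co-registration stage 'roi crop' failed: no segmented-surface "
            "vertices inside the ROI"
        )
    _, T2, rms0, hist1, hist2, src_roi, roi_normals = best
    seg_roi = TriangleMesh(vertices=src_roi)

    moved_roi = TriangleMesh(vertices=T2.apply(seg_roi.vertices))
    emap_seg = per_vertex_distance(moved_roi, cam_roi)
    emap_cam = per_vertex_distance(cam_roi, moved_roi)
    hd = max(emap_seg.max, emap_cam.max)
    frac_bad = float(np.mean(emap_seg.distances > 5.0))
    if hd > 5.0 and frac_bad > 0.10:
        warnings.warn(
            f"registration residual above 5 mm on {100 * frac_bad:.0f}% of ROI "
            f"vertices (Hausdorff {hd:.1f} mm); consider re-acquiring the surface",
            stacklevel=2,
        )
    return RegistrationResult(
        transform=T2,
        per_stage_rms=[rms0, hist1[-1], hist2[-1]],
        hausdorff=hd,
        error_map_segmented=emap_seg,
        error_map_camera=emap_cam,
        iterations_used=[len(hist1), len(hist2)],
        rms_history=[hist1, hist2],
        roi_segmented=seg_roi,
        roi_normals=roi_normals,
    )


def apply_to_volume(vol: VolumetricImage, T: RigidTransform) -> VolumetricImage:
    """Re-pose a volume by a rigid transform (header update only).

    Voxel data is untouched; the origin and direction matrix change so the
    world coordinate of every voxel moves by ``x -> R x + t``.
    """
    return VolumetricImage(
        data=vol.data,
        spacing=vol.spacing,
        origin=T.rotation @ vol.origin + T.translation,
        axes=T.rotation @ vol.axes,
        slice_axis=vol.slice_axis,
    )
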