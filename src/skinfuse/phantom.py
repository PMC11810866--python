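"""Synthetic phantoms and simulated depth-camera acquisitions.

Everything the pipeline consumes can be generated here with known ground
truth:

* :func:`make_phantom_volume` builds a CT/MR-like volume — a bright body
  (ellipsoid, CIRS-like cylinder, or an abdomen-like superellipsoid with an
  anterior bulge) on a dark air background, with optional scanner-bed slab,
  optional internal air cavity, and clipped Gaussian intensity noise that
  never crosses the skin iso-value.  The analytic shape is returned
  alongside the voxel grid so segmentation accuracy can be checked against
  the true surface.
* :func:`simulate_camera_surface` emulates a depth-camera acquisition of a
  segmented skin mesh: front-facing partial coverage (a contiguous window),
  vertex resampling, additive isotropic position noise, and a known
  ground-truth rigid pose into the "camera/tracking" frame.
* :func:`perturbation_suite` enumerates the robustness scenarios of a
  phantom study design: camera distance (noise grows with distance),
  camera tilt (the coverage window shifts off the perpendicular view), and
  15 mm misplacement of the virtual landmark.

All randomness flows through a seeded generator; equal seeds give
bit-identical volumes and surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .mesh import RigidTransform, TriangleMesh, select_front, vertex_normals
from .volume import VolumetricImage

__all__ = [
    "PhantomSpec",
    "CameraSimSpec",
    "AnalyticShape",
    "Scenario",
    "make_phantom_volume",
    "simulate_camera_surface",
    "perturbation_suite",
    "distance_noise_sigma",
]

_SHAPES = ("ellipsoid", "cylinder", "abdomen")


def distance_noise_sigma(distance_cm: float) -> float:
    """Positional noise (mm) of the simulated camera at a given stand-off.

    Linear stand-in schedule sigma = 0.3 + 0.02 * distance_cm: depth-camera
    noise grows with acquisition distance, but real curves are
    hardware-specific.
    """
    return 0.3 + 0.02 * distance_cm


@dataclass
class PhantomSpec:
    """Parameters of a synthetic CT/MR-like phantom volume.

    Defaults emulate an abdomen-scale CT: air at -1000 HU, soft tissue at
    40 HU, skin iso-value -300 HU, 20 HU acquisition noise, 4 mm voxels on
    a 96^3 grid (~38 cm field of view).
    """

    shape: str = "abdomen"
    semi_axes: tuple[float, float, float] = (150.0, 100.0, 170.0)
    body_intensity: float = 40.0
    air_intensity: float = -1000.0
    iso_value: float = -300.0
    noise_sigma: float = 20.0
    include_bed: bool = False
    internal_cavity: bool = False
    dims: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    bed_intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"shape must be one of {_SHAPES}, got {self.shape!r}")
        if not (self.air_intensity < self.iso_value <= self.body_intensity):
            raise ValueError(
                "need air_intensity < iso_value <= body_intensity, got "
                f"{self.air_intensity} / {self.iso_value} / {self.body_intensity}"
            )
        if any(d < 16 for d in self.dims):
            raise ValueError(f"dims must be >= 16 per axis, got {self.dims}")


@dataclass
class AnalyticShape:
    """Implicit description of the phantom body: inside iff F(x) <= 1."""

    name: str
    implicit: Callable[[np.ndarray], np.ndarray]
    semi_axes: tuple[float, float, float]

    def inside(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.implicit(pts) <= 1.0


def _shape_function(spec: PhantomSpec) -> AnalyticShape:
    a, b, c = spec.semi_axes

    if spec.shape == "ellipsoid":

        def F(p):
            return (p[..., 0] / a) ** 2 + (p[..., 1] / b) ** 2 + (p[..., 2] / c) ** 2

    elif spec.shape == "cylinder":
        # axis along z (head-feet), CIRS-like: symmetric elliptic cylinder
        def F(p):
            radial = (p[..., 0] / a) ** 2 + (p[..., 1] / b) ** 2
            return np.maximum(radial, (p[..., 2] / c) ** 2)

    else:  # abdomen: boxy superellipsoid cross-section plus anterior bulge
        p_exp = 2.5
        def F(p):
            x, y, z = p[..., 0], p[..., 1], p[..., 2]
            bulge = 1.0 + 0.15 * np.exp(-(((z + 0.2 * c) / (0.35 * c)) ** 2))
            b_eff = np.where(y > 0, b * bulge, b)
            return (
                np.abs(x / a) ** p_exp
                + np.abs(y / b_eff) ** p_exp
                + (z / c) ** 2
            )

    return AnalyticShape(name=spec.shape, implicit=F, semi_axes=spec.semi_axes)


def make_phantom_volume(
    spec: PhantomSpec, seed: int = 0
) -> tuple[VolumetricImage, AnalyticShape]:
    """Voxelise a phantom body with noise, bed and cavity options.

    The grid is centred on the body (origin chosen so world (0,0,0) is the
    volume centre).  Noise is clipped to 99% of the margin between each
    tissue class and the iso-value, so no voxel ever crosses to the other
    side of the threshold; a ``noise_sigma`` whose 4-sigma range exceeds the
    margin is rejected outright.
    """
    shape = _shape_function(spec)
    dims = np.asarray(spec.dims)
    spacing = np.asarray(spec.spacing, dtype=float)
    margin_air = spec.iso_value - spec.air_intensity
    margin_body = spec.body_intensity - spec.iso_value
    if spec.noise_sigma > 0 and 4.0 * spec.noise_sigma > min(margin_air, max(margin_body, 0)):
        raise ValueError(
            f"noise_sigma {spec.noise_sigma} violates air/body separability "
            f"(margins {margin_air} / {margin_body} around the iso-value)"
        )

    origin = -spacing * (dims - 1) / 2.0
    ii, jj, kk = np.meshgrid(
        np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]), indexing="ij"
    )
    world = origin + np.stack([ii, jj, kk], axis=-1) * spacing
    inside = shape.implicit(world) <= 1.0

    if spec.internal_cavity:
        cav = _shape_function(
            replace(spec, shape="ellipsoid",
                    semi_axes=tuple(s / 4.0 for s in spec.semi_axes))
        )
        inside_cavity = cav.implicit(world) <= 1.0
        body = inside & ~inside_cavity
        air = ~inside | inside_cavity
    else:
        body = inside
        air = ~inside

    data = np.where(body, spec.body_intensity, spec.air_intensity).astype(np.float32)

    if spec.include_bed:
        # flat slab under the body (posterior = low y-index rows), spanning
        # the full slice width so it touches the in-plane border
        bed_rows = max(2, int(round(8.0 / spacing[1])))
        data[:, :bed_rows, :] = spec.bed_intensity
        if spec.bed_intensity >= spec.iso_value:
            # body-like bed: clip its noise on the body side of the iso-value
            air = air.copy()
            air[:, :bed_rows, :] = False
            body = body.copy()
            body[:, :bed_rows, :] = True

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, spec.noise_sigma, size=data.shape).astype(np.float32)
        lim_air = 0.99 * margin_air
        np.clip(noise, -lim_air, lim_air, out=noise)
        out = data + noise
        # body-side clip: never drop below the iso-value
        if margin_body > 0:
            floor = spec.iso_value + 0.01 * margin_body
            out[body] = np.maximum(out[body], floor)
        else:
            out[body] = np.maximum(out[body], spec.iso_value)
        data = out

    vol = VolumetricImage(
        data=data, spacing=spacing, origin=origin, axes=np.eye(3), slice_axis=2
    )
    return vol, shape


@dataclass
class CameraSimSpec:
    """Parameters of a simulated depth-camera acquisition.

    ``pose`` is the ground-truth rigid transform from the skin-surface
    frame into the camera/tracking frame.  ``coverage`` is the fraction of
    front-facing vertices retained (a contiguous window around the view
    centre); ``view_tilt_deg`` rotates the window centre off the
    perpendicular anterior view, emulating a tilted camera.
    """

    pose: RigidTransform = field(default_factory=RigidTransform.identity)
    coverage: float = 0.6
    noise_sigma: float = 0.5
    sample_count: int = 2000
    seed: int = 0
    anterior: tuple[float, float, float] = (0.0, 1.0, 0.0)
    view_tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError("coverage must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def simulate_camera_surface(
    skin: TriangleMesh, spec: CameraSimSpec
) -> tuple[TriangleMesh, RigidTransform]:
    """Emulate a frontal depth-camera acquisition of a skin mesh.

    Returns the acquired point cloud in the camera frame together with the
    ground-truth pose.  Steps: front cut along ``anterior``; contiguous
    coverage window around the (possibly tilted) view centre; resampling to
    ``sample_count`` points; isotropic Gaussian noise; rigid pose.
    """
    rng = np.random.default_rng(spec.seed)
    anterior = np.asarray(spec.anterior, dtype=float)
    anterior = anterior / np.linalg.norm(anterior)
    m = skin if skin.normals is not None else vertex_normals(skin)
    front = select_front(m, anterior)

    view_dir = anterior
    if spec.view_tilt_deg:
        # tilt about the long (head-feet) axis, orthogonal-ish to anterior
        axis = np.array([0.0, 0.0, 1.0])
        if abs(axis @ anterior) > 0.9:
            axis = np.array([1.0, 0.0, 0.0])
        tilt = RigidTransform.from_axis_angle(axis, spec.view_tilt_deg)
        view_dir = tilt.rotation @ anterior

    center_of = skin.vertices.mean(axis=0)
    apex = front.vertices[np.argmax((front.vertices - center_of) @ view_dir)]
    n_keep = int(round(spec.coverage * front.n_vertices))
    order = np.argsort(np.linalg.norm(front.vertices - apex, axis=1))
    window = front.vertices[order[:n_keep]]
    if len(window) < 100:
        raise ValueError(
            f"coverage window holds only {len(window)} points; need >= 100"
        )

    if spec.sample_count <= len(window):
        pick = rng.choice(len(window), size=spec.sample_count, replace=False)
    else:
        pick = rng.choice(len(window), size=spec.sample_count, replace=True)
    pts = window[pick]
    if spec.noise_sigma > 0:
        pts = pts + rng.normal(0.0, spec.noise_sigma, size=pts.shape)
    pts = spec.pose.apply(pts)
    return TriangleMesh(vertices=pts), spec.pose


@dataclass
class Scenario:
    """One perturbation experiment: a camera spec plus a landmark offset."""

    name: str
    camera: CameraSimSpec
    landmark_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.landmark_offset = np.asarray(self.landmark_offset, dtype=float).reshape(3)


def perturbation_suite(base: CameraSimSpec, seed: int = 0) -> list[Scenario]:
    """Scenarios of the phantom robustness study design.

    Emits the base acquisition, four camera-distance analogues (20/25/30/
    35 cm — noise grows with distance), three tilt angles (perpendicular/
    30/45 deg at 35 cm) and three 15 mm virtual-landmark misplacements
    (horizontal/vertical/diagonal; the camera surface itself is untouched,
    only the landmark moves).  11 scenarios in total, each independently
    seeded.
    """
    scenarios = [Scenario("base", replace(base, seed=seed))]
    for i, d_cm in enumerate((20, 25, 30, 35)):
        scenarios.append(
            Scenario(
                f"distance_{d_cm}cm",
                replace(base, noise_sigma=distance_noise_sigma(d_cm), seed=seed + 1 + i),
            )
        )
    sigma35 = distance_noise_sigma(35)
    for i, tilt in enumerate((0, 30, 45)):
        scenarios.append(
            Scenario(
                f"tilt_{tilt}deg",
                replace(base, noise_sigma=sigma35, view_tilt_deg=float(tilt),
                        seed=seed + 5 + i),
            )
        )
    d = 15.0
    offsets = {
        "misplaced_15mm_horizontal": np.array([d, 0.0, 0.0]),
        "misplaced_15mm_vertical": np.array([0.0, 0.0, d]),
        "misplaced_15mm_diagonal": np.array([d, d, 0.0]) / np.sqrt(2.0),
    }
    for i, (name, off) in enumerate(offsets.items()):
        scenarios.append(
            Scenario(name, replace(base, noise_sigma=sigma35, seed=seed + 8 + i), off)
        )
    return scenarios
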