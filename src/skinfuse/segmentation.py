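"""Slice-by-slice skin segmentation by background region growing.

Given a CT/MR volume and the skin iso-value (an intensity threshold between
air and tissue), each 2D slice is segmented independently:

1. every element of a "mock-up" label grid starts at 2 (unvisited);
2. region growing starts at the slice corners (background seeds below the
   iso-value) and advances over 4-connected pixels;
3. a visited pixel below the iso-value becomes background (0) and its
   neighbours are queued; a pixel at/above the iso-value becomes body edge
   (1) and growth stops there;
4. pixels never reached — the body interior and any internal air pockets
   enclosed by tissue — keep the label 2.

The body is thus segmented *by exclusion*: everything that is not
outside-connected air belongs to the body mask (labels 1 and 2), which is
then turned into a triangle mesh by marching cubes at level 0.5.

The region growing is implemented with vectorised connected components
(the set of pixels reachable from the seeds through below-iso pixels is
exactly the union of below-iso 4-connected components containing a seed;
the edge is the set of at/above-iso pixels 4-adjacent to that background).
An explicit breadth-first queue yields identical labels and serves as the
independent oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .mesh import TriangleMesh
from .volume import SegmentationConfig, VolumetricImage, pad_volume

__all__ = [
    "BACKGROUND",
    "BODY_EDGE",
    "INTERIOR",
    "MockupGrid",
    "SeedError",
    "segment_skin",
    "binarize",
    "extract_skin_surface",
    "segment_skin_surface",
]

BACKGROUND, BODY_EDGE, INTERIOR = 0, 1, 2

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)  # 4-connectivity


class SeedError(RuntimeError):
    """No usable background seed: all slice corners are at/above the iso-value."""


@dataclass
class MockupGrid:
    """Per-voxel label grid: 0 background, 1 body edge, 2 unvisited/interior."""

    labels: np.ndarray
    iso_value: float
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label grid must be 3D")


def _segment_slice(sl: np.ndarray, iso_value: float, slice_index: int) -> np.ndarray:
    below = sl < iso_value
    corners = [(0, 0), (0, -1), (-1, 0), (-1, -1)]
    seed_vals = [below[c] for c in corners]
    if not any(seed_vals):
        raise SeedError(
            f"slice {slice_index}: all four corner seeds are at/above the "
            f"iso-value {iso_value}; pad the volume so corners are background"
        )
    comp, _ = ndimage.label(below, structure=_CROSS)
    seed_ids = np.unique([comp[c] for c, ok in zip(corners, seed_vals) if ok])
    background = np.isin(comp, seed_ids)
    edge = ~below & ndimage.binary_dilation(background, structure=_CROSS)
    out = np.full(sl.shape, INTERIOR, dtype=np.uint8)
    out[background] = BACKGROUND
    out[edge] = BODY_EDGE
    return out


def segment_skin(vol: VolumetricImage, cfg: SegmentationConfig) -> MockupGrid:
    """Label every voxel of the (padded) volume as background/edge/interior.

    If ``cfg.pad_width > 0`` the volume is padded internally first, so the
    returned grid has the padded dimensions; pass ``pad_width=0`` for an
    already-padded volume.  Raises :class:`SeedError` for a slice whose
    four corners are all at/above the iso-value.
    """
    if cfg.slice_axis is not None:
        vol = VolumetricImage(
            data=vol.data, spacing=vol.spacing, origin=vol.origin,
            axes=vol.axes, slice_axis=cfg.slice_axis,
        )
    if cfg.pad_width > 0:
        vol = pad_volume(vol, cfg)
    ax = vol.slice_axis
    data = np.moveaxis(vol.data, ax, 0)
    labels = np.empty(data.shape, dtype=np.uint8)
    for s in range(data.shape[0]):
        labels[s] = _segment_slice(data[s], cfg.iso_value, s)
    return MockupGrid(
        labels=np.moveaxis(labels, 0, ax), iso_value=cfg.iso_value, slice_axis=ax
    )


def binarize(grid: MockupGrid) -> np.ndarray:
    """Body mask: 1 where label is edge or interior (body by exclusion,
    internal air pockets included), 0 on outside-connected background."""
    return (grid.labels != BACKGROUND).astype(np.uint8)


def extract_skin_surface(grid: MockupGrid, vol: VolumetricImage) -> TriangleMesh:
    """Run marching cubes on the binarized body mask at level 0.5.

    ``vol`` must be the same (padded) volume the grid was computed from;
    its geometry maps mesh vertices to world mm.  The result is a closed,
    consistently wound triangle mesh with outward orientation.
    """
    if grid.labels.shape != vol.shape:
        raise ValueError(
            f"grid shape {grid.labels.shape} does not match volume shape {vol.shape}"
        )
    mask = binarize(grid)
    if mask.min() == mask.max():
        raise ValueError("no iso-surface: mask is entirely empty or entirely full")
    from skimage import measure

    verts, faces, normals, _ = measure.marching_cubes(
        mask.astype(np.float32), level=0.5, spacing=tuple(vol.spacing)
    )
    world = vol.origin + (vol.axes @ verts.T).T
    # skimage's default gradient direction ("descent") makes normals point
    # from body (1) towards air (0), i.e. outward; flip winding to match.
    world_normals = (vol.axes @ normals.T).T
    return TriangleMesh(
        vertices=world, triangles=faces[:, ::-1].copy(), normals=world_normals
    )


def segment_skin_surface(vol: VolumetricImage, cfg: SegmentationConfig) -> TriangleMesh:
    """Convenience pipeline: (subsample) -> pad -> region growing -> marching cubes."""
    from .volume import subsample_volume

    if cfg.subsample_factor > 1:
        vol = subsample_volume(vol, cfg.subsample_factor)
    if cfg.slice_axis is not None:
        vol = VolumetricImage(
            data=vol.data, spacing=vol.spacing, origin=vol.origin,
            axes=vol.axes, slice_axis=cfg.slice_axis,
        )
    padded = pad_volume(vol, cfg)
    grid = segment_skin(
        padded, SegmentationConfig(iso_value=cfg.iso_value, pad_width=0)
    )
    return extract_skin_surface(grid, padded)
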