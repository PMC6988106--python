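"""Multi-scale patch (MSP) extraction along surface normals.

Each graph node carries a stack of elongated patches sampled on a fixed grid
(default 13 x 13 x 17) whose long axis follows the outward surface normal;
scales share the center and orientation but double the sampling spacing, so
low scales capture local wall texture and high scales the surrounding
anatomy.  During training the patch center receives a random shift gamma ~
U(-R, +R) along the normal (negative = into the blood pool), emulating
over-/under-segmentation of the LA; at test time R = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .surface import SurfaceMesh
from .volume import ImageVolume

__all__ = [
    "MSPConfig",
    "ShiftConfig",
    "MSPStack",
    "local_frame",
    "extract_patch",
    "extract_msp",
    "extract_msp_batch",
]

DEFAULT_DIMS = (13, 13, 17)


@dataclass
class ShiftConfig:
    """Random normal-direction shift: gamma ~ Uniform(-R, +R) mm."""

    R: float = 8.0

    def __post_init__(self) -> None:
        if self.R < 0:
            raise ValueError("shift range R must be non-negative")


@dataclass
class MSPConfig:
    dims: tuple[int, int, int] = DEFAULT_DIMS
    n_scales: int = 3
    base_spacing_mm: float = 1.0
    shift: ShiftConfig = field(default_factory=ShiftConfig)

    def __post_init__(self) -> None:
        if self.n_scales < 1:
            raise ValueError("need at least one scale")
        if any(d % 2 == 0 for d in self.dims):
            raise ValueError("patch dims must be odd so the center voxel is defined")

    @property
    def spacings(self) -> np.ndarray:
        return self.base_spacing_mm * 2.0 ** np.arange(self.n_scales)


@dataclass
class MSPStack:
    patches: np.ndarray   # (N_s, *dims)
    spacings: np.ndarray  # (N_s,) mm, strictly increasing
    node: int
    shift_mm: float = 0.0


def local_frame(normal: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame (rows) with the normal as third axis.

    The first in-plane axis is the world axis least parallel to the normal,
    projected onto the normal's orthogonal plane — so patch orientations stay
    maximally aligned with the world coordinate system of the image.
    """
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("zero normal")
    if abs(norm - 1.0) > 1e-6:
        raise ValueError("normal must be a unit vector")
    n = n / norm
    k = int(np.argmin(np.abs(n)))
    e = np.zeros(3)
    e[k] = 1.0
    a1 = e - np.dot(e, n) * n
    a1 /= np.linalg.norm(a1)
    a2 = np.cross(n, a1)
    return np.stack([a1, a2, n])


def _lattice_offsets(dims) -> np.ndarray:
    """(P, 3) grid offsets in patch units, centered on the middle sample."""
    axes = [np.arange(d) - (d - 1) / 2.0 for d in dims]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


def extract_patch(image: ImageVolume, center, frame, dims=DEFAULT_DIMS,
                  spacing_mm: float = 1.0) -> np.ndarray:
    """Trilinearly sample one oriented patch; outside the volume -> 0."""
    offsets = _lattice_offsets(dims) * spacing_mm
    pts = np.asarray(center, dtype=float) + offsets @ np.asarray(frame, dtype=float)
    values = image.sample(pts, order=1, cval=0.0)
    return values.reshape(dims)


def extract_msp(image: ImageVolume, node: int, mesh: SurfaceMesh,
                cfg: MSPConfig, rng: np.random.Generator | None = None) -> MSPStack:
    """Extract the multi-scale patch stack for one node.

    One gamma is drawn per call (i.e. per node per epoch); with R = 0 (the
    testing phase) the center is exactly the vertex.
    """
    gamma = 0.0
    if cfg.shift.R > 0:
        if rng is None:
            raise ValueError("rng required when the shift range R > 0")
        gamma = float(rng.uniform(-cfg.shift.R, cfg.shift.R))
    normal = mesh.normals[node]
    center = mesh.vertices[node] + gamma * normal
    frame = local_frame(normal)
    patches = np.stack([
        extract_patch(image, center, frame, cfg.dims, s) for s in cfg.spacings
    ])
    return MSPStack(patches, cfg.spacings.copy(), node, gamma)


def extract_msp_batch(image: ImageVolume, mesh: SurfaceMesh, nodes,
                      cfg: MSPConfig, rng: np.random.Generator | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized MSP extraction for many nodes.

    Returns ``(patches, gammas)`` with ``patches`` of shape
    ``(n_nodes, N_s, *dims)``.  Equivalent to calling :func:`extract_msp`
    node by node but with one interpolation call per scale.
    """
    nodes = np.asarray(nodes, dtype=int)
    if cfg.shift.R > 0:
        if rng is None:
            raise ValueError("rng required when the shift range R > 0")
        gammas = rng.uniform(-cfg.shift.R, cfg.shift.R, size=len(nodes))
    else:
        gammas = np.zeros(len(nodes))
    normals = mesh.normals[nodes]
    centers = mesh.vertices[nodes] + gammas[:, None] * normals
    frames = np.stack([local_frame(n) for n in normals])  # (N, 3, 3)
    offsets = _lattice_offsets(cfg.dims)                   # (P, 3)
    data = image.data.astype(float, copy=False)
    out = np.empty((len(nodes), cfg.n_scales) + tuple(cfg.dims))
    for s, sp in enumerate(cfg.spacings):
        # (N, P, 3): center + (offset * spacing) through each node's frame
        pts = centers[:, None, :] + np.einsum("pk,nkj->npj", offsets * sp, frames)
        idx = (pts.reshape(-1, 3) - image.origin) / image.spacing
        vals = map_coordinates(data, idx.T, order=1, mode="constant", cval=0.0)
        out[:, s] = vals.reshape((len(nodes),) + tuple(cfg.dims))
    return out, gammas
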