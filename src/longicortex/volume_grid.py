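"""3D scalar image container, continuous sampling, and occupancy rasterization.

Convention (fixed for both training and inference): voxel centres sit at integer
indices; the stored 4x4 affine maps voxel indices to world millimetres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .surface_io import TriangleMesh

logger = logging.getLogger(__name__)


@dataclass
class ScalarVolume:
    """A single-channel 3D image ``X`` (H, W, D) with a voxel-to-world affine."""

    data: np.ndarray
    voxel_to_world: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.voxel_to_world = np.asarray(self.voxel_to_world, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise ValueError("data must be 3-D with every side >= 2")
        if self.voxel_to_world.shape != (4, 4):
            raise ValueError("voxel_to_world must be 4x4")
        if abs(np.linalg.det(self.voxel_to_world)) < 1e-12:
            raise ValueError("voxel_to_world affine is not invertible")

    @property
    def shape(self):
        return self.data.shape

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.voxel_to_world)
        pts = np.atleast_2d(points)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def save_nifti(self, path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.voxel_to_world),
                 str(path))

    @classmethod
    def load(cls, path) -> "ScalarVolume":
        """Load a NIfTI-1 (or .mgz) volume."""
        img = nib.load(str(Path(path)))
        return cls(np.asarray(img.dataobj, dtype=np.float64), np.asarray(img.affine))


@dataclass
class FeaturePyramid:
    """Multi-resolution image features registered to one world frame.

    ``levels`` is a list of ``(C_l, H, W, D)`` channel-first arrays; every level
    shares ``voxel_to_world`` (features are computed at the native grid with
    increasing smoothing scale rather than by decimation).
    """

    levels: list
    voxel_to_world: np.ndarray

    @property
    def n_channels(self) -> int:
        return int(sum(lv.shape[0] for lv in self.levels))


def make_feature_pyramid(volume: ScalarVolume, sigmas=(0.0, 1.0, 2.0)) -> FeaturePyramid:
    """Fixed Gaussian-derivative filter bank: per smoothing scale, the intensity
    and its three spatial gradients (world mm units)."""
    spacing = np.linalg.norm(volume.voxel_to_world[:3, :3], axis=0)
    levels = []
    for s in sigmas:
        sm = ndimage.gaussian_filter(volume.data, s) if s > 0 else volume.data
        g = np.gradient(sm, *spacing)
        levels.append(np.stack([sm, g[0], g[1], g[2]], axis=0))
    return FeaturePyramid(levels, volume.voxel_to_world.copy())


def _trilinear_core(data_cf: np.ndarray, vox: np.ndarray, want_grad: bool):
    """Trilinear interpolation of channel-first data at fractional voxel coords.

    Coordinates are clamped to the valid cube.  Returns (n, C) values and, if
    requested, (n, C, 3) gradients w.r.t. the *voxel* coordinates (zero in the
    clamped directions, consistent with clamping).
    """
    C = data_cf.shape[0]
    shape = np.array(data_cf.shape[1:])
    lo = np.floor(vox).astype(np.int64)
    lo = np.clip(lo, 0, shape - 2)
    frac = np.clip(vox - lo, 0.0, 1.0)
    x, y, z = frac[:, 0], frac[:, 1], frac[:, 2]
    i, j, k = lo[:, 0], lo[:, 1], lo[:, 2]

    c = np.empty((8, len(vox), C))
    for b, (di, dj, dk) in enumerate([(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1),
                                      (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1)]):
        c[b] = data_cf[:, i + di, j + dj, k + dk].T

    wx = np.stack([1 - x, x])[:, :, None]
    wy = np.stack([1 - y, y])[:, :, None]
    wz = np.stack([1 - z, z])[:, :, None]

    def blend(wx_, wy_, wz_):
        out = 0.0
        for b, (di, dj, dk) in enumerate([(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1),
                                          (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1)]):
            out = out + wx_[di] * wy_[dj] * wz_[dk] * c[b]
        return out

    vals = blend(wx, wy, wz)
    if not want_grad:
        return vals, None
    one = np.ones_like(wx)
    dwx = np.stack([-np.ones(len(vox)), np.ones(len(vox))])[:, :, None]
    gx = blend(dwx, wy, wz)
    gy = blend(wx, dwx, wz)
    gz = blend(wx, wy, dwx)
    # zero gradient where the query clamped outside the cube
    inside = ((vox >= 0) & (vox <= shape - 1)).astype(float)
    grads = np.stack([gx * inside[:, None, 0], gy * inside[:, None, 1],
                      gz * inside[:, None, 2]], axis=2)
    return vals, grads


def trilinear_sample(volume, points: np.ndarray, with_gradient: bool = False):
    """Trilinear interpolation at world-space points.

    Accepts a :class:`ScalarVolume` (returns (n, 1)) or a
    :class:`FeaturePyramid` (returns (n, C_total)).  Points outside the grid are
    clamped to the boundary (and counted in a log message).  With
    ``with_gradient=True``, also returns (n, C, 3) gradients with respect to the
    world coordinates.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if isinstance(volume, FeaturePyramid):
        data_cf = np.concatenate(volume.levels, axis=0)
        affine = volume.voxel_to_world
    else:
        data_cf = volume.data[None]
        affine = volume.voxel_to_world
    inv = np.linalg.inv(affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    shape = np.array(data_cf.shape[1:])
    n_out = int(np.sum(np.any((vox < 0) | (vox > shape - 1), axis=1)))
    if n_out:
        logger.debug("trilinear_sample: %d/%d points clamped to the grid", n_out, len(vox))
    vals, grads = _trilinear_core(data_cf, vox, with_gradient)
    if with_gradient:
        world_grads = np.einsum("ncv,vw->ncw", grads, inv[:3, :3])
        return vals, world_grads
    return vals


# ---------------------------------------------------------------------------
# Occupancy rasterization
# ---------------------------------------------------------------------------

LABEL_BACKGROUND, LABEL_GRAY, LABEL_WHITE = 0, 1, 2


def _inside_mask(mesh: TriangleMesh, grid_shape, affine) -> np.ndarray:
    """Boolean inside/outside at voxel centres by +z ray-crossing parity.

    Triangles are rasterized per (x, y) lattice column in voxel space; a tiny
    irrational offset keeps lattice points off triangle edges in general
    position.
    """
    H, W, D = grid_shape
    inv = np.linalg.inv(affine)
    v = mesh.vertices @ inv[:3, :3].T + inv[:3, 3]
    eps = (2.0 ** -20) * np.array([1.0, np.sqrt(2) - 1, 0.0])
    v = v + eps
    tri = v[mesh.faces]
    inside = np.zeros((H, W, D), dtype=bool)
    crossings: dict = {}
    for t in tri:
        (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = t
        xmin = max(int(np.ceil(min(x0, x1, x2))), 0)
        xmax = min(int(np.floor(max(x0, x1, x2))), H - 1)
        ymin = max(int(np.ceil(min(y0, y1, y2))), 0)
        ymax = min(int(np.floor(max(y0, y1, y2))), W - 1)
        if xmin > xmax or ymin > ymax:
            continue
        gx, gy = np.meshgrid(np.arange(xmin, xmax + 1), np.arange(ymin, ymax + 1),
                             indexing="ij")
        gx = gx.ravel()
        gy = gy.ravel()
        d = (y1 - y0) * (x2 - x0) - (x1 - x0) * (y2 - y0)
        if d == 0:
            continue  # edge-on triangle: no z-crossing
        l1 = ((gy - y0) * (x2 - x0) - (gx - x0) * (y2 - y0)) / d
        l2 = ((gx - x0) * (y1 - y0) - (gy - y0) * (x1 - x0)) / d
        l0 = 1.0 - l1 - l2
        hit = (l0 > 0) & (l1 > 0) & (l2 > 0)
        if not hit.any():
            continue
        zhit = l0[hit] * z0 + l1[hit] * z1 + l2[hit] * z2
        for xx, yy, zz in zip(gx[hit], gy[hit], zhit):
            crossings.setdefault((xx, yy), []).append(zz)
    for (xx, yy), zs in crossings.items():
        zs = np.sort(zs)
        # z-centres below an odd number of remaining crossings are inside
        idx = np.searchsorted(zs, np.arange(D))
        inside[xx, yy, :] = (len(zs) - idx) % 2 == 1
    return inside


def rasterize_occupancy(inner: TriangleMesh, outer: TriangleMesh, grid_shape,
                        affine) -> np.ndarray:
    """Label voxel centres: white (inside ``inner``), gray (between the
    surfaces), background (outside ``outer``).

    Requires both meshes closed and the inner surface strictly inside the outer.
    """
    for name, m in (("inner", inner), ("outer", outer)):
        if not m.is_closed_manifold():
            raise ValueError(f"{name} mesh is not a closed 2-manifold")
    in_inner = _inside_mask(inner, grid_shape, np.asarray(affine, dtype=np.float64))
    in_outer = _inside_mask(outer, grid_shape, np.asarray(affine, dtype=np.float64))
    if np.any(in_inner & ~in_outer):
        raise ValueError("inner mesh is not strictly inside the outer mesh")
    labels = np.full(tuple(grid_shape), LABEL_BACKGROUND, dtype=np.int8)
    labels[in_outer] = LABEL_GRAY
    labels[in_inner] = LABEL_WHITE
    return labels
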