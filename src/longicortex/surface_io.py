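"""Triangle-mesh data model, file I/O, and discrete-geometry primitives.

Surfaces are closed triangle meshes with counter-clockwise face orientation and
outward normals.  All coordinates are world-space millimetres; any voxel-to-world
bookkeeping lives in :mod:`longicortex.volume_grid`.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import scipy.sparse as sp
import trimesh as _trimesh
from nibabel.freesurfer import io as fsio
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

MeshFormat = Literal["freesurfer_surface", "off", "ply"]


class MeshFormatError(ValueError):
    """A mesh file does not parse under the requested dialect."""


@dataclass
class TriangleMesh:
    """A triangle mesh ``{V, F}`` with vertices in mm and CCW-oriented faces.

    Parameters
    ----------
    vertices : (V, 3) float array
    faces : (F, 3) int array of vertex indices
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range [0, V)")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("degenerate face (repeated vertex index)")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        """Unique undirected edges (E, 2) with ``e[:, 0] < e[:, 1]``."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def is_closed_manifold(self) -> bool:
        """True iff every undirected edge is shared by exactly two faces."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def face_normals(self, normalized: bool = True) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        if normalized:
            n = np.linalg.norm(cr, axis=1, keepdims=True)
            with np.errstate(invalid="ignore", divide="ignore"):
                cr = np.where(n > 0, cr / n, 0.0)
        return cr

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same connectivity, new coordinates (faces shared, not copied)."""
        m = TriangleMesh.__new__(TriangleMesh)
        m.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        m.faces = self.faces
        return m


@dataclass
class VertexScalarField:
    """A per-vertex scalar field aligned to a mesh's vertex order."""

    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")

    def check_mesh(self, mesh: TriangleMesh) -> None:
        if len(self.values) != mesh.n_vertices:
            raise ValueError(
                f"field '{self.name}' has {len(self.values)} values for a mesh with "
                f"{mesh.n_vertices} vertices"
            )


@dataclass
class SurfaceSequence:
    """Ordered per-visit meshes of one subject sharing one connectivity.

    Vertex row ``v`` denotes the same anatomical point at every visit.
    """

    subject_id: str
    meshes: list = field(default_factory=list)
    surface_class: Literal["white", "pial"] = "white"

    def __post_init__(self) -> None:
        if not self.meshes:
            raise ValueError("SurfaceSequence needs at least one mesh")
        f0 = self.meshes[0].faces
        for j, m in enumerate(self.meshes[1:], start=1):
            if m.faces.shape != f0.shape or not np.array_equal(m.faces, f0):
                raise ValueError(f"visit {j} does not share connectivity with visit 0")

    @property
    def n_visits(self) -> int:
        return len(self.meshes)

    @property
    def faces(self) -> np.ndarray:
        return self.meshes[0].faces


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> MeshFormat:
    s = path.suffix.lower()
    if s == ".off":
        return "off"
    if s == ".ply":
        return "ply"
    return "freesurfer_surface"


def read_mesh(path, format: MeshFormat | None = None) -> TriangleMesh:
    """Read a triangle mesh from FreeSurfer binary, OFF, or PLY.

    Raises
    ------
    MeshFormatError
        If the file does not parse under the named dialect, including faces
        referencing out-of-range vertices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _detect_format(path)
    try:
        if fmt == "freesurfer_surface":
            with open(path, "rb") as fh:
                magic = fh.read(3)
            if magic != b"\xff\xff\xfe":
                raise MeshFormatError(
                    f"{path}: bad FreeSurfer triangle-file magic {magic!r} at byte offset 0"
                )
            verts, faces = fsio.read_geometry(str(path))
            return TriangleMesh(np.asarray(verts, dtype=np.float64), np.asarray(faces))
        # OFF / PLY via trimesh
        tm = _trimesh.load(str(path), file_type=fmt, process=False)
        if not isinstance(tm, _trimesh.Trimesh):
            raise MeshFormatError(f"{path}: no triangle mesh in file")
        return TriangleMesh(np.asarray(tm.vertices, dtype=np.float64), np.asarray(tm.faces))
    except MeshFormatError:
        raise
    except (ValueError, struct.error, IndexError, KeyError) as exc:
        raise MeshFormatError(f"{path}: malformed {fmt} file: {exc}") from exc


def write_mesh(mesh: TriangleMesh, path, format: MeshFormat | None = None) -> None:
    """Write a mesh; FreeSurfer surfaces carry an identity volume-geometry footer."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "freesurfer_surface":
        volume_info = {
            "head": np.array([2, 0, 20], dtype=np.int32),
            "valid": "1  # volume info valid",
            "filename": "none",
            "volume": np.array([256, 256, 256]),
            "voxelsize": np.array([1.0, 1.0, 1.0]),
            "xras": np.array([1.0, 0.0, 0.0]),
            "yras": np.array([0.0, 1.0, 0.0]),
            "zras": np.array([0.0, 0.0, 1.0]),
            "cras": np.array([0.0, 0.0, 0.0]),
        }
        fsio.write_geometry(
            str(path), mesh.vertices.astype(np.float32), mesh.faces.astype(np.int32),
            volume_info=volume_info,
        )
        return
    tm = _trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    data = tm.export(file_type=fmt)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def read_scalar_field(path, name: str = "") -> VertexScalarField:
    """Read a per-vertex field from a FreeSurfer curv file or a one-column CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        vals = np.loadtxt(path, delimiter=",", skiprows=1)
        return VertexScalarField(np.atleast_1d(vals), name=name or path.stem)
    return VertexScalarField(fsio.read_morph_data(str(path)).astype(np.float64),
                             name=name or path.name)


def write_scalar_field(fld: VertexScalarField, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, fld.values, delimiter=",", header=fld.name or "value", comments="")
    else:
        fsio.write_morph_data(str(path), fld.values.astype(np.float32))


# ---------------------------------------------------------------------------
# Discrete differential geometry
# ---------------------------------------------------------------------------

def vertex_normals(mesh: TriangleMesh) -> np.ndarray:
    """Unit per-vertex normals: area-weighted average of incident face normals.

    Zero-area faces contribute nothing (a warning is logged).
    """
    v, f = mesh.vertices, mesh.faces
    cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2*area*normal
    areas = np.linalg.norm(cr, axis=1)
    n_zero = int(np.sum(areas == 0))
    if n_zero:
        logger.warning("vertex_normals: skipping %d zero-area faces", n_zero)
    acc = np.zeros_like(v)
    for k in range(3):
        np.add.at(acc, f[:, k], cr)
    norms = np.linalg.norm(acc, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 0, acc / norms, 0.0)
    return out


def _cotangent_weights(mesh: TriangleMesh):
    """Cotangent edge weights and Meyer mixed-Voronoi vertex areas."""
    v, f = mesh.vertices, mesh.faces
    i0, i1, i2 = f[:, 0], f[:, 1], f[:, 2]
    p0, p1, p2 = v[i0], v[i1], v[i2]

    def cot(a, b):  # cot of angle between vectors a, b
        cr = np.linalg.norm(np.cross(a, b), axis=1)
        return np.einsum("ij,ij->i", a, b) / np.maximum(cr, 1e-300)

    # angle at vertex k is opposite edge (i, j)
    c0 = cot(p1 - p0, p2 - p0)  # opposite edge (1, 2)
    c1 = cot(p2 - p1, p0 - p1)  # opposite edge (2, 0)
    c2 = cot(p0 - p2, p1 - p2)  # opposite edge (0, 1)

    rows = np.concatenate([i1, i2, i2, i0, i0, i1])
    cols = np.concatenate([i2, i1, i0, i2, i1, i0])
    w = 0.5 * np.concatenate([c0, c0, c1, c1, c2, c2])
    V = mesh.n_vertices
    W = sp.coo_matrix((w, (rows, cols)), shape=(V, V)).tocsr()

    # Mixed Voronoi areas (Meyer et al.): Voronoi area for non-obtuse triangles,
    # T/2 at the obtuse corner and T/4 at the others otherwise.
    area_t = mesh.face_areas()
    sq01 = np.einsum("ij,ij->i", p1 - p0, p1 - p0)
    sq12 = np.einsum("ij,ij->i", p2 - p1, p2 - p1)
    sq20 = np.einsum("ij,ij->i", p0 - p2, p0 - p2)
    # Voronoi contribution at corner k: (|e_kj|^2 cot(angle at m) + |e_km|^2 cot(angle at j)) / 8
    a0 = (sq01 * c2 + sq20 * c1) / 8.0
    a1 = (sq01 * c2 + sq12 * c0) / 8.0
    a2 = (sq20 * c1 + sq12 * c0) / 8.0
    obt0 = c0 < 0
    obt1 = c1 < 0
    obt2 = c2 < 0
    any_obt = obt0 | obt1 | obt2
    a0 = np.where(any_obt, np.where(obt0, area_t / 2, area_t / 4), a0)
    a1 = np.where(any_obt, np.where(obt1, area_t / 2, area_t / 4), a1)
    a2 = np.where(any_obt, np.where(obt2, area_t / 2, area_t / 4), a2)
    areas = np.zeros(V)
    np.add.at(areas, i0, a0)
    np.add.at(areas, i1, a1)
    np.add.at(areas, i2, a2)
    return W, areas


def mean_curvature(mesh: TriangleMesh) -> VertexScalarField:
    """Discrete mean curvature via the cotangent Laplace–Beltrami operator.

    ``kappa(v) = 0.5 * ||Delta x(v)||``, signed positive where the surface bends
    away from the outward normal (a sphere of radius r with outward normals gets
    ``+1/r``).  On a non-closed mesh, boundary vertices are set to 0.
    """
    W, areas = _cotangent_weights(mesh)
    deg = np.asarray(W.sum(axis=1)).ravel()
    # Laplace-Beltrami: (1 / A_v) * sum_u w_uv (x_u - x_v)
    lap = (W @ mesh.vertices - deg[:, None] * mesh.vertices) / np.maximum(areas, 1e-300)[:, None]
    mag = 0.5 * np.linalg.norm(lap, axis=1)
    normals = vertex_normals(mesh)
    # lap points toward the centre of curvature; bending away from the outward
    # normal means lap is anti-parallel to it
    sign = -np.sign(np.einsum("ij,ij->i", lap, normals))
    kappa = mag * np.where(sign == 0, 1.0, sign)
    if not mesh.is_closed_manifold():
        e = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        boundary = np.unique(uniq[counts != 2])
        kappa[boundary] = 0.0
        logger.warning("mean_curvature: %d boundary vertices set to 0", len(boundary))
    return VertexScalarField(kappa, name="mean_curvature")


# ---------------------------------------------------------------------------
# Surface sampling and distances
# ---------------------------------------------------------------------------

def sample_surface_points(mesh: TriangleMesh, n: int, rng_seed=None,
                          return_barycentric: bool = False):
    """Sample ``n`` points uniformly by area: faces chosen proportionally to
    area, barycentric coordinates uniform on the simplex.  Reproducible per seed.
    """
    if mesh.n_faces == 0:
        raise ValueError("cannot sample from an empty mesh")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    areas = mesh.face_areas()
    total = areas.sum()
    if total <= 0:
        raise ValueError("mesh has zero total area")
    fidx = rng.choice(mesh.n_faces, size=n, p=areas / total)
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    b0 = 1.0 - r1
    b1 = r1 * (1.0 - r2)
    b2 = r1 * r2
    tri = mesh.vertices[mesh.faces[fidx]]
    pts = b0[:, None] * tri[:, 0] + b1[:, None] * tri[:, 1] + b2[:, None] * tri[:, 2]
    if return_barycentric:
        return pts, fidx, np.stack([b0, b1, b2], axis=1)
    return pts


def _point_triangle_distance_sq(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                                c: np.ndarray) -> np.ndarray:
    """Squared distance from points ``p`` to triangles ``(a, b, c)`` (paired rows).

    Closest-feature handling (face interior, edges, vertices) after Ericson,
    vectorized over rows.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    closest[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    closest[m] = c[m]
    done |= m
    # edge AB
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    if m.any():
        t = d1[m] / (d1[m] - d3[m])
        closest[m] = a[m] + t[:, None] * ab[m]
    done |= m
    # edge AC
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    if m.any():
        t = d2[m] / (d2[m] - d6[m])
        closest[m] = a[m] + t[:, None] * ac[m]
    done |= m
    # edge BC
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    if m.any():
        t = (d4[m] - d3[m]) / ((d4[m] - d3[m]) + (d5[m] - d6[m]))
        closest[m] = b[m] + t[:, None] * (c[m] - b[m])
    done |= m
    # face interior
    m = ~done
    if m.any():
        denom = va[m] + vb[m] + vc[m]
        v = vb[m] / denom
        w = vc[m] / denom
        closest[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    diff = p - closest
    return np.einsum("ij,ij->i", diff, diff)


def point_to_mesh_distance(points: np.ndarray, mesh: TriangleMesh) -> np.ndarray:
    """Exact unsigned Euclidean distance from each point to the mesh surface.

    Accelerated with a kd-tree on face centroids; the candidate set is pruned
    conservatively, so the result equals the brute-force minimum over all faces.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if mesh.n_faces == 0:
        raise ValueError("empty mesh")
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    centroids = tri.mean(axis=1)
    # per-face radius: max distance centroid -> corner
    rad = np.sqrt(np.max(np.einsum("fkj,fkj->fk", tri - centroids[:, None, :],
                                   tri - centroids[:, None, :]), axis=1))
    rmax = rad.max()
    tree = cKDTree(centroids)
    k = min(8, mesh.n_faces)
    _, nearest = tree.query(points, k=k, workers=-1)
    nearest = np.atleast_2d(nearest.reshape(len(points), k))
    # upper bound from the k nearest-centroid faces
    rep = np.repeat(np.arange(len(points)), k)
    cand = nearest.ravel()
    d2 = _point_triangle_distance_sq(points[rep], tri[cand, 0], tri[cand, 1], tri[cand, 2])
    upper = np.sqrt(d2.reshape(len(points), k).min(axis=1))
    # all faces whose slab [centroid-dist - rad, ...] could beat the bound
    lists = tree.query_ball_point(points, upper + rmax + 1e-12, workers=-1)
    ip = np.concatenate([np.full(len(l), i) for i, l in enumerate(lists)])
    fc = np.concatenate([np.asarray(l, dtype=np.int64) for l in lists])
    d2_all = _point_triangle_distance_sq(points[ip], tri[fc, 0], tri[fc, 1], tri[fc, 2])
    best = upper ** 2
    np.minimum.at(best, ip, d2_all)
    return np.sqrt(best)
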