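"""Surface-quality and longitudinal-consistency metrics.

Quality of a single reconstruction against a reference surface:

* **ASSD** — average symmetric surface distance between uniformly sampled
  point sets and the opposing mesh.
* **HDX** — symmetric percentile Hausdorff distance (HD100 is the classical
  Hausdorff distance; HD90/HD99 are robust to isolated outliers).
* **SIF** — fraction of faces properly intersecting another, non-adjacent face
  of the same mesh.

Consistency of a longitudinal sequence reconstructed with shared connectivity:

* **MCVar / CThVar** — per-vertex unbiased sample variance across visits of
  discrete mean curvature / cortical thickness, summarized per subject by the
  median over vertices (lower = more consistent).
* **ParcF1** — support-weighted F1 of parcellation labels matched by
  nearest-neighbour vertices across visit pairs (higher = more consistent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.metrics import f1_score

from .surface_io import (TriangleMesh, SurfaceSequence, VertexScalarField,
                         point_to_mesh_distance, sample_surface_points)


@dataclass
class MetricReport:
    """Container for per-scan quality and per-subject consistency scores."""

    per_scan: dict = field(default_factory=dict)
    per_subject: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Surface quality
# ---------------------------------------------------------------------------

def _directed_distances(src: TriangleMesh, dst: TriangleMesh, n: int, seed):
    pts = sample_surface_points(src, n, rng_seed=seed)
    return point_to_mesh_distance(pts, dst)


def assd(pred: TriangleMesh, ref: TriangleMesh, n: int = 100_000, seed=None) -> float:
    """Average symmetric surface distance (mm): mean of point-to-surface
    distances pooled over both sampling directions."""
    d_pr = _directed_distances(pred, ref, n, seed)
    d_rp = _directed_distances(ref, pred, n, None if seed is None else seed + 1)
    return float((d_pr.sum() + d_rp.sum()) / (len(d_pr) + len(d_rp)))


def hdx(pred: TriangleMesh, ref: TriangleMesh, percentile: float = 90.0,
        n: int = 100_000, seed=None) -> float:
    """Symmetric percentile Hausdorff distance (mm).

    The X-th percentile of each directed point-to-surface distance set is taken
    with linear interpolation of the empirical CDF (type-7 quantile), and the
    maximum of the two directions is returned.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    d_pr = _directed_distances(pred, ref, n, seed)
    d_rp = _directed_distances(ref, pred, n, None if seed is None else seed + 1)
    return float(max(np.percentile(d_pr, percentile), np.percentile(d_rp, percentile)))


# -- self-intersections ------------------------------------------------------

def _tri_tri_intersect(t1: np.ndarray, t2: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Vectorized proper triangle-triangle intersection test (paired rows).

    Interval test on the intersection line of the two supporting planes;
    coplanar pairs are resolved by a 2-D separating-axis test.  Touching at a
    measure-zero set within ``eps`` does not count.
    """
    n_pairs = len(t1)
    out = np.zeros(n_pairs, dtype=bool)
    if n_pairs == 0:
        return out

    n1 = np.cross(t1[:, 1] - t1[:, 0], t1[:, 2] - t1[:, 0])
    d1 = -np.einsum("ij,ij->i", n1, t1[:, 0])
    dist2 = np.einsum("ik,ijk->ij", n1, t2) + d1[:, None]

    n2 = np.cross(t2[:, 1] - t2[:, 0], t2[:, 2] - t2[:, 0])
    d2 = -np.einsum("ij,ij->i", n2, t2[:, 0])
    dist1 = np.einsum("ik,ijk->ij", n2, t1) + d2[:, None]

    scale = (np.linalg.norm(n1, axis=1) + np.linalg.norm(n2, axis=1))[:, None] + eps
    same_side2 = np.all(dist2 > eps * scale, axis=1) | np.all(dist2 < -eps * scale, axis=1)
    same_side1 = np.all(dist1 > eps * scale, axis=1) | np.all(dist1 < -eps * scale, axis=1)
    candidate = ~(same_side1 | same_side2)
    coplanar = candidate & np.all(np.abs(dist1) <= eps * scale, axis=1) \
        & np.all(np.abs(dist2) <= eps * scale, axis=1)
    generic = candidate & ~coplanar

    if generic.any():
        idx = np.where(generic)[0]
        out[idx] = _interval_test(t1[idx], t2[idx], n1[idx], n2[idx],
                                  dist1[idx], dist2[idx], eps)
    if coplanar.any():
        idx = np.where(coplanar)[0]
        out[idx] = np.array([_coplanar_test(t1[i], t2[i], n1[i], eps) for i in idx])
    return out


def _interval_test(t1, t2, n1, n2, dist1, dist2, eps):
    D = np.cross(n1, n2)
    axis = np.argmax(np.abs(D), axis=1)
    p1 = np.take_along_axis(t1[:, :, :], axis[:, None, None], axis=2)[:, :, 0]
    p2 = np.take_along_axis(t2[:, :, :], axis[:, None, None], axis=2)[:, :, 0]

    def interval(p, dist):
        # projections of the two edge crossings of the plane onto the line
        lo = np.full(len(p), np.inf)
        hi = np.full(len(p), -np.inf)
        for a, b in ((0, 1), (1, 2), (2, 0)):
            da, db = dist[:, a], dist[:, b]
            cross = (da * db) < 0
            denom = np.where(cross, da - db, 1.0)
            t = np.where(cross, da / denom, 0.0)
            proj = p[:, a] + t * (p[:, b] - p[:, a])
            lo = np.where(cross, np.minimum(lo, proj), lo)
            hi = np.where(cross, np.maximum(hi, proj), hi)
        # vertices lying exactly on the plane extend the interval
        on = np.abs(dist) <= 0
        for a in range(3):
            lo = np.where(on[:, a], np.minimum(lo, p[:, a]), lo)
            hi = np.where(on[:, a], np.maximum(hi, p[:, a]), hi)
        return lo, hi

    lo1, hi1 = interval(p1, dist1)
    lo2, hi2 = interval(p2, dist2)
    span = np.maximum(hi1 - lo1, hi2 - lo2) + eps
    return (np.minimum(hi1, hi2) - np.maximum(lo1, lo2)) > eps * span


def _coplanar_test(tri1, tri2, n, eps):
    """2-D separating-axis test for coplanar triangles."""
    axis = int(np.argmax(np.abs(n)))
    keep = [i for i in range(3) if i != axis]
    a = tri1[:, keep]
    b = tri2[:, keep]

    def edges(t):
        return [t[1] - t[0], t[2] - t[1], t[0] - t[2]]

    for e in edges(a) + edges(b):
        ax = np.array([-e[1], e[0]])
        pa = a @ ax
        pb = b @ ax
        if pa.max() <= pb.min() + eps or pb.max() <= pa.min() + eps:
            return False
    return True


def self_intersection_fraction(mesh: TriangleMesh) -> float:
    """Fraction of faces properly intersecting a non-adjacent face of the same
    mesh (faces sharing a vertex are never counted)."""
    F = mesh.n_faces
    if F == 0:
        return 0.0
    tri = mesh.vertices[mesh.faces]
    centroids = tri.mean(axis=1)
    rad = np.sqrt(np.max(np.einsum("fkj,fkj->fk", tri - centroids[:, None, :],
                                   tri - centroids[:, None, :]), axis=1))
    tree = cKDTree(centroids)
    pairs = tree.query_pairs(2.0 * rad.max() + 1e-12, output_type="ndarray")
    if len(pairs):
        # cull by the actual per-pair radius sum
        keep = np.linalg.norm(centroids[pairs[:, 0]] - centroids[pairs[:, 1]], axis=1) \
            <= rad[pairs[:, 0]] + rad[pairs[:, 1]]
        pairs = pairs[keep]
    if len(pairs):
        f1 = mesh.faces[pairs[:, 0]]
        f2 = mesh.faces[pairs[:, 1]]
        shares = (f1[:, :, None] == f2[:, None, :]).any(axis=(1, 2))
        pairs = pairs[~shares]
    bad = np.zeros(F, dtype=bool)
    if len(pairs):
        hit = _tri_tri_intersect(tri[pairs[:, 0]], tri[pairs[:, 1]])
        bad[pairs[hit, 0]] = True
        bad[pairs[hit, 1]] = True
    return float(bad.sum() / F)


# ---------------------------------------------------------------------------
# Longitudinal consistency
# ---------------------------------------------------------------------------

def cortical_thickness(white: TriangleMesh, pial: TriangleMesh) -> VertexScalarField:
    """Bilateral per-vertex thickness: the average of the shortest distance
    from each white vertex to the pial surface and from the corresponding pial
    vertex back to the white surface."""
    if white.n_vertices != pial.n_vertices:
        raise ValueError("white and pial surfaces must share vertex count and order")
    d_wp = point_to_mesh_distance(white.vertices, pial)
    d_pw = point_to_mesh_distance(pial.vertices, white)
    return VertexScalarField(0.5 * (d_wp + d_pw), name="cortical_thickness")


def longitudinal_variance(fields: list) -> tuple[VertexScalarField, float]:
    """Per-vertex unbiased sample variance across a subject's visits, plus the
    subject-level median over vertices.

    Serves both MCVar (curvature input) and CThVar (thickness input).  Requires
    at least two visits.
    """
    if len(fields) < 2:
        raise ValueError("longitudinal variance needs at least 2 visits")
    vals = np.stack([np.asarray(f.values if isinstance(f, VertexScalarField) else f)
                     for f in fields])
    var = vals.var(axis=0, ddof=1)
    return VertexScalarField(var, name="longitudinal_variance"), float(np.median(var))


def mcvar(sequence: SurfaceSequence, curvature_fn=None) -> tuple[VertexScalarField, float]:
    """Mean-curvature variance of a surface sequence (per vertex + subject
    median).  The magnitude of the discrete mean curvature is used, so the
    estimator's sign convention cannot affect the score."""
    from .surface_io import mean_curvature as _mc
    fn = curvature_fn or (lambda m: np.abs(_mc(m).values))
    return longitudinal_variance([fn(m) for m in sequence.meshes])


def cthvar(white_seq: SurfaceSequence, pial_seq: SurfaceSequence) -> tuple[VertexScalarField, float]:
    """Cortical-thickness variance across visits (per vertex + subject median)."""
    if white_seq.n_visits != pial_seq.n_visits:
        raise ValueError("white and pial sequences must have equal visit counts")
    th = [cortical_thickness(w, p).values
          for w, p in zip(white_seq.meshes, pial_seq.meshes)]
    return longitudinal_variance(th)


def parc_f1(sequence: SurfaceSequence, labels: VertexScalarField) -> float:
    """Support-weighted parcellation F1 across all ordered visit pairs.

    Labels live on the shared template vertex order and are propagated to every
    visit by vertex identity; for a pair (j, k) each vertex of visit j is
    matched to the spatially nearest vertex of visit k and the per-class F1 of
    (label_j(v), label_k(NN(v))) is weighted by class support.
    """
    if sequence.n_visits < 2:
        raise ValueError("ParcF1 needs at least 2 visits")
    lab = np.asarray(labels.values)
    if len(lab) != sequence.meshes[0].n_vertices:
        raise ValueError("label field does not align with the template vertex order")
    lab = lab.astype(np.int64)
    trees = [cKDTree(m.vertices) for m in sequence.meshes]
    scores = []
    for j in range(sequence.n_visits):
        for k in range(sequence.n_visits):
            if j == k:
                continue
            _, nn = trees[k].query(sequence.meshes[j].vertices, workers=-1)
            scores.append(f1_score(lab, lab[nn], average="weighted"))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def evaluate_scan(pred: TriangleMesh, ref: TriangleMesh, n: int = 100_000,
                  seed=None) -> dict:
    """ASSD, HD90, HD99 and SIF of one predicted surface against a reference."""
    return {
        "assd": assd(pred, ref, n=n, seed=seed),
        "hd90": hdx(pred, ref, 90.0, n=n, seed=seed),
        "hd99": hdx(pred, ref, 99.0, n=n, seed=seed),
        "sif": self_intersection_fraction(pred),
    }


def evaluate_subject(white_seq: SurfaceSequence, pial_seq: SurfaceSequence,
                     labels: VertexScalarField | None = None) -> dict:
    """Subject-level longitudinal consistency scores (medians over vertices)."""
    out = {
        "mcvar_white": mcvar(white_seq)[1],
        "mcvar_pial": mcvar(pial_seq)[1],
        "cthvar": cthvar(white_seq, pial_seq)[1],
    }
    if labels is not None:
        out["parcf1_white"] = parc_f1(white_seq, labels)
        out["parcf1_pial"] = parc_f1(pial_seq, labels)
    return out
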