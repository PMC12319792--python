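"""Mesh-space within-subject template creation.

A subject's visits, reconstructed with one shared connectivity, are aggregated
vertex-wise into a single template: the mean of the *generalized vertices*
(coordinates concatenated with per-vertex deep features).  To first order in
the integration step size, the mean of the per-visit flow solutions equals the
solution of the mean flow field, so the mesh-space mean is the deformable-
template aggregate of the subject's visits; because the sample mean is
unbiased, the template favours no particular visit.  Coordinate-wise median
aggregation is available as an alternative but is known to degrade surface
quality (more self-intersections, higher curvature variance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .deform_model import euler_integrate
from .surface_io import TriangleMesh, read_mesh, write_mesh


@dataclass
class GeneralizedVertices:
    """Vertex coordinates concatenated with per-vertex deep features."""

    coordinates: np.ndarray  # (V, 3)
    features: np.ndarray  # (V, D_f); D_f may be 0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim == 1:
            self.features = self.features.reshape(len(self.coordinates), -1)
        if len(self.features) != len(self.coordinates):
            raise ValueError("features and coordinates must align row-wise")

    @property
    def n_vertices(self) -> int:
        return len(self.coordinates)


@dataclass
class WithinSubjectTemplate:
    """Per-surface-class aggregated generalized vertices plus shared faces."""

    surfaces: dict  # surface class -> GeneralizedVertices
    faces: np.ndarray
    n_visits_used: int
    aggregation: Literal["mean", "median"] = "mean"

    def mesh(self, surface: str) -> TriangleMesh:
        return TriangleMesh(self.surfaces[surface].coordinates, self.faces)


def aggregate_generalized(visits: Sequence[GeneralizedVertices],
                          method: Literal["mean", "median"] = "mean") -> GeneralizedVertices:
    """Element-wise mean (or coordinate-wise median) over a subject's visits.

    Coordinates and features are aggregated by the same operator.
    """
    if len(visits) == 0:
        raise ValueError("cannot aggregate an empty visit list")
    V = visits[0].n_vertices
    Df = visits[0].features.shape[1]
    for j, g in enumerate(visits):
        if g.n_vertices != V or g.features.shape[1] != Df:
            raise ValueError(f"visit {j} vertex/feature shape mismatch")
    coords = np.stack([g.coordinates for g in visits])
    feats = np.stack([g.features for g in visits])
    if method == "mean":
        return GeneralizedVertices(coords.mean(axis=0), feats.mean(axis=0))
    if method == "median":
        return GeneralizedVertices(np.median(coords, axis=0), np.median(feats, axis=0))
    raise ValueError(f"unknown aggregation method {method!r}")


def aggregate_template(stage1_outputs: dict, faces: np.ndarray,
                       method: Literal["mean", "median"] = "mean") -> WithinSubjectTemplate:
    """Build the within-subject template from stage-1 reconstructions.

    ``stage1_outputs`` maps surface class -> list of per-visit
    :class:`GeneralizedVertices`.  All of a subject's visits always enter the
    aggregate (omitting later visits would bias the template toward earlier
    anatomy).
    """
    n_visits = None
    surfaces = {}
    for surf, visits in stage1_outputs.items():
        if n_visits is None:
            n_visits = len(visits)
        elif len(visits) != n_visits:
            raise ValueError("surface classes disagree on the number of visits")
        surfaces[surf] = aggregate_generalized(visits, method=method)
    if not surfaces:
        raise ValueError("no surfaces to aggregate")
    return WithinSubjectTemplate(surfaces=surfaces, faces=np.asarray(faces),
                                 n_visits_used=n_visits, aggregation=method)


# ---------------------------------------------------------------------------
# First-order equivalence of mean-of-solutions and solution-of-mean-field
# ---------------------------------------------------------------------------

def verify_mean_flow_equivalence(fields, v0: np.ndarray,
                                 step_sizes=(0.2, 0.1, 0.05),
                                 n_steps: int = 5) -> dict:
    """Quantify the gap between (a) the mean of per-visit Euler solutions and
    (b) the Euler solution under the mean field.

    ``fields`` is a list of callables ``f_j(t, V) -> dV/dt``.  The two
    quantities agree exactly when the fields are identical across visits or
    constant in ``V``.  For heterogeneous fields the agreement is first order
    in the deformation magnitude: the number of steps is held fixed and the
    step size is shrunk, so the total deformation scales with ``h`` while the
    gap shrinks as ``h^2`` (i.e., super-linearly — the mean template solves the
    mean-field flow to first order).  Returns ``{"gaps": {h: sup-norm gap},
    "ratios": [gap(h_i)/gap(h_{i+1})]}``.
    """
    v0 = np.asarray(v0, dtype=np.float64)
    J = len(fields)

    def mean_field(t, V):
        return sum(np.asarray(f(t, V)) for f in fields) / J

    gaps = {}
    for h in step_sizes:
        per_visit = [euler_integrate(f, v0, n_steps=n_steps, step_size=h) for f in fields]
        mean_of_solutions = np.mean(per_visit, axis=0)
        solution_of_mean = euler_integrate(mean_field, v0, n_steps=n_steps, step_size=h)
        gaps[h] = float(np.max(np.abs(mean_of_solutions - solution_of_mean)))
    hs = list(step_sizes)
    ratios = []
    for a, b in zip(hs[:-1], hs[1:]):
        ratios.append(gaps[a] / gaps[b] if gaps[b] > 0 else np.inf)
    return {"gaps": gaps, "ratios": ratios}


# ---------------------------------------------------------------------------
# Serialization: mesh files + feature sidecars
# ---------------------------------------------------------------------------

def save_template(template: WithinSubjectTemplate, out_dir, subject_id: str) -> dict:
    """Write per-surface mesh + feature-matrix sidecar + JSON metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {"subject_id": subject_id, "n_visits_used": template.n_visits_used,
            "aggregation": template.aggregation, "surfaces": {}}
    for surf, gv in template.surfaces.items():
        mesh_path = out_dir / f"{subject_id}_{surf}_template.ply"
        feat_path = out_dir / f"{subject_id}_{surf}_features.npy"
        write_mesh(template.mesh(surf), mesh_path, format="ply")
        np.save(feat_path, gv.features)
        meta["surfaces"][surf] = {"mesh": mesh_path.name, "features": feat_path.name,
                                  "feature_dim": int(gv.features.shape[1])}
    meta_path = out_dir / f"{subject_id}_template.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    return meta


def load_template(out_dir, subject_id: str) -> WithinSubjectTemplate:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / f"{subject_id}_template.json").read_text())
    surfaces = {}
    faces = None
    for surf, entry in meta["surfaces"].items():
        mesh = read_mesh(out_dir / entry["mesh"], format="ply")
        feats = np.load(out_dir / entry["features"])
        surfaces[surf] = GeneralizedVertices(mesh.vertices, feats)
        faces = mesh.faces
    return WithinSubjectTemplate(surfaces=surfaces, faces=faces,
                                 n_visits_used=meta["n_visits_used"],
                                 aggregation=meta["aggregation"])
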