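"""Synthetic longitudinal "cortex-like" cohorts.

Each subject is a pair of nested closed surfaces — an outer (pial-like) and an
inner (white-like) boundary — with known vertex correspondence across visits,
plus rasterized noisy volumes, a vertex parcellation, and covariates (baseline
age, visit times, diagnosis).  The outer shape is a sphere modulated by a
smooth random radial field (low-order spherical harmonics); the inner surface
is the outer one eroded inward along vertex normals by a smooth positive
thickness field.  Visits add a small smooth shape drift (diagnosis-independent)
and a diagnosis-dependent thickness loss proportional to time from baseline,
emulating accelerated cortical thinning in the disease group.  Volumes are
piecewise-constant occupancy images (bright white matter, intermediate gray
matter, dark background — a T1-like ordering) plus Gaussian noise; they are not
MRI-physics simulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.special import sph_harm_y
import scipy.sparse as sp
import trimesh as _trimesh

from .surface_io import TriangleMesh, VertexScalarField, read_mesh, vertex_normals, write_mesh
from .volume_grid import LABEL_BACKGROUND, LABEL_GRAY, LABEL_WHITE, ScalarVolume, rasterize_occupancy


def icosphere_template(subdivisions: int = 3, radius: float = 1.0,
                       center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Icosphere-derived spherical template with fixed connectivity."""
    tm = _trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(tm.vertices) + np.asarray(center, dtype=float),
                        np.asarray(tm.faces))


@dataclass
class SyntheticCohortConfig:
    """Study conditions of the synthetic longitudinal cohort.

    Defaults emulate a desk-scale analogue of a longitudinal aging/AD study:
    a mean of 4.4 visits per subject (SD 1.9, clipped to 2..5), ~2.5 mm mean
    cortical thickness, disease-group thinning of 0.1 mm/yr versus 0.01 mm/yr
    in controls, and 48^3 1 mm voxel grids.
    """

    n_subjects: int = 20
    visits_mean: float = 4.4
    visits_sd: float = 1.9
    visits_range: tuple = (2, 5)
    grid_shape: tuple = (48, 48, 48)
    template_subdivisions: int = 3
    radius_mm: float = 14.0
    radius_sd: float = 1.0
    bump_amplitude: float = 0.08       # relative SD of the radial harmonic field
    harmonic_degrees: tuple = (2, 3, 4)
    thickness_mm: float = 2.5
    thickness_variation: float = 0.4   # SD (mm) of the smooth thickness field
    min_thickness: float = 0.3
    drift_sd: float = 0.15             # per-visit radial drift SD (mm)
    atrophy_rate: dict = dc_field(default_factory=lambda: {0: 0.01, 1: 0.1})  # mm/yr
    group_proportions: dict = dc_field(default_factory=lambda: {0: 0.5, 1: 0.5})
    baseline_age_range: tuple = (60.0, 85.0)
    visit_spacing_range: tuple = (0.5, 1.5)  # years
    intensity: dict = dc_field(default_factory=lambda: {
        LABEL_BACKGROUND: 0.05, LABEL_GRAY: 0.6, LABEL_WHITE: 1.0})
    noise_sd: float = 0.05
    n_regions: int = 12
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for rate in self.atrophy_rate.values():
            if not np.isfinite(rate):
                raise ValueError("atrophy rates must be finite")

    def grid_affine(self) -> np.ndarray:
        return np.eye(4)  # 1 mm voxels, world = voxel indices

    def grid_center(self) -> np.ndarray:
        return (np.asarray(self.grid_shape, dtype=float) - 1) / 2.0


@dataclass
class SyntheticSubject:
    """One generated subject: per-visit ground truth and static covariates."""

    subject_id: str
    diagnosis: int
    baseline_age: float
    visit_times: np.ndarray                     # years since initial visit
    volumes: list                               # per visit ScalarVolume
    white_meshes: list                          # per visit TriangleMesh
    pial_meshes: list                           # per visit TriangleMesh
    thickness_fields: list                      # per visit (V,) injected thickness
    label_volumes: list                         # per visit int8 occupancy labels

    @property
    def n_visits(self) -> int:
        return len(self.visit_times)


# ---------------------------------------------------------------------------
# Smooth random fields on the sphere
# ---------------------------------------------------------------------------

def _real_sh_basis(directions: np.ndarray, degrees) -> np.ndarray:
    """Real spherical-harmonic basis evaluated at unit directions, (n, n_basis)."""
    x, y, z = directions[:, 0], directions[:, 1], directions[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    cols = []
    for l in degrees:
        for m in range(0, l + 1):
            Y = sph_harm_y(l, m, theta, phi)
            if m == 0:
                cols.append(np.real(Y))
            else:
                cols.append(np.sqrt(2.0) * np.real(Y))
                cols.append(np.sqrt(2.0) * np.imag(Y))
    return np.stack(cols, axis=1)


class _SphereField:
    """A random zero-mean smooth field on the sphere with unit marginal SD."""

    def __init__(self, rng: np.random.Generator, degrees):
        self.degrees = tuple(degrees)
        n_basis = sum(2 * l + 1 for l in self.degrees)
        decay = np.concatenate([np.full(2 * l + 1, 1.0 / (1 + l)) for l in self.degrees])
        self.coeffs = rng.standard_normal(n_basis) * decay
        # unit variance: E[field^2] = sum c^2 / (4 pi) for orthonormal basis
        norm = np.sqrt(np.sum(self.coeffs ** 2) / (4 * np.pi))
        self.coeffs = self.coeffs / max(norm, 1e-12)

    def __call__(self, directions: np.ndarray) -> np.ndarray:
        return _real_sh_basis(directions, self.degrees) @ self.coeffs


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------

def generate_subject(config: SyntheticCohortConfig, subject_seed: int,
                     subject_id: str | None = None,
                     template: TriangleMesh | None = None) -> SyntheticSubject:
    """Generate one fully reproducible synthetic subject."""
    rng = np.random.default_rng(subject_seed)
    cfg = config
    template = template or icosphere_template(cfg.template_subdivisions)
    dirs = template.vertices / np.linalg.norm(template.vertices, axis=1, keepdims=True)
    faces = template.faces
    center = cfg.grid_center()
    affine = cfg.grid_affine()

    diagnosis = int(rng.random() < cfg.group_proportions.get(1, 0.5))
    baseline_age = float(rng.uniform(*cfg.baseline_age_range))
    n_visits = int(np.clip(np.rint(rng.normal(cfg.visits_mean, cfg.visits_sd)),
                           cfg.visits_range[0], cfg.visits_range[1]))
    spacings = rng.uniform(*cfg.visit_spacing_range, size=n_visits - 1)
    visit_times = np.concatenate([[0.0], np.cumsum(spacings)])

    r0 = float(rng.normal(cfg.radius_mm, cfg.radius_sd))
    shape_field = _SphereField(rng, cfg.harmonic_degrees)(dirs)
    thickness_field = _SphereField(rng, cfg.harmonic_degrees)(dirs)
    thickness_base = np.clip(cfg.thickness_mm + cfg.thickness_variation * thickness_field,
                             cfg.min_thickness, 2.0 * cfg.thickness_mm)
    rate = cfg.atrophy_rate.get(diagnosis, 0.0)

    radial_base = r0 * (1.0 + np.clip(cfg.bump_amplitude * shape_field, -0.25, 0.25))

    volumes, whites, pials, th_fields, label_vols = [], [], [], [], []
    for j, w in enumerate(visit_times):
        drift = cfg.drift_sd * _SphereField(rng, cfg.harmonic_degrees)(dirs) \
            if cfg.drift_sd > 0 else np.zeros(len(dirs))
        radial = radial_base + drift
        outer_v = center + dirs * radial[:, None]
        outer = TriangleMesh(outer_v, faces)
        th = np.maximum(thickness_base - rate * w, cfg.min_thickness)
        normals = vertex_normals(outer)
        inner_v = outer_v - th[:, None] * normals
        inner = TriangleMesh(inner_v, faces)
        rel = inner_v - center
        inner_r = np.linalg.norm(rel, axis=1)
        # signed radial coordinate: negative or >= outer radius means crossing
        proj = np.einsum("ij,ij->i", rel, dirs)
        if np.any(proj <= 1e-3) or np.any(inner_r >= radial - 1e-3):
            raise ValueError(
                "generated inner surface crosses the outer surface; "
                "reduce bump_amplitude/thickness or drift")
        labels = rasterize_occupancy(inner, outer, cfg.grid_shape, affine)
        lut = np.zeros(3)
        for lab, val in cfg.intensity.items():
            lut[lab] = val
        data = lut[labels] + cfg.noise_sd * rng.standard_normal(labels.shape)
        volumes.append(ScalarVolume(data, affine.copy()))
        whites.append(inner)
        pials.append(outer)
        th_fields.append(th)
        label_vols.append(labels)

    return SyntheticSubject(
        subject_id=subject_id or f"sub-{subject_seed:06d}",
        diagnosis=diagnosis, baseline_age=baseline_age, visit_times=visit_times,
        volumes=volumes, white_meshes=whites, pial_meshes=pials,
        thickness_fields=th_fields, label_volumes=label_vols)


def generate_cohort(config: SyntheticCohortConfig,
                    template: TriangleMesh | None = None) -> list:
    """Generate the full cohort; per-subject seeds are spawned from the config
    seed, so any subject is reproducible in isolation."""
    ss = np.random.SeedSequence(config.rng_seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(config.n_subjects)]
    template = template or icosphere_template(config.template_subdivisions)
    return [generate_subject(config, seed, subject_id=f"sub-{i:03d}", template=template)
            for i, seed in enumerate(seeds)]


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

def generate_parcellation(template: TriangleMesh, n_regions: int,
                          seed=None) -> VertexScalarField:
    """Contiguous regions by farthest-point seeding and geodesic nearest-seed
    assignment on the mesh graph (a synthetic stand-in for a cortical atlas)."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    V = template.n_vertices
    e = template.edges()
    w = np.linalg.norm(template.vertices[e[:, 0]] - template.vertices[e[:, 1]], axis=1)
    G = sp.coo_matrix((np.concatenate([w, w]),
                       (np.concatenate([e[:, 0], e[:, 1]]),
                        np.concatenate([e[:, 1], e[:, 0]]))), shape=(V, V)).tocsr()
    seeds = [int(rng.integers(V))]
    dist = dijkstra(G, indices=seeds[0])
    while len(seeds) < min(n_regions, V):
        nxt = int(np.argmax(dist))
        seeds.append(nxt)
        dist = np.minimum(dist, dijkstra(G, indices=nxt))
    dall = dijkstra(G, indices=seeds)
    labels = np.argmin(dall, axis=0)
    return VertexScalarField(labels.astype(np.int64), name="parcellation")


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def export_cohort(cohort: list, out_dir) -> pd.DataFrame:
    """Write NIfTI volumes, mesh files, a covariate CSV, and a manifest CSV
    (one row per visit) consumable by the pipeline CLI."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cov_rows, man_rows = [], []
    for subj in cohort:
        cov_rows.append({"subject_id": subj.subject_id, "diagnosis": subj.diagnosis,
                         "baseline_age": subj.baseline_age, "n_visits": subj.n_visits})
        for j in range(subj.n_visits):
            stem = f"{subj.subject_id}_visit-{j}"
            vol_path = out_dir / f"{stem}.nii.gz"
            white_path = out_dir / f"{stem}.white.ply"
            pial_path = out_dir / f"{stem}.pial.ply"
            subj.volumes[j].save_nifti(vol_path)
            write_mesh(subj.white_meshes[j], white_path, format="ply")
            write_mesh(subj.pial_meshes[j], pial_path, format="ply")
            man_rows.append({"subject_id": subj.subject_id, "visit": j,
                             "time_years": float(subj.visit_times[j]),
                             "volume": vol_path.name, "white": white_path.name,
                             "pial": pial_path.name})
    cov = pd.DataFrame(cov_rows)
    man = pd.DataFrame(man_rows)
    cov.to_csv(out_dir / "covariates.csv", index=False)
    man.to_csv(out_dir / "manifest.csv", index=False)
    return man


def import_cohort(out_dir) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Re-read an exported cohort.  Returns (manifest, covariates, data) where
    ``data[(subject_id, visit)]`` holds the volume and mesh objects."""
    out_dir = Path(out_dir)
    man = pd.read_csv(out_dir / "manifest.csv")
    cov = pd.read_csv(out_dir / "covariates.csv")
    data = {}
    for row in man.itertuples():
        data[(row.subject_id, int(row.visit))] = {
            "volume": ScalarVolume.load(out_dir / row.volume),
            "white": read_mesh(out_dir / row.white, format="ply"),
            "pial": read_mesh(out_dir / row.pial, format="ply"),
        }
    return man, cov, data
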