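"""Two-stage longitudinal reconstruction pipeline.

Stage 1 deforms a generic population template to every scan and aggregates the
per-visit results (coordinates + deep vertex features) into one within-subject
template per subject.  Stage 2 deforms that subject template back to the
contours of each visit, giving the final surfaces with shared connectivity
across visits *and* subjects.  Training minimizes the combined mesh losses
(curvature-weighted Chamfer, edge, normal consistency) jointly for white and
pial surfaces; the checkpoint with the lowest validation ASSD is kept.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .deform_model import (Adam, DeformationModel, DeformationModelConfig, SurfaceGraph,
                           build_graph, init_parameters, init_stage2_from_stage1)
from .recon_metrics import assd
from .subject_template import (GeneralizedVertices, WithinSubjectTemplate,
                               aggregate_template)
from .surface_io import SurfaceSequence, TriangleMesh
from .synthetic_cortex import SyntheticCohortConfig, icosphere_template
from .train_losses import LossWeights, curvature_chamfer_weights, total_loss
from .volume_grid import FeaturePyramid, ScalarVolume, make_feature_pyramid

logger = logging.getLogger(__name__)


@dataclass
class ScanRecord:
    """One scan of one subject, with optional reference surfaces for training."""

    subject_id: str
    visit: int
    volume: ScalarVolume
    ref_white: TriangleMesh | None = None
    ref_pial: TriangleMesh | None = None
    pyramid: FeaturePyramid | None = None


@dataclass
class TrainConfig:
    """Optimization settings (non-canonical; tuned on the synthetic benchmark)."""

    epochs: int = 20
    lr: float = 2e-3
    n_ref_points: int = 3000        # reference points per surface per scan
    n_pred_points: int = 1500       # predicted points per Chamfer evaluation
    weights: LossWeights = field(default_factory=lambda: LossWeights(
        w_chamfer=1.0, w_edge=0.1, w_normal=0.1, w_voxel=0.0, n_loss_points=1500))
    val_interval: int = 5
    n_val_points: int = 4000
    rng_seed: int = 0


def make_population_template(cohort_config: SyntheticCohortConfig | None = None,
                             subdivisions: int | None = None):
    """Generic spherical white/pial template pair (the population-template
    analogue): concentric icospheres at the nominal outer radius and one
    nominal thickness inside, centred in the grid."""
    cfg = cohort_config or SyntheticCohortConfig()
    sub = subdivisions if subdivisions is not None else cfg.template_subdivisions
    center = cfg.grid_center()
    pial = icosphere_template(sub, radius=cfg.radius_mm, center=center)
    white = icosphere_template(sub, radius=cfg.radius_mm - cfg.thickness_mm, center=center)
    return white, pial


def _ensure_pyramid(scan: ScanRecord, model_config: DeformationModelConfig,
                    dtype=np.float32) -> FeaturePyramid:
    if scan.pyramid is None:
        pyr = make_feature_pyramid(scan.volume, sigmas=model_config.encoder_sigmas)
        pyr.levels = [lv.astype(dtype) for lv in pyr.levels]
        scan.pyramid = pyr
    return scan.pyramid


def _stacked_template(white: TriangleMesh, pial: TriangleMesh) -> np.ndarray:
    return np.vstack([white.vertices, pial.vertices])


def _split_vertices(stacked: np.ndarray, graph: SurfaceGraph):
    return stacked[graph.white_slice], stacked[graph.pial_slice]


def _scan_assd(model: DeformationModel, scan: ScanRecord, init_vertices, feats,
               n_points: int, seed: int) -> float:
    out = model.integrate(init_vertices, scan.pyramid, feats)
    w, p = _split_vertices(out["vertices"], model.graph)
    faces = model.graph.faces
    a_w = assd(TriangleMesh(w, faces), scan.ref_white, n=n_points, seed=seed)
    a_p = assd(TriangleMesh(p, faces), scan.ref_pial, n=n_points, seed=seed + 1)
    return 0.5 * (a_w + a_p)


def train_stage(stage: int, scans: list, model_config: DeformationModelConfig,
                train_config: TrainConfig, graph: SurfaceGraph,
                init_vertices_by_scan: dict, features_by_scan: dict | None = None,
                params_init: dict | None = None, val_scans: list | None = None,
                val_init_vertices: dict | None = None, val_features: dict | None = None):
    """Train one template-deformation stage.

    ``init_vertices_by_scan[(subject, visit)]`` supplies the stacked
    (white | pial) starting vertices for each scan: the population template in
    stage 1, the per-subject template in stage 2 (``features_by_scan``
    similarly supplies the template vertex features for stage 2).  Returns
    (best-validation params, history dict).
    """
    if stage == 2:
        missing = [s.subject_id for s in scans
                   if (s.subject_id, s.visit) not in init_vertices_by_scan]
        if missing:
            raise ValueError(f"missing within-subject template for subjects: "
                             f"{sorted(set(missing))}")
    rng = np.random.default_rng(train_config.rng_seed)
    params = copy.deepcopy(params_init) if params_init is not None \
        else init_parameters(model_config, rng_seed=train_config.rng_seed)
    model = DeformationModel(model_config, graph, params)
    adam = Adam(params, lr=train_config.lr)
    faces = graph.faces

    # per-scan reference point sets with curvature weights, sampled once
    refs = {}
    for i, scan in enumerate(scans):
        if scan.ref_white is None or scan.ref_pial is None:
            raise ValueError(f"scan {scan.subject_id}/{scan.visit} lacks reference surfaces")
        _ensure_pyramid(scan, model_config)
        seed = int(rng.integers(2 ** 31))
        refs[i] = {
            "white": curvature_chamfer_weights(scan.ref_white, train_config.n_ref_points,
                                               rng_seed=seed),
            "pial": curvature_chamfer_weights(scan.ref_pial, train_config.n_ref_points,
                                              rng_seed=seed + 1),
        }
    if val_scans:
        for scan in val_scans:
            _ensure_pyramid(scan, model_config)

    history = {"epoch_loss": [], "val_assd": [], "breakdowns": []}
    best = {"params": copy.deepcopy(params), "val_assd": np.inf}
    wts = train_config.weights
    wts = LossWeights(wts.w_chamfer, wts.w_edge, wts.w_normal, wts.w_voxel,
                      min(wts.n_loss_points, train_config.n_pred_points))

    def validate(epoch):
        if not val_scans:
            return None
        vals = []
        for scan in val_scans:
            key = (scan.subject_id, scan.visit)
            init = (val_init_vertices or init_vertices_by_scan)[key]
            feats = (val_features or features_by_scan or {}).get(key)
            vals.append(_scan_assd(model, scan, init, feats,
                                   train_config.n_val_points, seed=12345))
        v = float(np.mean(vals))
        history["val_assd"].append((epoch, v))
        if v < best["val_assd"]:
            best["val_assd"] = v
            best["params"] = copy.deepcopy(params)
        return v

    step_counter = 0
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(scans))
        epoch_loss = 0.0
        for i in order:
            scan = scans[i]
            key = (scan.subject_id, scan.visit)
            init = init_vertices_by_scan[key]
            feats = (features_by_scan or {}).get(key)
            out = model.integrate(init, scan.pyramid, feats, record=True)
            w, p = _split_vertices(out["vertices"], graph)
            pred = {"white": TriangleMesh(w, faces), "pial": TriangleMesh(p, faces)}
            references = {k: refs[i][k] for k in pred}
            loss, breakdown, grads = total_loss(
                pred, references, wts, rng_seed=step_counter, return_grad=True)
            grad_final = np.vstack([grads["white"], grads["pial"]])
            param_grads = model.backward(out["caches"], grad_final)
            adam.step(params, param_grads)
            epoch_loss += loss
            step_counter += 1
        history["epoch_loss"].append(epoch_loss / len(scans))
        if (epoch + 1) % train_config.val_interval == 0 or epoch == train_config.epochs - 1:
            v = validate(epoch)
            logger.info("stage %d epoch %d: loss=%.5f val_assd=%s",
                        stage, epoch, history["epoch_loss"][-1], v)
    if not val_scans:
        best["params"] = copy.deepcopy(params)
    return best["params"], history


def run_stage1_and_aggregate(model: DeformationModel, scans_by_subject: dict,
                             population_init: np.ndarray,
                             aggregation: str = "mean") -> dict:
    """Stage-1 inference on every visit and mesh-space aggregation into
    within-subject templates (coordinates and deep vertex features alike).

    ``scans_by_subject`` maps subject_id -> list of ScanRecord (all visits).
    """
    graph = model.graph
    V = graph.n_surface_vertices
    templates = {}
    for sid, scans in scans_by_subject.items():
        per_surface = {"white": [], "pial": []}
        for scan in sorted(scans, key=lambda s: s.visit):
            _ensure_pyramid(scan, model.config)
            out = model.integrate(population_init, scan.pyramid)
            vtx, feats = out["vertices"], out["features"]
            per_surface["white"].append(GeneralizedVertices(vtx[:V], feats[:V]))
            per_surface["pial"].append(GeneralizedVertices(vtx[V:], feats[V:]))
        templates[sid] = aggregate_template(per_surface, graph.faces, method=aggregation)
    return templates


def reconstruct(model2: DeformationModel, templates: dict,
                scans_by_subject: dict) -> dict:
    """Stage-2 inference: deform each subject's template to every visit.

    Returns ``{subject_id: {"white": SurfaceSequence, "pial": SurfaceSequence}}``;
    all output meshes share the template connectivity across visits and
    subjects.
    """
    graph = model2.graph
    faces = graph.faces
    results = {}
    for sid, scans in scans_by_subject.items():
        if sid not in templates:
            raise ValueError(f"no within-subject template for subject {sid}")
        tpl = templates[sid]
        init = np.vstack([tpl.surfaces["white"].coordinates, tpl.surfaces["pial"].coordinates])
        feats = np.vstack([tpl.surfaces["white"].features, tpl.surfaces["pial"].features])
        if model2.config.template_feature_dim == 0:
            feats = None
        elif feats.shape[1] != model2.config.template_feature_dim:
            raise ValueError("template feature width does not match the stage-2 model")
        whites, pials = [], []
        for scan in sorted(scans, key=lambda s: s.visit):
            _ensure_pyramid(scan, model2.config)
            out = model2.integrate(init, scan.pyramid, feats)
            w, p = _split_vertices(out["vertices"], graph)
            whites.append(TriangleMesh(w, faces))
            pials.append(TriangleMesh(p, faces))
        results[sid] = {
            "white": SurfaceSequence(sid, whites, "white"),
            "pial": SurfaceSequence(sid, pials, "pial"),
        }
    return results


# ---------------------------------------------------------------------------
# End-to-end benchmark driver (used by tests, the acceptance script, examples)
# ---------------------------------------------------------------------------

def scans_from_cohort(cohort: list, with_references: bool = True) -> dict:
    out = {}
    for subj in cohort:
        recs = []
        for j in range(subj.n_visits):
            recs.append(ScanRecord(
                subject_id=subj.subject_id, visit=j, volume=subj.volumes[j],
                ref_white=subj.white_meshes[j] if with_references else None,
                ref_pial=subj.pial_meshes[j] if with_references else None))
        out[subj.subject_id] = recs
    return out


def run_two_stage_benchmark(cohort_config: SyntheticCohortConfig,
                            train_config: TrainConfig | None = None,
                            model_seed: int = 0,
                            train_frac: float = 0.7, val_frac: float = 0.15,
                            metric_points: int = 10_000) -> dict:
    """Generate a cohort, train both stages, reconstruct held-out subjects and
    score accuracy (ASSD in voxels) plus longitudinal consistency of stage-1
    versus stage-2 outputs.
    """
    from .recon_metrics import evaluate_subject  # local import to avoid cycles
    tc = train_config or TrainConfig()
    cohort = generate_cohort_cached(cohort_config)
    white_t, pial_t = make_population_template(cohort_config)
    graph = build_graph(white_t, pial_t, virtual_edges=True)
    pop_init = _stacked_template(white_t, pial_t)

    n = len(cohort)
    n_train = max(1, int(round(train_frac * n)))
    n_val = max(1, int(round(val_frac * n)))
    train_subj = cohort[:n_train]
    val_subj = cohort[n_train:n_train + n_val]
    test_subj = cohort[n_train + n_val:]
    if not test_subj:
        raise ValueError("cohort too small for a held-out test split")

    cfg1 = DeformationModelConfig(rng_seed=model_seed)
    scans_train = [s for subj in train_subj for s in scans_from_cohort([subj])[subj.subject_id]]
    scans_val = [s for subj in val_subj for s in scans_from_cohort([subj])[subj.subject_id]]
    init1 = {(s.subject_id, s.visit): pop_init for s in scans_train + scans_val}
    tc1 = copy.deepcopy(tc)
    tc1.rng_seed = model_seed
    params1, hist1 = train_stage(1, scans_train, cfg1, tc1, graph, init1,
                                 val_scans=scans_val, val_init_vertices=init1)
    model1 = DeformationModel(cfg1, graph, params1)

    # stage-1 templates for all subjects
    all_scans = scans_from_cohort(cohort)
    templates = run_stage1_and_aggregate(model1, all_scans, pop_init)

    # stage-2 training on the same training subjects
    cfg2 = DeformationModelConfig(rng_seed=model_seed + 1,
                                  template_feature_dim=2 * cfg1.graph_feature_dim)
    params2_init = init_stage2_from_stage1(params1, cfg1, cfg2, rng_seed=model_seed + 1)

    def stage2_inputs(subjects):
        init, feats = {}, {}
        for subj in subjects:
            tpl = templates[subj.subject_id]
            iv = np.vstack([tpl.surfaces["white"].coordinates,
                            tpl.surfaces["pial"].coordinates])
            fv = np.vstack([tpl.surfaces["white"].features,
                            tpl.surfaces["pial"].features])
            for j in range(subj.n_visits):
                init[(subj.subject_id, j)] = iv
                feats[(subj.subject_id, j)] = fv
        return init, feats

    init2, feats2 = stage2_inputs(train_subj)
    init2v, feats2v = stage2_inputs(val_subj)
    tc2 = copy.deepcopy(tc)
    tc2.rng_seed = model_seed + 1
    params2, hist2 = train_stage(2, scans_train, cfg2, tc2, graph,
                                 init2, feats2, params_init=params2_init,
                                 val_scans=scans_val, val_init_vertices=init2v,
                                 val_features=feats2v)
    model2 = DeformationModel(cfg2, graph, params2)

    # held-out evaluation
    test_scans = {subj.subject_id: scans_from_cohort([subj])[subj.subject_id]
                  for subj in test_subj}
    recon2 = reconstruct(model2, templates, test_scans)

    V = graph.n_surface_vertices
    rows = []
    stage1_seqs = {}
    for subj in test_subj:
        whites1, pials1 = [], []
        for scan in test_scans[subj.subject_id]:
            out = model1.integrate(pop_init, scan.pyramid)
            w, p = _split_vertices(out["vertices"], graph)
            whites1.append(TriangleMesh(w, graph.faces))
            pials1.append(TriangleMesh(p, graph.faces))
        stage1_seqs[subj.subject_id] = {
            "white": SurfaceSequence(subj.subject_id, whites1, "white"),
            "pial": SurfaceSequence(subj.subject_id, pials1, "pial")}

    voxel_mm = float(np.linalg.norm(cohort_config.grid_affine()[:3, 0]))
    assd_vals = {1: [], 2: []}
    for subj in test_subj:
        for j, scan in enumerate(test_scans[subj.subject_id]):
            for stage, seqs in ((1, stage1_seqs), (2, recon2)):
                a_w = assd(seqs[subj.subject_id]["white"].meshes[j], subj.white_meshes[j],
                           n=metric_points, seed=1000 + j)
                a_p = assd(seqs[subj.subject_id]["pial"].meshes[j], subj.pial_meshes[j],
                           n=metric_points, seed=2000 + j)
                assd_vals[stage].append(0.5 * (a_w + a_p) / voxel_mm)

    cons = {1: [], 2: []}
    for subj in test_subj:
        for stage, seqs in ((1, stage1_seqs), (2, recon2)):
            s = seqs[subj.subject_id]
            cons[stage].append(evaluate_subject(s["white"], s["pial"]))

    def agg(stage, key):
        return float(np.mean([c[key] for c in cons[stage]]))

    return {
        "graph": graph, "models": {1: model1, 2: model2},
        "templates": templates, "history": {1: hist1, 2: hist2},
        "test_subjects": [s.subject_id for s in test_subj],
        "stage1_sequences": stage1_seqs, "stage2_sequences": recon2,
        "assd_voxels": {k: float(np.mean(v)) for k, v in assd_vals.items()},
        "mcvar": {k: 0.5 * (agg(k, "mcvar_white") + agg(k, "mcvar_pial")) for k in (1, 2)},
        "mcvar_white": {k: agg(k, "mcvar_white") for k in (1, 2)},
        "mcvar_pial": {k: agg(k, "mcvar_pial") for k in (1, 2)},
        "cthvar": {k: agg(k, "cthvar") for k in (1, 2)},
        "voxel_mm": voxel_mm,
    }


_COHORT_CACHE: dict = {}


def generate_cohort_cached(config: SyntheticCohortConfig):
    """Cohort generation memoized on the config (rasterization dominates)."""
    from .synthetic_cortex import generate_cohort
    key = repr(config)
    if key not in _COHORT_CACHE:
        _COHORT_CACHE[key] = generate_cohort(config)
    return _COHORT_CACHE[key]
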