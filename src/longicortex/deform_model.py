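"""Template-deformation network: image feature sampling, graph deformation
blocks, and Euler integration of the vertex flow.

The deformation of a template ``T`` toward the contours in an image ``X`` is the
initial value problem ``dV/dt = f_theta(t, X, V(t))``, ``V(0) = T``, solved with
an explicit Euler scheme on ``t in [0, 1]`` (five steps of size 0.2 by default).
``f_theta`` samples multi-resolution image features at the current vertex
positions by trilinear interpolation and feeds them, together with the (scaled)
coordinates, optional per-vertex template features, the integration time, and a
surface-class indicator, through residual graph-convolution blocks.  The
velocity head is zero-initialized, so an untrained model is exactly the
identity deformation.

White and pial surfaces are deformed jointly on one graph; optional *virtual
edges* connect corresponding white/pial vertices so each surface sees the
other's state, discouraging intersections.

All forward and backward passes are explicit numpy; gradients flow through the
full integration (backprop through time) including the spatial derivative of
the trilinear sampler.
"""

from __future__ import annotations

import hashlib
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .surface_io import TriangleMesh
from .volume_grid import FeaturePyramid, ScalarVolume, make_feature_pyramid, trilinear_sample

N_FILTER_CHANNELS_PER_LEVEL = 4  # intensity + 3 spatial gradients


@dataclass
class DeformationModelConfig:
    """Hyperparameters of one template-deformation network."""

    encoder_sigmas: tuple = (0.0, 1.0, 2.0)  # smoothing scales of the filter bank
    n_graph_blocks: int = 2
    graph_feature_dim: int = 64
    n_integration_steps: int = 5
    step_size: float = 0.2
    virtual_edges: bool = True
    template_feature_dim: int = 0  # D_f: per-vertex input features (stage 2)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.n_integration_steps * self.step_size - 1.0) > 1e-9:
            raise ValueError("n_integration_steps * step_size must equal 1")
        if self.graph_feature_dim < 1:
            raise ValueError("graph_feature_dim must be >= 1")

    @property
    def n_image_channels(self) -> int:
        return N_FILTER_CHANNELS_PER_LEVEL * len(self.encoder_sigmas)

    @property
    def input_dim(self) -> int:
        # image features | coords | template features | t | surface indicator
        return self.n_image_channels + 3 + self.template_feature_dim + 2


@dataclass
class DeformationState:
    """Vertex positions and per-block features at integration time ``t``."""

    vertices: np.ndarray
    block_features: np.ndarray | None
    t: float


class SurfaceGraph:
    """Joint graph over the white and pial template vertices.

    Nodes 0..V-1 are white vertices, V..2V-1 pial vertices.  Mesh edges come
    from the (shared) face array; with ``virtual_edges`` node ``v`` is linked to
    node ``V + v`` for every ``v``.
    """

    def __init__(self, white: TriangleMesh, pial: TriangleMesh, virtual_edges: bool = True):
        if white.n_vertices != pial.n_vertices or not np.array_equal(white.faces, pial.faces):
            raise ValueError("white and pial templates must share vertex count and connectivity")
        V = white.n_vertices
        self.n_surface_vertices = V
        self.faces = white.faces.copy()
        self.virtual_edges = virtual_edges
        e = white.edges()
        edges = [e, e + V]
        if virtual_edges:
            ve = np.stack([np.arange(V), np.arange(V) + V], axis=1)
            edges.append(ve)
            self.n_virtual_edges = V
        else:
            self.n_virtual_edges = 0
        e_all = np.vstack(edges)
        rows = np.concatenate([e_all[:, 0], e_all[:, 1]])
        cols = np.concatenate([e_all[:, 1], e_all[:, 0]])
        A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(2 * V, 2 * V)).tocsr()
        deg = np.asarray(A.sum(axis=1)).ravel()
        # neighbourhood-mean aggregation
        self.adjacency = sp.diags(1.0 / np.maximum(deg, 1)) @ A
        self.degrees = deg.astype(np.int64)
        self.surface_indicator = np.concatenate([np.zeros(V), np.ones(V)])
        self.white_slice = slice(0, V)
        self.pial_slice = slice(V, 2 * V)

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_surface_vertices

    def template_fingerprint(self) -> str:
        return hashlib.sha256(self.faces.tobytes()).hexdigest()[:16]


def build_graph(white: TriangleMesh, pial: TriangleMesh,
                virtual_edges: bool = True) -> SurfaceGraph:
    """Build the joint white+pial deformation graph."""
    return SurfaceGraph(white, pial, virtual_edges)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

def init_parameters(config: DeformationModelConfig, rng_seed: int | None = None) -> dict:
    """Glorot-initialized parameters; the velocity head is zero-initialized so
    the untrained flow is identically zero."""
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    h = config.graph_feature_dim

    def glorot(n_in, n_out):
        s = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-s, s, size=(n_in, n_out))

    params = {"W_in": glorot(config.input_dim, h), "b_in": np.zeros(h)}
    for i in range(config.n_graph_blocks):
        params[f"W_self_{i}"] = glorot(h, h)
        params[f"W_neigh_{i}"] = glorot(h, h)
        params[f"b_{i}"] = np.zeros(h)
    params["W_out"] = np.zeros((h, 3))
    params["b_out"] = np.zeros(3)
    return params


def init_stage2_from_stage1(params_stage1: dict, config_stage1: DeformationModelConfig,
                            config_stage2: DeformationModelConfig,
                            rng_seed: int = 0) -> dict:
    """Warm-start the template-deformation stage from the template-creation
    stage: copy every parameter except input layers whose width changed (those
    are freshly initialized, seeded)."""
    fresh = init_parameters(config_stage2, rng_seed=rng_seed)
    out = {}
    for k, v1 in params_stage1.items():
        if k not in fresh:
            raise ValueError(f"architectures differ outside input layers: extra tensor {k}")
        if fresh[k].shape == v1.shape:
            out[k] = v1.copy()
        elif k in ("W_in", "b_in"):
            out[k] = fresh[k]
        else:
            raise ValueError(
                f"shape mismatch outside input layers: {k} {v1.shape} vs {fresh[k].shape}")
    for k in fresh:
        if k not in out:
            raise ValueError(f"architectures differ outside input layers: missing tensor {k}")
    return out


# ---------------------------------------------------------------------------
# Flow field and integration
# ---------------------------------------------------------------------------

def _coord_frame(pyramid: FeaturePyramid) -> tuple[np.ndarray, float]:
    shape = np.array(pyramid.levels[0].shape[1:], dtype=float)
    A = pyramid.voxel_to_world
    center = A[:3, :3] @ ((shape - 1) / 2.0) + A[:3, 3]
    corner = A[:3, :3] @ (shape - 1) + A[:3, 3]
    scale = 0.5 * np.linalg.norm(corner - A[:3, 3])
    return center, float(scale)


class DeformationModel:
    """One template-deformation network (image filter bank + graph flow)."""

    def __init__(self, config: DeformationModelConfig, graph: SurfaceGraph,
                 params: dict | None = None):
        self.config = config
        self.graph = graph
        self.params = params if params is not None else init_parameters(config)

    # -- forward -----------------------------------------------------------

    def flow_field(self, state: DeformationState, pyramid: FeaturePyramid,
                   template_features: np.ndarray | None = None,
                   want_cache: bool = False):
        """Evaluate ``f_theta`` at the given state.

        Returns (velocities (n, 3), block feature matrix (n, 64 * n_blocks))
        and, with ``want_cache``, the intermediates needed for the backward
        pass.
        """
        cfg, p, g = self.config, self.params, self.graph
        V = state.vertices
        if not np.all(np.isfinite(V)):
            raise FloatingPointError("non-finite vertex coordinates in flow_field input")
        s, dsdV = trilinear_sample(pyramid, V, with_gradient=True)
        if not np.all(np.isfinite(s)):
            bad = np.where(~np.isfinite(s))[1]
            raise FloatingPointError(f"NaN in sampled image features (channel {bad[0]})")
        center, scale = _coord_frame(pyramid)
        xn = (V - center) / scale
        cols = [s, xn]
        if cfg.template_feature_dim:
            if template_features is None or template_features.shape[1] != cfg.template_feature_dim:
                raise ValueError("template_features with configured width required")
            cols.append(template_features)
        cols.append(np.full((len(V), 1), state.t))
        cols.append(g.surface_indicator[:, None])
        z0 = np.concatenate(cols, axis=1)
        a0 = z0 @ p["W_in"] + p["b_in"]
        hcur = np.maximum(a0, 0.0)
        hs, ms, acts = [hcur], [], []
        for i in range(cfg.n_graph_blocks):
            m = g.adjacency @ hcur
            a = hcur @ p[f"W_self_{i}"] + m @ p[f"W_neigh_{i}"] + p[f"b_{i}"]
            hcur = hcur + np.maximum(a, 0.0)
            ms.append(m)
            acts.append(a)
            hs.append(hcur)
        vel = hcur @ p["W_out"] + p["b_out"]
        feats = np.concatenate(hs[1:], axis=1)
        if want_cache:
            cache = {"z0": z0, "a0": a0, "hs": hs, "ms": ms, "acts": acts,
                     "dsdV": dsdV, "scale": scale}
            return vel, feats, cache
        return vel, feats

    def _backward_step(self, cache: dict, g_vel: np.ndarray, grads: dict) -> np.ndarray:
        """Backprop one flow evaluation; returns dL/d(vertices) through f."""
        cfg, p = self.config, self.params
        hs, ms, acts = cache["hs"], cache["ms"], cache["acts"]
        grads["W_out"] += hs[-1].T @ g_vel
        grads["b_out"] += g_vel.sum(axis=0)
        g_h = g_vel @ p["W_out"].T
        for i in reversed(range(cfg.n_graph_blocks)):
            g_r = g_h * (acts[i] > 0)
            grads[f"W_self_{i}"] += hs[i].T @ g_r
            grads[f"W_neigh_{i}"] += ms[i].T @ g_r
            grads[f"b_{i}"] += g_r.sum(axis=0)
            g_h = g_h + g_r @ p[f"W_self_{i}"].T \
                + self.graph.adjacency.T @ (g_r @ p[f"W_neigh_{i}"].T)
        g_a0 = g_h * (cache["a0"] > 0)
        grads["W_in"] += cache["z0"].T @ g_a0
        grads["b_in"] += g_a0.sum(axis=0)
        g_z0 = g_a0 @ p["W_in"].T
        Cs = cfg.n_image_channels
        g_s = g_z0[:, :Cs]
        g_xn = g_z0[:, Cs:Cs + 3]
        return g_xn / cache["scale"] + np.einsum("nc,ncw->nw", g_s, cache["dsdV"])

    def integrate(self, init_vertices: np.ndarray, pyramid: FeaturePyramid,
                  template_features: np.ndarray | None = None,
                  record: bool = False):
        """Euler-integrate the flow from the (stacked white|pial) template.

        Returns a dict with ``vertices`` (V(1)), ``features`` (per-block vertex
        features of the final flow evaluation), and with ``record=True`` the
        caches needed by :meth:`backward`.
        """
        cfg = self.config
        h = cfg.step_size
        V = np.array(init_vertices, dtype=np.float64)
        center, scale = _coord_frame(pyramid)
        diam = 2.0 * scale
        caches, feats = [], None
        for k in range(cfg.n_integration_steps):
            state = DeformationState(V, None, t=k * h)
            if record:
                vel, feats, cache = self.flow_field(state, pyramid, template_features,
                                                    want_cache=True)
                caches.append(cache)
            else:
                vel, feats = self.flow_field(state, pyramid, template_features)
            V = V + h * vel
            if np.max(np.abs(V - center)) > 10.0 * diam:
                raise FloatingPointError(
                    f"flow diverged at step {k}: max |V - center| exceeds 10x grid diameter")
        out = {"vertices": V, "features": feats}
        if record:
            out["caches"] = caches
        return out

    def backward(self, caches: list, grad_final_vertices: np.ndarray) -> dict:
        """Backprop through time: gradient of a loss on V(1) w.r.t. all
        parameters, chaining through every Euler step and the trilinear
        sampler's spatial derivative."""
        h = self.config.step_size
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        lam = np.array(grad_final_vertices, dtype=np.float64)
        for cache in reversed(caches):
            g_vel = h * lam
            lam = lam + self._backward_step(cache, g_vel, grads)
        return grads


def integrate_flow(template_vertices: np.ndarray, volume, model: DeformationModel,
                   template_features: np.ndarray | None = None) -> dict:
    """Convenience wrapper: build the feature pyramid from a raw volume (or use
    a pre-built one) and Euler-integrate the model's flow."""
    if isinstance(volume, ScalarVolume):
        pyramid = make_feature_pyramid(volume, sigmas=model.config.encoder_sigmas)
    else:
        pyramid = volume
    return model.integrate(template_vertices, pyramid, template_features)


def euler_integrate(f, v0: np.ndarray, n_steps: int = 5, step_size: float = 0.2) -> np.ndarray:
    """Plain explicit Euler for an arbitrary field ``f(t, V) -> dV/dt``."""
    V = np.array(v0, dtype=np.float64)
    for k in range(n_steps):
        V = V + step_size * np.asarray(f(k * step_size, V))
    return V


# ---------------------------------------------------------------------------
# Optimizer and checkpoints
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the usual bias correction."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_checkpoint(path, params: dict, config: DeformationModelConfig,
                    template_fingerprint: str, extra: dict | None = None) -> None:
    payload = {"params": params, "config": asdict(config),
               "template_fingerprint": template_fingerprint, "extra": extra or {}}
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_checkpoint(path):
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    cfg = DeformationModelConfig(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in payload["config"].items()})
    return payload["params"], cfg, payload["template_fingerprint"], payload["extra"]
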