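"""Graph construction, flow-field contracts, and Euler integration oracles."""

import copy

import numpy as np
import pytest

from longicortex.deform_model import (Adam, DeformationModel, DeformationModelConfig,
                                      DeformationState, build_graph, euler_integrate,
                                      init_parameters, init_stage2_from_stage1,
                                      load_checkpoint, save_checkpoint)
from longicortex.synthetic_cortex import icosphere_template
from longicortex.volume_grid import ScalarVolume, make_feature_pyramid


@pytest.fixture(scope="module")
def templates():
    center = (15.5, 15.5, 15.5)
    white = icosphere_template(1, radius=6.0, center=center)
    pial = icosphere_template(1, radius=8.0, center=center)
    return white, pial


@pytest.fixture(scope="module")
def pyramid():
    rng = np.random.default_rng(0)
    vol = ScalarVolume(rng.normal(0.5, 0.3, (32, 32, 32)), np.eye(4))
    return make_feature_pyramid(vol)


def _model(templates, seed=0, **kw):
    graph = build_graph(*templates, virtual_edges=kw.pop("virtual_edges", True))
    cfg = DeformationModelConfig(rng_seed=seed, **kw)
    return DeformationModel(cfg, graph)


class TestBuildGraph:
    def test_virtual_edge_counts(self, templates):
        g = build_graph(*templates, virtual_edges=True)
        assert g.n_nodes == 84
        assert g.n_virtual_edges == 42

    def test_degrees(self, templates):
        white, _ = templates
        g_on = build_graph(*templates, virtual_edges=True)
        g_off = build_graph(*templates, virtual_edges=False)
        e = white.edges()
        mesh_deg = np.bincount(e.ravel(), minlength=42)
        assert np.array_equal(g_off.degrees, np.concatenate([mesh_deg, mesh_deg]))
        assert np.array_equal(g_on.degrees, np.concatenate([mesh_deg, mesh_deg]) + 1)

    def test_vertex_count_mismatch_rejected(self, templates):
        white, _ = templates
        other = icosphere_template(2, radius=8.0)
        with pytest.raises(ValueError):
            build_graph(white, other)


class TestFlowField:
    def test_zero_initialized_head_gives_zero_velocity(self, templates, pyramid):
        model = _model(templates)
        init = np.vstack([templates[0].vertices, templates[1].vertices])
        vel, feats = model.flow_field(DeformationState(init, None, 0.0), pyramid)
        assert np.all(vel == 0.0)
        assert feats.shape == (84, 128)

    def test_permutation_equivariance(self, templates, pyramid, rng):
        """Permuting node order together with the graph permutes velocities."""
        model = _model(templates)
        for k, v in model.params.items():
            model.params[k] = rng.normal(0, 0.1, v.shape)
        init = np.vstack([templates[0].vertices, templates[1].vertices])
        vel, _ = model.flow_field(DeformationState(init, None, 0.2), pyramid)

        perm = rng.permutation(84)
        model_p = DeformationModel(model.config, copy.copy(model.graph), model.params)
        model_p.graph = copy.copy(model.graph)
        model_p.graph.adjacency = model.graph.adjacency[perm][:, perm]
        model_p.graph.surface_indicator = model.graph.surface_indicator[perm]
        vel_p, _ = model_p.flow_field(DeformationState(init[perm], None, 0.2), pyramid)
        assert np.allclose(vel_p, vel[perm], atol=1e-12)

    def test_sensitive_to_image_content(self, templates, pyramid, rng):
        model = _model(templates)
        for k, v in model.params.items():
            model.params[k] = rng.normal(0, 0.1, v.shape)
        init = np.vstack([templates[0].vertices, templates[1].vertices])
        vel1, _ = model.flow_field(DeformationState(init, None, 0.0), pyramid)
        vol2 = ScalarVolume(np.zeros((32, 32, 32)), np.eye(4))
        vel2, _ = model.flow_field(DeformationState(init, None, 0.0),
                                   make_feature_pyramid(vol2))
        assert not np.allclose(vel1, vel2)

    def test_nan_features_rejected(self, templates, pyramid):
        model = _model(templates)
        init = np.vstack([templates[0].vertices, templates[1].vertices])
        init[0] = np.nan
        with pytest.raises(FloatingPointError):
            model.flow_field(DeformationState(init, None, 0.0), pyramid)


class TestIntegration:
    def test_identity_flow_returns_template(self, templates, pyramid):
        model = _model(templates)
        init = np.vstack([templates[0].vertices, templates[1].vertices])
        out = model.integrate(init, pyramid)
        assert np.array_equal(out["vertices"], init)

    def test_constant_field_closed_form(self, rng):
        c = rng.normal(0, 1, 3)
        v0 = rng.normal(0, 1, (10, 3))
        v1 = euler_integrate(lambda t, V: np.broadcast_to(c, V.shape), v0)
        assert np.allclose(v1, v0 + c, atol=1e-12)

    def test_linear_field_matches_matrix_power_oracle(self, rng):
        """f(V) = V A^T integrates to V0 ((I + hA)^5)^T."""
        A = rng.normal(0, 0.3, (3, 3))
        v0 = rng.normal(0, 1, (15, 3))
        v1 = euler_integrate(lambda t, V: V @ A.T, v0, n_steps=5, step_size=0.2)
        M = np.linalg.matrix_power(np.eye(3) + 0.2 * A, 5)
        assert np.allclose(v1, v0 @ M.T, atol=1e-5)

    def test_determinism(self, templates, pyramid, rng):
        model = _model(templates)
        for k, v in model.params.items():
            model.params[k] = rng.normal(0, 0.05, v.shape)
        init = np.vstack([templates[0].vertices, templates[1].vertices])
        a = model.integrate(init, pyramid)["vertices"]
        b = model.integrate(init, pyramid)["vertices"]
        assert np.array_equal(a, b)

    def test_divergence_aborts(self, templates, pyramid):
        model = _model(templates)
        model.params["b_out"] = np.array([1e4, 0.0, 0.0])
        init = np.vstack([templates[0].vertices, templates[1].vertices])
        with pytest.raises(FloatingPointError, match="diverged"):
            model.integrate(init, pyramid)

    def test_backward_matches_finite_differences(self, templates, pyramid, rng):
        """End-to-end BPTT gradient equals central differences."""
        model = _model(templates)
        for k in model.params:
            if k != "b_out":
                model.params[k] = rng.normal(0, 0.05, model.params[k].shape)
        init = np.vstack([templates[0].vertices, templates[1].vertices])
        tgt = init + rng.normal(0, 0.1, init.shape)

        def loss(params):
            out = DeformationModel(model.config, model.graph, params).integrate(init, pyramid)
            return 0.5 * np.sum((out["vertices"] - tgt) ** 2)

        out = model.integrate(init, pyramid, record=True)
        grads = model.backward(out["caches"], out["vertices"] - tgt)
        for k in ("W_in", "W_neigh_0", "W_self_1", "W_out", "b_1"):
            idx = tuple(rng.integers(0, s) for s in model.params[k].shape)
            eps = 1e-6
            p_hi = copy.deepcopy(model.params)
            p_lo = copy.deepcopy(model.params)
            p_hi[k][idx] += eps
            p_lo[k][idx] -= eps
            num = (loss(p_hi) - loss(p_lo)) / (2 * eps)
            assert grads[k][idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestStage2Init:
    def test_degenerate_copy_when_widths_match(self):
        cfg = DeformationModelConfig(rng_seed=3)
        p1 = init_parameters(cfg)
        p2 = init_stage2_from_stage1(p1, cfg, DeformationModelConfig(rng_seed=9))
        for k in p1:
            assert np.array_equal(p1[k], p2[k])

    def test_non_input_tensors_copied_input_fresh(self, rng):
        cfg1 = DeformationModelConfig(rng_seed=3)
        cfg2 = DeformationModelConfig(rng_seed=3, template_feature_dim=128)
        p1 = init_parameters(cfg1)
        for k in p1:
            p1[k] = rng.normal(0, 0.1, p1[k].shape)
        p2 = init_stage2_from_stage1(p1, cfg1, cfg2, rng_seed=11)
        for k in p1:
            if k == "W_in":
                assert p2[k].shape[0] == cfg2.input_dim
            elif k == "b_in":
                pass
            else:
                assert np.array_equal(p1[k], p2[k])
        # fresh init detected: stage-2 input layer is not a zero-padded copy
        overlap = p2["W_in"][:cfg1.input_dim]
        assert not np.allclose(overlap, p1["W_in"])

    def test_mismatch_outside_input_layer_rejected(self):
        cfg1 = DeformationModelConfig(rng_seed=0)
        cfg2 = DeformationModelConfig(rng_seed=0, graph_feature_dim=32)
        p1 = init_parameters(cfg1)
        with pytest.raises(ValueError, match="outside input layers"):
            init_stage2_from_stage1(p1, cfg1, cfg2)


class TestCheckpointAndConfig:
    def test_config_invariant_enforced(self):
        with pytest.raises(ValueError):
            DeformationModelConfig(n_integration_steps=4, step_size=0.2)

    def test_checkpoint_round_trip(self, tmp_path, templates):
        model = _model(templates)
        fp = model.graph.template_fingerprint()
        path = tmp_path / "ckpt.pkl"
        save_checkpoint(path, model.params, model.config, fp)
        params, cfg, fp2, _ = load_checkpoint(path)
        assert fp2 == fp
        assert cfg == model.config
        for k in model.params:
            assert np.array_equal(params[k], model.params[k])

    def test_adam_reduces_quadratic(self, rng):
        params = {"x": rng.normal(0, 1, (5,))}
        opt = Adam(params, lr=0.1)
        for _ in range(200):
            opt.step(params, {"x": 2 * params["x"]})
        assert np.linalg.norm(params["x"]) < 1e-3
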