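"""Network invariances: permutation/translation symmetry, dense-conv oracle,
head properties, serialization."""

import numpy as np
import pytest

from surfppi import autodiff as ad
from surfppi.chemfeat import gather_vertex_chem_inputs
from surfppi.network import (
    ModelConfig,
    build_point_graphs,
    embed_chemistry,
    embed_geometry,
    forward_embeddings,
    init_model,
    interaction_head,
    interaction_scores,
    load_model,
    radius_convolution,
    save_model,
    site_head,
    site_scores,
)

from conftest import random_cloud


SMALL = ModelConfig(conv_radius=4.0, k_atoms=5, gcn_k=4)


def random_inputs(rng, n_points=40, cloud_n=20):
    cloud = random_cloud(rng, n=cloud_n, scale=4.0)
    points = rng.normal(scale=4.0, size=(n_points, 3))
    normals = rng.normal(size=(n_points, 3))
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    chem = gather_vertex_chem_inputs(points, cloud, k=SMALL.k_atoms, F=SMALL.F)
    k1 = rng.normal(scale=0.3, size=n_points)
    k2 = k1 + np.abs(rng.normal(scale=0.2, size=n_points))
    graphs = build_point_graphs(points, normals, SMALL)
    return cloud, points, normals, chem, k1, k2, graphs


class TestEmbedChemistry:
    def test_zero_parameters_give_zero_embeddings(self, rng):
        _, _, _, chem, _, _, graphs = random_inputs(rng)
        state = init_model(SMALL, seed=0)
        for name, p in state.params.items():
            if name.startswith("chem"):
                p.data[:] = 0.0
        out = embed_chemistry(chem, graphs, state)
        np.testing.assert_allclose(out.data, 0.0)

    def test_neighbor_record_permutation_invariance(self, rng):
        _, _, _, chem, _, _, graphs = random_inputs(rng)
        state = init_model(SMALL, seed=1)
        base = embed_chemistry(chem, graphs, state).data
        perm = rng.permutation(chem.k)
        import dataclasses

        shuffled = dataclasses.replace(
            chem,
            element_onehot=chem.element_onehot[:, perm],
            fourier=chem.fourier[:, perm],
            hydrophobicity=chem.hydrophobicity[:, perm],
            hbond=chem.hbond[:, perm],
            distances=chem.distances[:, perm],
            neighbor_indices=chem.neighbor_indices[:, perm],
            rel_pos=chem.rel_pos[:, perm],
        )
        out = embed_chemistry(shuffled, graphs, state).data
        np.testing.assert_allclose(out, base, atol=1e-6)

    def test_duplicated_records_leave_mean_unchanged(self, rng):
        _, _, _, chem, _, _, graphs = random_inputs(rng)
        state = init_model(SMALL, seed=1)
        base = embed_chemistry(chem, graphs, state).data
        import dataclasses

        doubled = dataclasses.replace(
            chem,
            element_onehot=np.tile(chem.element_onehot, (1, 2, 1)),
            fourier=np.tile(chem.fourier, (1, 2, 1)),
            hydrophobicity=np.tile(chem.hydrophobicity, (1, 2)),
            hbond=np.tile(chem.hbond, (1, 2)),
            distances=np.tile(chem.distances, (1, 2)),
            neighbor_indices=np.tile(chem.neighbor_indices, (1, 2)),
            rel_pos=np.tile(chem.rel_pos, (1, 2, 1)),
        )
        out = embed_chemistry(doubled, graphs, state).data
        np.testing.assert_allclose(out, base, atol=1e-6)


class TestEmbedGeometry:
    def test_pure_function_of_curvature_pair(self, rng):
        state = init_model(SMALL, seed=2)
        k1 = np.array([0.1, 0.5, 0.1])
        k2 = np.array([0.2, 0.7, 0.2])
        out = embed_geometry(k1, k2, state).data
        np.testing.assert_allclose(out[0], out[2], atol=1e-12)
        assert not np.allclose(out[0], out[1])

    def test_finite_for_large_curvatures(self):
        state = init_model(SMALL, seed=2)
        out = embed_geometry(np.array([-10.0, 10.0]), np.array([10.0, 10.0]), state)
        assert np.all(np.isfinite(out.data))

    def test_nan_curvature_rejected(self):
        state = init_model(SMALL, seed=2)
        with pytest.raises(ValueError):
            embed_geometry(np.array([np.nan]), np.array([0.0]), state)


def dense_radius_conv_reference(points, normals, feats, state, config):
    """O(V^2) masked-sum reference for the stacked radius convolution."""

    def linear(name, x):
        return x @ state.params[f"{name}.W"].data + state.params[f"{name}.b"].data

    v = len(points)
    d = np.linalg.norm(points[:, None] - points[None], axis=2)
    mask = d <= config.conv_radius
    x = feats.copy()
    for layer in range(config.n_conv_layers):
        g = np.maximum(linear(f"conv{layer}.pre", x), 0.0)
        out = np.zeros((v, g.shape[1]))
        for i in range(v):
            for j in np.flatnonzero(mask[i]):
                e = np.concatenate([points[j] - points[i], normals[j] - normals[i]])
                w = linear(f"conv{layer}.kernel.1",
                           np.tanh(linear(f"conv{layer}.kernel.0", e[None])))
                out[i] += w[0, 0] * g[j]
        x = linear(f"conv{layer}.post", out)
        if layer < config.n_conv_layers - 1:
            x = np.maximum(x, 0.0)
    return x


class TestRadiusConvolution:
    def test_matches_dense_oracle(self, rng):
        for trial in range(3):
            _, points, normals, _, _, _, graphs = random_inputs(rng, n_points=50)
            state = init_model(SMALL, seed=10 + trial)
            feats = rng.normal(size=(50, SMALL.fused_dim))
            fast = radius_convolution(graphs, ad.constant(feats), state).data
            slow = dense_radius_conv_reference(points, normals, feats, state, SMALL)
            np.testing.assert_allclose(fast, slow, atol=1e-5)

    def test_translation_invariance(self, rng):
        _, points, normals, _, _, _, _ = random_inputs(rng)
        state = init_model(SMALL, seed=3)
        feats = rng.normal(size=(len(points), SMALL.fused_dim))
        g1 = build_point_graphs(points, normals, SMALL)
        g2 = build_point_graphs(points + np.array([7.0, -3.0, 11.0]), normals, SMALL)
        out1 = radius_convolution(g1, ad.constant(feats), state).data
        out2 = radius_convolution(g2, ad.constant(feats), state).data
        np.testing.assert_allclose(out1, out2, atol=1e-5)

    def test_isolated_point_self_term_only(self, rng):
        state = init_model(SMALL, seed=4)
        points = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        normals = np.tile([0.0, 0, 1.0], (2, 1))
        graphs = build_point_graphs(points, normals, SMALL)
        feats = rng.normal(size=(2, SMALL.fused_dim))
        out = radius_convolution(graphs, ad.constant(feats), state).data

        def linear(name, x):
            return x @ state.params[f"{name}.W"].data + state.params[f"{name}.b"].data

        x = feats[0:1]
        for layer in range(SMALL.n_conv_layers):
            g = np.maximum(linear(f"conv{layer}.pre", x), 0.0)
            w = linear(f"conv{layer}.kernel.1",
                       np.tanh(linear(f"conv{layer}.kernel.0", np.zeros((1, 6)))))
            x = linear(f"conv{layer}.post", w[0, 0] * g)
            if layer < SMALL.n_conv_layers - 1:
                x = np.maximum(x, 0.0)
        np.testing.assert_allclose(out[0], x[0], atol=1e-9)

    def test_rotation_invariance_in_tangent_frame_mode(self, rng):
        cfg_rot = ModelConfig(conv_radius=4.0, k_atoms=5, gcn_k=4,
                              rotation_invariant_kernel=True)
        _, points, normals, _, _, _, _ = random_inputs(rng)
        state = init_model(cfg_rot, seed=5)
        feats = rng.normal(size=(len(points), cfg_rot.fused_dim))
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        g1 = build_point_graphs(points, normals, cfg_rot)
        g2 = build_point_graphs(points @ rot.T, normals @ rot.T, cfg_rot)
        out1 = radius_convolution(g1, ad.constant(feats), state).data
        out2 = radius_convolution(g2, ad.constant(feats), state).data
        np.testing.assert_allclose(out1, out2, atol=1e-6)


class TestEndToEnd:
    def test_translation_invariance_of_site_scores(self, rng):
        cloud, points, normals, chem, k1, k2, graphs = random_inputs(rng)
        state = init_model(SMALL, seed=6)
        scores1 = site_scores(forward_embeddings(chem, k1, k2, graphs, state), state)
        shift = np.array([13.0, 5.0, -2.0])
        chem_t = gather_vertex_chem_inputs(points + shift, cloud.translated(shift),
                                           k=SMALL.k_atoms, F=SMALL.F)
        graphs_t = build_point_graphs(points + shift, normals, SMALL)
        scores2 = site_scores(forward_embeddings(chem_t, k1, k2, graphs_t, state), state)
        np.testing.assert_allclose(scores1, scores2, atol=1e-5)

    def test_vertex_permutation_equivariance(self, rng):
        cloud, points, normals, chem, k1, k2, graphs = random_inputs(rng)
        state = init_model(SMALL, seed=7)
        base = site_scores(forward_embeddings(chem, k1, k2, graphs, state), state)
        perm = rng.permutation(len(points))
        chem_p = gather_vertex_chem_inputs(points[perm], cloud, k=SMALL.k_atoms,
                                           F=SMALL.F)
        graphs_p = build_point_graphs(points[perm], normals[perm], SMALL)
        out = site_scores(forward_embeddings(chem_p, k1[perm], k2[perm],
                                             graphs_p, state), state)
        np.testing.assert_allclose(out, base[perm], atol=1e-6)

    def test_deterministic_across_runs(self, rng):
        _, _, _, chem, k1, k2, graphs = random_inputs(rng)
        runs = []
        for _ in range(2):
            state = init_model(SMALL, seed=8)
            runs.append(site_scores(forward_embeddings(chem, k1, k2, graphs, state),
                                    state))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_stream_ablation_changes_output(self, rng):
        _, _, _, chem, k1, k2, graphs = random_inputs(rng)
        state = init_model(SMALL, seed=9)
        full = forward_embeddings(chem, k1, k2, graphs, state).data
        state.config.use_geom = False
        ablated = forward_embeddings(chem, k1, k2, graphs, state).data
        state.config.use_geom = True
        assert not np.allclose(full, ablated)


class TestHeads:
    def test_zero_logit_gives_half(self):
        state = init_model(SMALL, seed=0)
        for name in ("site.0", "site.1"):
            state.params[f"{name}.W"].data[:] = 0.0
            state.params[f"{name}.b"].data[:] = 0.0
        emb = ad.constant(np.random.default_rng(0).normal(size=(5, 8)))
        scores = site_scores(emb, state)
        np.testing.assert_allclose(scores, 0.5)

    def test_scores_strictly_inside_unit_interval(self, rng):
        state = init_model(SMALL, seed=11)
        emb = ad.constant(rng.normal(size=(50, 8)) * 5)
        s = site_scores(emb, state)
        assert np.all((s > 0) & (s < 1))

    def test_site_scores_monotone_in_logit(self, rng):
        state = init_model(SMALL, seed=11)
        emb = ad.constant(rng.normal(size=(20, 8)))
        logits = site_head(emb, state).data.reshape(-1)
        scores = site_scores(emb, state)
        order = np.argsort(logits)
        assert np.all(np.diff(scores[order]) >= 0)

    def test_interaction_symmetry_exact(self, rng):
        state = init_model(SMALL, seed=12)
        ea = ad.constant(rng.normal(size=(10, 8)))
        eb = ad.constant(rng.normal(size=(10, 8)))
        s_ab = interaction_scores(ea, eb, state)
        s_ba = interaction_scores(eb, ea, state)
        np.testing.assert_allclose(s_ab, s_ba, atol=1e-12)

    def test_equal_embeddings_zero_difference_branch(self, rng):
        state = init_model(SMALL, seed=12)
        e = rng.normal(size=(4, 8))
        logit_same = interaction_head(ad.constant(e), ad.constant(e), state)
        # reconstruct: with |e-e| = 0 the head sees [2e, 0]
        h_in = np.concatenate([2 * e, np.zeros_like(e)], axis=1)
        w0 = state.params["inter.0.W"].data
        b0 = state.params["inter.0.b"].data
        manual = np.maximum(h_in @ w0 + b0, 0.0) @ state.params["inter.1.W"].data \
            + state.params["inter.1.b"].data
        np.testing.assert_allclose(logit_same.data, manual, atol=1e-12)


class TestSerialization:
    def test_round_trip(self, tmp_path, rng):
        state = init_model(SMALL, seed=13)
        path = tmp_path / "model.npz"
        save_model(state, path)
        back = load_model(path)
        assert back.config == state.config
        for k in state.params:
            np.testing.assert_array_equal(back.params[k].data, state.params[k].data)

    def test_unknown_schema_rejected(self, tmp_path):
        path = tmp_path / "bad.npz"
        np.savez(path, __meta__=np.frombuffer(b'{"schema": "x"}', dtype=np.uint8))
        with pytest.raises(ValueError, match="schema"):
            load_model(path)


class TestModelConfig:
    def test_out_dim_fixed(self):
        with pytest.raises(ValueError):
            ModelConfig(out_dim=4)

    @pytest.mark.parametrize("field,value", [("conv_radius", 0.0), ("F", -1),
                                             ("hidden_dim", 0)])
    def test_invalid_fields(self, field, value):
        with pytest.raises(ValueError):
            ModelConfig(**{field: value})
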