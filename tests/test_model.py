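"""The message-passing committor model: basis functions, invariances,
attention, gradients, checkpointing."""

import numpy as np
import pytest

from graphcommittor.model import (
    CommittorModel,
    ModelConfig,
    ModelError,
    batched_z_closure,
    committor_gradient,
    cutoff_envelope,
    rbf_expand,
    sigmoid,
)
from graphcommittor.systems import (
    Configuration,
    SystemSpec,
    generate_dimer_bath,
    make_low_dim_configuration,
)

DIMER_SPEC = SystemSpec(3, "dimer_bath", {
    "bond_h": 6.0, "bond_r0": 1.12, "bond_w": 0.35,
    "wca_epsilon": 1.0, "wca_sigma": 1.0, "box_length": 7.0, "n_bath": 10})


def dimer_model(seed=0, use_attention=False, zero_init=False):
    config = ModelConfig(feature_dim=8, n_interactions=2, n_rbf=8,
                         rbf_cutoff=2.5, use_attention=use_attention,
                         sigmoid_p=3.0, seed=seed, zero_init_update=zero_init)
    return CommittorModel(config, species_codes=[1, 2],
                          graph_settings={"r_cut": 2.5, "delta_b": 0.5})


def random_dimer(seed, n_bath=10):
    return generate_dimer_bath(n_bath, 7.0, seed=seed, spec=DIMER_SPEC)


class TestRBF:
    def test_center_hit_gives_one(self):
        e = rbf_expand(1.0, n_rbf=5, rbf_cutoff=2.0)[0]
        assert e[2] == pytest.approx(1.0)  # centers at 0, .5, 1, 1.5, 2

    def test_midpoint_symmetry(self):
        e = rbf_expand(0.75, n_rbf=5, rbf_cutoff=2.0)[0]
        assert e[1] == pytest.approx(e[2])

    def test_closed_form_at_zero(self):
        n, cut = 5, 2.0
        centers = np.linspace(0, cut, n)
        gamma = 1.0 / (2 * (cut / (n - 1)) ** 2)
        e = rbf_expand(0.0, n, cut)[0]
        assert np.allclose(e, np.exp(-gamma * centers**2))

    def test_values_in_unit_interval(self):
        e = rbf_expand(np.linspace(0, 4, 50), 8, 2.5)
        assert np.all(e > 0) and np.all(e <= 1)

    def test_envelope_vanishes_at_cutoff(self):
        assert cutoff_envelope(2.5, 2.5) == 0.0
        assert cutoff_envelope(0.0, 2.5) == pytest.approx(1.0)
        assert cutoff_envelope(3.0, 2.5) == 0.0


class TestSigmoid:
    def test_half_at_zero(self):
        assert sigmoid(0.0, 3.0) == pytest.approx(0.5)

    def test_monotone_and_order_preserving(self):
        z = np.linspace(-5, 5, 41)
        q = sigmoid(z, 3.0)
        assert np.all(np.diff(q) > 0)


class TestForwardInvariances:
    def test_permutation_invariance(self):
        model = dimer_model()
        cfg = random_dimer(1)
        z0 = model.z_value(cfg)
        rng = np.random.default_rng(0)
        perm = np.concatenate([[0, 1], 2 + rng.permutation(cfg.n_atoms - 2)])
        cfg2 = Configuration(cfg.positions[perm], cfg.species[perm],
                             cfg.reacting[perm], cell=cfg.cell)
        assert model.z_value(cfg2) == pytest.approx(z0, abs=1e-10)

    def test_rotation_translation_invariance(self):
        model = dimer_model()
        cfg = random_dimer(2, n_bath=6)
        cfg.cell = None  # rigid rotation of a non-periodic cluster
        z0 = model.z_value(cfg)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        cfg2 = cfg.copy()
        cfg2.positions = cfg.positions @ R.T + np.array([1.0, -2.0, 0.5])
        assert model.z_value(cfg2) == pytest.approx(z0, abs=1e-8)

    def test_z_continuous_when_atom_crosses_cutoff(self):
        # cosine envelope: z is continuous across R_c (bisection probe)
        model = dimer_model()
        base = generate_dimer_bath(0, 12.0, seed=0)
        cfg = Configuration(
            np.vstack([base.positions, [[6.0 + 1.12 / 2 + 2.499, 6.0, 6.0]]]),
            np.array([1, 1, 2]), np.array([True, True, False]),
            cell=base.cell)
        z_in = model.z_value(cfg)
        cfg_out = cfg.copy()
        cfg_out.positions[2, 0] += 0.002  # now just beyond R_c from atom 1
        z_out = model.z_value(cfg_out)
        assert abs(z_in - z_out) < 1e-4

    def test_truncation_leaves_z_unchanged(self):
        model = dimer_model()
        for seed in range(5):
            cfg = random_dimer(seed, n_bath=20)
            graph = model.build_graph(cfg)
            kept = graph.node_atom_ids
            sub = Configuration(cfg.positions[kept], cfg.species[kept],
                                cfg.reacting[kept], cell=cfg.cell)
            assert model.z_value(sub) == pytest.approx(model.z_value(cfg),
                                                       abs=1e-6)

    def test_unknown_species_rejected(self):
        model = dimer_model()
        cfg = random_dimer(0)
        cfg.species[0] = 99  # a reacting atom, always retained in the graph
        with pytest.raises(ModelError):
            model.z_value(cfg)


class TestAttention:
    def test_scores_normalize_per_node(self):
        model = dimer_model(use_attention=True)
        for seed in range(5):
            cfg = random_dimer(seed)
            out = model.forward(cfg)
            assert len(out.attention_records) == model.config.n_interactions
            for alpha in out.attention_records:
                sums = np.zeros(out.graph.n_nodes)
                np.add.at(sums, out.graph.edge_dst, alpha)
                receiving = np.unique(out.graph.edge_dst)
                assert np.allclose(sums[receiving], 1.0, atol=1e-6)

    def test_single_neighbor_attention_is_one(self):
        model = dimer_model(use_attention=True)
        cfg = generate_dimer_bath(0, 8.0, seed=0)
        out = model.forward(cfg)
        for alpha in out.attention_records:
            assert np.allclose(alpha, 1.0)

    def test_mean_and_attention_agree_on_identical_messages(self):
        # a symmetric trimer: every incoming message to the center is identical
        cfg = Configuration(
            positions=np.array([[0.0, 0, 0], [1.2, 0, 0], [-1.2, 0, 0]]),
            species=np.array([1, 2, 2]),
            reacting=np.array([True, False, False]))
        z_mean = dimer_model(seed=4).z_value(cfg)
        z_att = dimer_model(seed=4, use_attention=True).z_value(cfg)
        # attention adds gate parameters, but with identical messages the
        # aggregate reduces to the plain average: compare the two aggregations
        # on the same parameters by zeroing the gate's effect is implicit in
        # softmax uniformity; here we only require both to be finite and the
        # attention weights to be uniform
        model = dimer_model(seed=4, use_attention=True)
        out = model.forward(cfg)
        center_in = out.graph.edge_dst == 0
        for alpha in out.attention_records:
            a = alpha[center_in]
            assert np.allclose(a, a[0], atol=1e-12)
        assert np.isfinite(z_mean) and np.isfinite(z_att)


class TestResidualIdentity:
    def test_zero_init_update_keeps_embeddings(self):
        model = dimer_model(zero_init=True)
        cfg = random_dimer(3)
        out = model.forward(cfg)
        emb = model.params["embed"][
            [model.species_map[int(s)] for s in out.graph.node_species]]
        assert np.allclose(out.node_features, emb)


class TestGradients:
    def test_matches_finite_differences(self):
        model = dimer_model(seed=5)
        for seed in range(3):
            cfg = random_dimer(seed, n_bath=6)
            _, grad_z, _ = committor_gradient(cfg, model)
            zf, graph = model.z_closure(cfg)
            h = 1e-5
            rng = np.random.default_rng(seed)
            for _ in range(4):
                atom = rng.integers(cfg.n_atoms)
                dim = rng.integers(3)
                pp, pm = cfg.positions.copy(), cfg.positions.copy()
                pp[atom, dim] += h
                pm[atom, dim] -= h
                fd = (zf(pp, model.params) - zf(pm, model.params)) / (2 * h)
                if abs(fd) > 1e-10:
                    assert grad_z[atom, dim] == pytest.approx(fd, rel=1e-4)

    def test_chain_rule_q_z(self):
        model = dimer_model(seed=6)
        cfg = random_dimer(4)
        grad_q, grad_z, _ = committor_gradient(cfg, model)
        out = model.forward(cfg)
        p = model.config.sigmoid_p
        assert np.allclose(grad_q, p * out.q * (1 - out.q) * grad_z, atol=1e-8)

    def test_excluded_atom_zero_gradient(self):
        model = dimer_model(seed=7)
        cfg = random_dimer(5, n_bath=15)
        graph = model.build_graph(cfg)
        excluded = sorted(set(range(cfg.n_atoms)) - set(graph.node_atom_ids))
        if not excluded:
            pytest.skip("all atoms inside R_t for this draw")
        _, grad_z, _ = committor_gradient(cfg, model, graph=graph)
        assert np.all(grad_z[excluded] == 0.0)

    def test_mass_scaled_norm(self):
        model = dimer_model(seed=8)
        cfg = random_dimer(6, n_bath=4)
        cfg.masses = np.full(cfg.n_atoms, 2.0)
        grad_q, _, gsq = committor_gradient(cfg, model)
        assert gsq == pytest.approx(np.sum(grad_q**2) / 2.0)


class TestBatchedForward:
    def test_matches_per_frame_forward(self):
        spec = SystemSpec(1, "double_well_1d",
                          {"barrier": 6.0, "anchor_half_width": 2.0})
        config = ModelConfig(feature_dim=8, n_interactions=1, n_rbf=8,
                             rbf_cutoff=4.5, seed=2, zero_init_update=False)
        model = CommittorModel(config, species_codes=[0, 100, 101],
                               graph_settings={"r_cut": 4.5, "delta_b": 0.5})
        frames = [make_low_dim_configuration(spec, [x])
                  for x in np.linspace(-1.5, 1.5, 7)]
        z_fn, _ = batched_z_closure(model, frames[0])
        z_batch = z_fn(np.stack([f.positions for f in frames]), model.params)
        z_single = [model.z_value(f) for f in frames]
        assert np.allclose(z_batch, z_single, atol=1e-12)

    def test_matches_with_attention(self):
        spec = SystemSpec(1, "double_well_1d",
                          {"barrier": 6.0, "anchor_half_width": 2.0})
        config = ModelConfig(feature_dim=8, n_interactions=2, n_rbf=8,
                             rbf_cutoff=4.5, use_attention=True, seed=3,
                             zero_init_update=False)
        model = CommittorModel(config, species_codes=[0, 100, 101],
                               graph_settings={"r_cut": 4.5, "delta_b": 0.5})
        frames = [make_low_dim_configuration(spec, [x]) for x in (-1.0, 0.2, 0.9)]
        z_fn, _ = batched_z_closure(model, frames[0])
        z_batch = z_fn(np.stack([f.positions for f in frames]), model.params)
        z_single = [model.z_value(f) for f in frames]
        assert np.allclose(z_batch, z_single, atol=1e-12)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        model = dimer_model(seed=9, use_attention=True)
        cfg = random_dimer(7)
        z0 = model.z_value(cfg)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = CommittorModel.load(path)
        assert loaded.z_value(cfg) == pytest.approx(z0, abs=1e-12)
        assert loaded.graph_settings == model.graph_settings
        assert loaded.config == model.config
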