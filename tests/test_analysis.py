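"""p_K weights, TSE clustering, FES projection and interpretability."""

import numpy as np
import pytest

from graphcommittor import presets
from graphcommittor.analysis import (
    AnalysisError,
    attention_profile,
    kolmogorov_weights,
    kolmogorov_weights_on_grid,
    project_fes,
    node_sensitivity,
    tse_modes,
)
from graphcommittor.oracle import solve_committor_grid
from graphcommittor.systems import make_low_dim_configuration


@pytest.fixture(scope="module")
def dw_model():
    spec = presets.double_well_spec()
    return spec, presets.default_model(spec, seed=11)


class TestKolmogorovWeights:
    def test_ratio_three_to_one(self, dw_model):
        spec, model = dw_model
        # pick two frames and check p_K ~ w * |grad q|^2 normalization
        frames = [make_low_dim_configuration(spec, [x]) for x in (-0.3, 0.4)]
        from graphcommittor.biasing import EPS_GRAD
        g = [model.gradients(f)[2] for f in frames]
        pk = kolmogorov_weights(frames, model, spec.beta)
        assert pk.sum() == pytest.approx(1.0)
        assert pk[0] / pk[1] == pytest.approx(
            (g[0] + EPS_GRAD) / (g[1] + EPS_GRAD), rel=1e-9)

    def test_uniform_rescaling_invariance(self, dw_model):
        spec, model = dw_model
        frames = [make_low_dim_configuration(spec, [x])
                  for x in np.linspace(-1, 1, 9)]
        pk0 = kolmogorov_weights(frames, model, spec.beta)
        for f in frames:
            f.weight *= 7.5
        assert np.allclose(kolmogorov_weights(frames, model, spec.beta), pk0)

    def test_grid_pk_band_mass_follows_flux_identity(self):
        # for the exact committor the reactive flux through each isosurface
        # is constant, so q is the CDF of p_K and P(a < q < b) = b - a
        spec = presets.double_well_spec()
        gc = presets.double_well_oracle(spec)
        pk = kolmogorov_weights_on_grid(gc)
        band = (gc.q_values > 0.2) & (gc.q_values < 0.8)
        assert pk[band].sum() == pytest.approx(0.6, abs=0.03)
        mean_q = np.sum(pk * gc.q_values)
        assert 0.4 <= mean_q <= 0.6
        # and p_K is nonetheless sharply localized in coordinate space:
        # the central quarter of the interior carries most of the mass
        x = gc.axes[0]
        central = np.abs(x) < 0.4
        assert pk[central].sum() > 0.85


class TestTSEModes:
    def test_single_cluster_mass_one(self):
        feats = np.random.default_rng(0).normal(size=(12, 3))
        res = tse_modes(list(range(12)), np.full(12, 1 / 12), None, k=1,
                        features=feats)
        assert res.mode_masses == pytest.approx([1.0])

    def test_two_blob_masses_recovered(self):
        rng = np.random.default_rng(1)
        blob1 = rng.normal(0.0, 0.05, size=(30, 4))
        blob2 = rng.normal(3.0, 0.05, size=(20, 4))
        feats = np.vstack([blob1, blob2])
        w = np.concatenate([np.full(30, 0.6 / 30), np.full(20, 0.4 / 20)])
        res = tse_modes(list(range(50)), w, None, k=2, features=feats, seed=0)
        assert sorted(np.round(res.mode_masses, 6)) == pytest.approx([0.4, 0.6])
        # medoids belong to their own clusters
        for c, m in enumerate(res.medoid_indices):
            assert res.mode_assignments[m] == c

    def test_k_larger_than_frames_rejected(self):
        feats = np.zeros((3, 2))
        with pytest.raises(AnalysisError):
            tse_modes(list(range(3)), np.full(3, 1 / 3), None, k=5,
                      features=feats)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        feats = rng.normal(size=(25, 3))
        w = np.full(25, 1 / 25)
        a = tse_modes(list(range(25)), w, None, k=3, features=feats, seed=5)
        b = tse_modes(list(range(25)), w, None, k=3, features=feats, seed=5)
        assert np.array_equal(a.mode_assignments, b.mode_assignments)
        assert np.array_equal(a.medoid_indices, b.medoid_indices)


class TestFES:
    def test_single_occupied_bin(self, dw_model):
        spec, _ = dw_model
        frames = [make_low_dim_configuration(spec, [0.01]),
                  make_low_dim_configuration(spec, [0.02])]
        fes, edges = project_fes(frames, [1.0, 1.0], ["x"],
                                 [np.linspace(-1, 1, 5)], beta=1.0)
        occupied = np.isfinite(fes)
        assert occupied.sum() == 1 and fes[occupied][0] == 0.0

    def test_weight_doubling_invariance(self, dw_model):
        spec, _ = dw_model
        rng = np.random.default_rng(0)
        frames = [make_low_dim_configuration(spec, [x])
                  for x in rng.uniform(-1.2, 1.2, 60)]
        w = rng.uniform(0.5, 2.0, 60)
        f1, _ = project_fes(frames, w, ["x"], [np.linspace(-1.5, 1.5, 13)], 1.0)
        f2, _ = project_fes(frames, 2 * w, ["x"], [np.linspace(-1.5, 1.5, 13)], 1.0)
        assert np.allclose(np.nan_to_num(f1), np.nan_to_num(f2))

    def test_boltzmann_inversion_recovers_potential(self):
        # unbiased double-well samples: F(x) ~ U(x) - min U where sampled
        from graphcommittor.systems import run_langevin
        spec = presets.double_well_spec(barrier=2.0)
        init = make_low_dim_configuration(spec, [-1.0])
        frames = run_langevin(spec, init, 50000, 5e-3, 1.0, seed=4,
                              save_stride=5)
        edges = np.linspace(-1.6, 1.6, 25)
        fes, _ = project_fes(frames, np.ones(len(frames)), ["x"], [edges],
                             spec.beta)
        centers = 0.5 * (edges[:-1] + edges[1:])
        u = spec.parameters["barrier"] * (centers**2 - 1) ** 2
        ok = np.isfinite(fes)
        assert np.nanmax(np.abs(fes[ok] - (u[ok] - u[ok].min()))) < 0.5

    def test_frames_outside_grid_rejected(self, dw_model):
        spec, _ = dw_model
        frames = [make_low_dim_configuration(spec, [5.0])]
        with pytest.raises(AnalysisError):
            project_fes(frames, [1.0], ["x"], [np.linspace(-1, 1, 5)], 1.0)


class TestSensitivity:
    def test_duplicating_frames_leaves_scores(self, dw_model):
        spec, model = dw_model
        frames = [make_low_dim_configuration(spec, [x]) for x in (-0.4, 0.3)]
        s1 = node_sensitivity(frames, model).per_atom_scores
        s2 = node_sensitivity(frames * 2, model).per_atom_scores
        assert np.allclose(s1, s2)

    def test_ranking_sorted_by_score(self, dw_model):
        spec, model = dw_model
        frames = [make_low_dim_configuration(spec, [x]) for x in (-0.4, 0.1)]
        rep = node_sensitivity(frames, model)
        scores = rep.per_atom_scores[rep.ranking]
        assert np.all(np.diff(scores) <= 1e-15)
        assert np.all(rep.per_atom_scores >= 0)

    def test_empty_dataset_rejected(self, dw_model):
        _, model = dw_model
        with pytest.raises(AnalysisError):
            node_sensitivity([], model)

    def test_frozen_anchor_atoms_still_scored_mobile_particle_dominates(self, dw_model):
        # gradients flow to anchors too, but the particle moves most signal
        spec, model = dw_model
        frames = [make_low_dim_configuration(spec, [x]) for x in (-0.2, 0.2)]
        rep = node_sensitivity(frames, model)
        assert rep.n_graphs == 2


class TestAttentionProfile:
    def test_requires_attention_model(self, dw_model):
        spec, model = dw_model
        assert not model.config.use_attention
        frames = [make_low_dim_configuration(spec, [0.0])]
        with pytest.raises(AnalysisError, match="attention"):
            attention_profile(frames, model, (100, "reacting"),
                              np.linspace(0, 4.5, 10))

    def test_bad_selector_rejected(self):
        spec = presets.dimer_spec(n_bath=4)
        model = presets.default_model(spec, seed=1, use_attention=True)
        frames = [presets.dimer_configuration(spec, seed=3)]
        with pytest.raises(AnalysisError, match="matches no edges"):
            attention_profile(frames, model, (77, "reacting"),
                              np.linspace(0, 2.5, 8))

    def test_profile_normalized_to_unit_range(self):
        spec = presets.dimer_spec(n_bath=10)
        model = presets.default_model(spec, seed=2, use_attention=True)
        frames = [presets.dimer_configuration(spec, seed=s) for s in range(4)]
        prof = attention_profile(frames, model, (2, "reacting"),
                                 np.linspace(0.8, 2.5, 9))
        att = prof.mean_attention_per_bin
        ok = np.isfinite(att)
        assert np.nanmin(att[ok]) == pytest.approx(0.0)
        assert np.nanmax(att[ok]) == pytest.approx(1.0)
        assert np.nanmax(prof.reference_rdf_per_bin) == pytest.approx(1.0)
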