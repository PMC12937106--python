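"""Canonical study systems and end-to-end workflow helpers.

This module fixes, in one place, the reference conditions under which the
method is exercised and validated:

- ``flat``: free diffusion on [0, 1] with reflecting walls, states at the
  ends; the exact committor is linear between the state edges.
- ``double well`` (1D): U = h (x^2 - 1)^2 with h = 6 at beta = 1, i.e. a
  6 k_B T barrier — high enough that unbiased transitions are rare on the
  simulated timescales, low enough that a high-temperature run crosses
  freely and can seed the transition-state region.
- ``dimer in a bath``: two reacting atoms with a double-well bond potential
  (compact/extended minima, 6 k_B T barrier) among purely repulsive bath
  particles in a periodic box; the committor is controlled by the bond
  length by construction.

Training data follows the iterative philosophy of the method: labeled
frames from short unbiased runs inside each basin, optionally augmented
with transition-state-region frames from a pre-biasing stage.  At desk
scale that stage is a high-temperature run at ``beta_hot``, recorded as a
biased run with ``V = (beta_hot/beta - 1) U`` so the standard
``exp(+beta V)`` reweighting applies exactly.
"""

from __future__ import annotations

import numpy as np

from .model import CommittorModel, ModelConfig
from .oracle import GridCommittor, solve_committor_grid
from .systems import (
    Configuration,
    StateDefinition,
    SystemSpec,
    generate_dimer_bath,
    make_low_dim_configuration,
    potential_energy,
    run_langevin,
)
from .training import LabeledDataset, TrainSettings, reweight_frames, train_committor
from .systems import assign_state_label

__all__ = [
    "flat_spec", "flat_states", "double_well_spec", "double_well_states",
    "dimer_spec", "dimer_states", "default_model", "default_train_settings",
    "basin_dataset", "ts_seeded_dataset", "double_well_oracle", "flat_oracle",
    "model_q_on_axis", "train_default",
]


# ---------------------------------------------------------------------------
# systems


def flat_spec(beta: float = 1.0) -> SystemSpec:
    return SystemSpec(1, "flat", {"lo": 0.0, "hi": 1.0}, beta=beta)


def flat_states() -> list[StateDefinition]:
    return [StateDefinition("A", {"x": (None, 0.1)}),
            StateDefinition("B", {"x": (0.9, None)})]


def double_well_spec(barrier: float = 6.0, beta: float = 1.0) -> SystemSpec:
    return SystemSpec(1, "double_well_1d",
                      {"barrier": barrier, "anchor_half_width": 2.0}, beta=beta)


def double_well_states() -> list[StateDefinition]:
    return [StateDefinition("A", {"x": (None, -0.8)}),
            StateDefinition("B", {"x": (0.8, None)})]


def dimer_spec(n_bath: int = 8, box_length: float = 6.5,
               beta: float = 1.0) -> SystemSpec:
    return SystemSpec(3, "dimer_bath", {
        "bond_h": 6.0, "bond_r0": 1.12, "bond_w": 0.35,
        "wca_epsilon": 1.0, "wca_sigma": 1.0,
        "box_length": box_length, "n_bath": n_bath,
    }, beta=beta)


def dimer_states() -> list[StateDefinition]:
    # bond minima at 1.12 and 1.82, barrier at 1.47
    return [StateDefinition("A", {"bond_length": (None, 1.30)}),
            StateDefinition("B", {"bond_length": (1.64, None)})]


def dimer_configuration(spec: SystemSpec, seed: int,
                        bond_length: float | None = None) -> Configuration:
    p = spec.parameters
    return generate_dimer_bath(int(p["n_bath"]), p["box_length"], seed,
                               spec=spec, bond_length=bond_length)


# ---------------------------------------------------------------------------
# models


def default_model(spec: SystemSpec, seed: int = 0,
                  use_attention: bool | None = None) -> CommittorModel:
    """The reference architecture for each study system."""
    if spec.potential_id == "dimer_bath":
        config = ModelConfig(
            feature_dim=8, n_interactions=1, n_rbf=8, rbf_cutoff=2.5,
            use_attention=True if use_attention is None else use_attention,
            readout_widths=(16,), sigmoid_p=3.0, seed=seed,
            zero_init_update=False,
        )
        return CommittorModel(config, species_codes=[1, 2],
                              graph_settings={"r_cut": 2.5, "delta_b": 0.5})
    cutoff = 1.2 if spec.potential_id == "flat" else 4.5
    config = ModelConfig(
        feature_dim=8, n_interactions=1, n_rbf=8 if spec.potential_id == "flat" else 10,
        rbf_cutoff=cutoff,
        use_attention=False if use_attention is None else use_attention,
        readout_widths=(16,), sigmoid_p=3.0, seed=seed,
        zero_init_update=False,
    )
    species = [0, 100, 101] if spec.dimensionality == 1 else [0, 100, 101, 102]
    return CommittorModel(config, species_codes=species,
                          graph_settings={"r_cut": cutoff, "delta_b": 0.5})


def default_train_settings(spec: SystemSpec, seed: int = 0) -> TrainSettings:
    if spec.potential_id == "dimer_bath":
        return TrainSettings(alpha1=100.0, alpha2=1.0, z_r=5.0,
                             learning_rate=5e-3, epochs=140, warmup_epochs=40,
                             seed=seed)
    if spec.potential_id == "flat":
        # without a barrier the committor extends to the state edges, so the
        # boundary term needs more weight to keep q pinned inside the slabs
        return TrainSettings(alpha1=300.0, alpha2=1.0, z_r=5.0,
                             learning_rate=1e-2, epochs=400, warmup_epochs=60,
                             seed=seed)
    return TrainSettings(alpha1=100.0, alpha2=1.0, z_r=5.0,
                         learning_rate=5e-3, epochs=300, warmup_epochs=60,
                         seed=seed)


# ---------------------------------------------------------------------------
# datasets


def _low_dim_start(spec: SystemSpec, x: float) -> Configuration:
    return make_low_dim_configuration(spec, [x])


def basin_dataset(spec: SystemSpec, states, seed: int,
                  n_steps: int = 6000, dt: float = 5e-3, friction: float = 1.0,
                  save_stride: int = 20) -> LabeledDataset:
    """Short unbiased runs started inside each basin (plus one from the
    middle for the flat system, where there is no barrier to confine it)."""
    if spec.potential_id == "flat":
        starts = [(seed + 1, 0.05), (seed + 2, 0.95), (seed + 3, 0.5)]
        scheme = "overdamped"
        frames = []
        for s, x0 in starts:
            frames += run_langevin(spec, _low_dim_start(spec, x0), n_steps,
                                   dt, friction, seed=s, save_stride=save_stride)
    elif spec.potential_id == "double_well_1d":
        frames = []
        for s, x0 in [(seed + 1, -1.0), (seed + 2, 1.0)]:
            frames += run_langevin(spec, _low_dim_start(spec, x0), n_steps,
                                   dt, friction, seed=s, save_stride=save_stride)
    elif spec.potential_id == "dimer_bath":
        frames = []
        for s, r0 in [(seed + 1, spec.parameters["bond_r0"]),
                      (seed + 2, spec.parameters["bond_r0"] + 2 * spec.parameters["bond_w"])]:
            start = dimer_configuration(spec, seed=s, bond_length=r0)
            frames += run_langevin(spec, start, n_steps, dt=2e-3,
                                   friction=2.0, seed=s, save_stride=save_stride,
                                   scheme="baoab")
    else:
        raise ValueError(f"no basin preset for {spec.potential_id!r}")
    return LabeledDataset.from_frames(frames, states, spec.beta)


def hot_dataset(spec: SystemSpec, states, seed: int, beta_hot_factor: float = 0.25,
                n_steps: int = 8000, dt: float = 5e-3, friction: float = 1.0,
                save_stride: int = 20) -> LabeledDataset:
    """High-temperature run recorded as a biased run (transition-state seed).

    Sampling at ``beta_hot = f * beta`` equals sampling at ``beta`` under the
    bias ``V = (f - 1) U``, so frames carry ``bias_energy = (f - 1) U(x)``
    and reweight to the target ensemble with ``exp(+beta V)``.
    """
    import dataclasses

    f = beta_hot_factor
    hot = dataclasses.replace(spec, beta=f * spec.beta)
    if spec.potential_id == "dimer_bath":
        start = dimer_configuration(spec, seed=seed + 7,
                                    bond_length=spec.parameters["bond_r0"]
                                    + spec.parameters["bond_w"])
        frames = run_langevin(hot, start, n_steps, dt=2e-3, friction=2.0,
                              seed=seed + 11, save_stride=save_stride,
                              scheme="baoab")
    else:
        start = _low_dim_start(spec, 0.0)
        frames = run_langevin(hot, start, n_steps, dt, friction,
                              seed=seed + 11, save_stride=save_stride)
    for frame in frames:
        frame.bias_energy = (f - 1.0) * potential_energy(spec, frame)
    labels = [assign_state_label(fr, states) for fr in frames]
    return LabeledDataset(frames, labels, reweight_frames(frames, spec.beta))


def ts_seeded_dataset(spec: SystemSpec, states, seed: int, **hot_kwargs) -> LabeledDataset:
    """Basin data plus the high-temperature transition-state seed."""
    return basin_dataset(spec, states, seed).merge(
        hot_dataset(spec, states, seed, **hot_kwargs))


def train_default(spec: SystemSpec, dataset: LabeledDataset,
                  model: CommittorModel | None = None, seed: int = 0):
    model = model or default_model(spec, seed=seed)
    settings = default_train_settings(spec, seed=seed)
    return train_committor(dataset, model, settings)


def default_loop_settings(seed: int = 0):
    """Self-consistent-loop settings validated on the double-well system."""
    from .training import LoopSettings

    return LoopSettings(
        max_iterations=4, min_iterations=4, n_steps=15000, dt=2e-3,
        save_stride=15, bias_stride=2, integrator="lm", k_rel_tolerance=0.02,
        train=TrainSettings(alpha1=100.0, alpha2=1.0, z_r=5.0,
                            epochs=300, warmup_epochs=50, learning_rate=1e-2),
        seed=seed)


# ---------------------------------------------------------------------------
# enhanced-sampling demonstration protocol

COLD_BETA = 1.75  # 10.5 k_B T barrier: no unbiased crossings on the horizon
COLD_N_STEPS = 150000
COLD_BURN_FRACTION = 1 / 3  # discard the adaptive-bias filling transient


def cold_spec() -> SystemSpec:
    import dataclasses

    return dataclasses.replace(double_well_spec(), beta=COLD_BETA)


def run_cold_demo(model: CommittorModel, seed: int):
    """Paired unbiased/biased double-well runs at the cold temperature.

    Returns ``(unbiased_frames, biased_frames, bias_state)``; the biased run
    uses the committor bias V_K plus the adaptive z bias sized to the
    inverted-landscape gap (gamma = 10, epsilon = 1e-6).
    """
    from .biasing import BiasState, run_biased_sampling

    spec = cold_spec()
    start = make_low_dim_configuration(spec, [-1.0])
    unbiased = run_langevin(spec, start, COLD_N_STEPS, 2e-3, 1.0,
                            seed=seed, save_stride=25, scheme="lm")
    biased, bias_state = run_biased_sampling(
        spec, model, start, COLD_N_STEPS, seed=seed + 1, dt=2e-3,
        save_stride=25, bias_stride=2, integrator="lm",
        bias_state=BiasState(beta=spec.beta, gamma=10.0, epsilon_floor=1e-6))
    return unbiased, biased, bias_state


def cold_tail(frames):
    """Quasi-stationary part of a cold biased run (burn-in removed)."""
    return frames[int(len(frames) * COLD_BURN_FRACTION):]


def cold_fes_deviation_kt(biased_frames, min_count: int = 20):
    """Sup-norm discrepancy (k_B T) between the reweighted free-energy
    profile of the biased run's tail and the Boltzmann inversion of U.

    Free energies are defined up to an additive constant; the comparison
    uses the constant that minimizes the sup-norm (Chebyshev centering)
    over bins holding at least ``min_count`` frames.
    """
    from .analysis import project_fes

    spec = cold_spec()
    frames = cold_tail(biased_frames)
    w = reweight_frames(frames, spec.beta)
    edges = np.linspace(-1.3, 1.3, 27)
    centers = 0.5 * (edges[:-1] + edges[1:])
    xs = np.array([f.positions[0, 0] for f in frames])
    counts, _ = np.histogram(xs, bins=edges)
    fes, _ = project_fes(frames, w, ["x"], [edges], spec.beta)
    u = spec.parameters["barrier"] * (centers**2 - 1.0) ** 2
    ok = np.isfinite(fes) & (counts >= min_count)
    dev = fes[ok] - u[ok]
    dev -= 0.5 * (dev.max() + dev.min())
    return float(np.max(np.abs(dev)) * spec.beta), int(ok.sum())


# ---------------------------------------------------------------------------
# oracles and grid evaluation


def flat_oracle(spec: SystemSpec, n_grid: int = 201) -> GridCommittor:
    lo, hi = spec.parameters["lo"], spec.parameters["hi"]
    x = np.linspace(lo, hi, n_grid)
    u = np.zeros_like(x)
    mask_a = x <= 0.1
    mask_b = x >= 0.9
    return solve_committor_grid([x], u, mask_a, mask_b, spec.beta)


def double_well_oracle(spec: SystemSpec, n_grid: int = 321,
                       x_range: tuple = (-1.6, 1.6)) -> GridCommittor:
    h = spec.parameters["barrier"]
    x = np.linspace(*x_range, n_grid)
    u = h * (x**2 - 1.0) ** 2
    mask_a = x <= -0.8
    mask_b = x >= 0.8
    return solve_committor_grid([x], u, mask_a, mask_b, spec.beta)


def model_q_on_axis(model: CommittorModel, spec: SystemSpec, xs) -> np.ndarray:
    """Evaluate the trained committor along the 1D particle coordinate."""
    return np.array([
        model.q_value(make_low_dim_configuration(spec, [x])) for x in xs
    ])


def model_z_on_axis(model: CommittorModel, spec: SystemSpec, xs) -> np.ndarray:
    return np.array([
        model.z_value(make_low_dim_configuration(spec, [x])) for x in xs
    ])
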