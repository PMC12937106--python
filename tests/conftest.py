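"""Shared session fixtures: trained models and sampling runs are expensive,
so every test that needs them reuses one instance built at the package's
reference study settings."""

import pytest

from graphcommittor import presets
from graphcommittor.systems import make_low_dim_configuration
from graphcommittor.training import self_consistent_loop


@pytest.fixture(scope="session")
def flat_result():
    """Flat-potential dataset + fully trained model (analytic-limit check)."""
    spec = presets.flat_spec()
    states = presets.flat_states()
    dataset = presets.basin_dataset(spec, states, seed=100)
    model, history = presets.train_default(spec, dataset, seed=0)
    return {"spec": spec, "states": states, "dataset": dataset,
            "model": model, "history": history}


@pytest.fixture(scope="session")
def dw_bundle():
    """Double-well (6 k_B T) self-consistent loop result plus the PDE oracle."""
    spec = presets.double_well_spec()
    states = presets.double_well_states()
    dataset = presets.ts_seeded_dataset(spec, states, seed=100)
    model = presets.default_model(spec, seed=0)
    start = make_low_dim_configuration(spec, [-1.0])
    model, dataset, diagnostics = self_consistent_loop(
        dataset, spec, model, states, start, presets.default_loop_settings(seed=0))
    oracle = presets.double_well_oracle(spec)
    return {"spec": spec, "states": states, "dataset": dataset,
            "model": model, "diagnostics": diagnostics, "oracle": oracle}


@pytest.fixture(scope="session")
def dw_cold_runs(dw_bundle):
    """Paired unbiased/biased runs at the cold temperature (10.5 k_B T
    barrier), where the unbiased dynamics cannot cross on the horizon."""
    unbiased, biased, bias_state = presets.run_cold_demo(dw_bundle["model"],
                                                         seed=50)
    return {"spec": presets.cold_spec(), "states": dw_bundle["states"],
            "unbiased": unbiased, "biased": biased, "bias_state": bias_state}


@pytest.fixture(scope="session")
def dimer_bundle():
    """Trained dimer-in-bath committor (bond-length transition)."""
    spec = presets.dimer_spec()
    states = presets.dimer_states()
    dataset = presets.ts_seeded_dataset(spec, states, seed=200,
                                        n_steps=6000, save_stride=40)
    model, history = presets.train_default(spec, dataset, seed=0)
    return {"spec": spec, "states": states, "dataset": dataset,
            "model": model, "history": history}
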