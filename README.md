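# graphcommittor

Descriptor-free committor learning with graph neural networks, committor-based
enhanced sampling, and transition-state ensemble analysis — on built-in toy
systems with exact finite-difference references.

## The problem

Rare transitions between metastable states A and B (reactions, nucleation,
binding) are governed by the committor `q(x)`: the probability that a
trajectory launched from configuration `x` reaches B before A.  The committor
is the ideal one-dimensional reaction coordinate, but its brute-force
estimation is prohibitively expensive.  This package implements a
self-consistent, variational route to `q`:

- **Learning.**  The committor minimizes the Kolmogorov functional
  `K[q] = <|∇_u q(x)|²>_U` (Boltzmann average, mass-scaled gradients) under
  the boundary conditions `q|_A = 0`, `q|_B = 1`.  `q = σ(p·z(x))` is
  parametrized by a SchNet-style message-passing network that reads atomic
  coordinates directly — species embeddings, continuous-filter convolutions
  over RBF-expanded interatomic distances, optional per-edge attention,
  mean pooling over the reacting atoms, and an MLP readout for the collective
  variable `z`.  The training loss is
  `L = log L_v + α₁ L_b + α₂ L_r`, with `L_v` the weighted sample estimate of
  `K[q]`, `L_b` the boundary penalty, and `L_r` a range regularizer on `z`.
- **Sampling.**  The learned committor defines the bias
  `V_K = −(1/β) log|∇_u q|²`, which turns the transition-state region into an
  effective minimum, complemented by an adaptive OPES-style bias on `z` that
  flattens its marginal and drives A↔B transitions.  Biased frames carry
  weights `w ∝ e^{+βV}`, so unbiased averages and free-energy surfaces are
  recovered by reweighting.
- **Iteration.**  Train → bias → sample → reweight → merge, until the
  variational estimate of `K` stops improving.  Seeding the first dataset
  with transition-region frames (here: a reweighted high-temperature run)
  shortens the loop.
- **Analysis.**  The Kolmogorov distribution `p_K ∝ e^{−βU}|∇_u q|²` weights
  configurations by their contribution to the reactive flux; its modes —
  found by weighted k-medoids in the network's latent node features — are the
  transition-state ensemble channels, with masses equal to their share of the
  rate.  Node-sensitivity scores `s_i = <|∂z/∂x_i|>` and distance-resolved
  attention profiles `Att(r)` identify the atoms and coordination structures
  the model considers relevant.

Everything is validated against an exact finite-difference solver of the
steady backward Kolmogorov equation `∇·(e^{−βU}∇q) = 0` on 1D/2D grids.

Intended users: method developers and students of enhanced sampling who want
a complete, inspectable implementation of committor-driven sampling at desk
scale.  There are no molecular force fields here; the built-in systems (flat
potential, 1D double well, a double-well dimer in a repulsive bath) are small
enough that every claim is checked against an oracle or a closed form.

## Worked example

Train the double-well committor self-consistently and compare with the PDE
oracle (about five minutes on one CPU core):

```python
import numpy as np
from graphcommittor import presets
from graphcommittor.oracle import kolmogorov_functional_on_grid
from graphcommittor.systems import make_low_dim_configuration
from graphcommittor.training import self_consistent_loop

spec = presets.double_well_spec()        # U = 6 (x² − 1)², beta = 1
states = presets.double_well_states()    # A: x ≤ −0.8, B: x ≥ 0.8
data = presets.ts_seeded_dataset(spec, states, seed=100)
model = presets.default_model(spec, seed=0)
start = make_low_dim_configuration(spec, [-1.0])

model, data, diag = self_consistent_loop(
    data, spec, model, states, start, presets.default_loop_settings(seed=0))
for d in diag:
    print(f"iteration {d['iteration']}: K estimate {d['K_estimate']:.4f} "
          f"({d['n_frames']} frames)")

oracle = presets.double_well_oracle(spec)
x = oracle.axes[0]
q = presets.model_q_on_axis(model, spec, x)
inside = oracle.interior()
print("RMSE vs oracle:",
      round(float(np.sqrt(np.mean((q[inside] - oracle.q_values[inside])**2))), 4))
print("K model/oracle:",
      round(kolmogorov_functional_on_grid(oracle, q)
            / kolmogorov_functional_on_grid(oracle), 3))
```

Output:

```
iteration 0: K estimate 0.0120 (1000 frames)
iteration 1: K estimate 0.0099 (2000 frames)
iteration 2: K estimate 0.0088 (3000 frames)
iteration 3: K estimate 0.0094 (4000 frames)
RMSE vs oracle: 0.0287
K model/oracle: 1.054
```

The variational estimate of `K` relaxes toward the oracle value (0.0062 for
this system) as biased sampling populates the transition region; the final
committor agrees with the exact grid solution to RMSE 0.029, and its
quadrature `K` sits 5% above the oracle's, on the correct side of the
variational bound.

The same pipeline is scriptable from the shell:

```bash
graphcommittor --config run.yml loop        # train + sample iterations
graphcommittor --config run.yml sample --model out/model.json
graphcommittor --config run.yml analyze tse --model out/model.json --data out/biased.xyz --k 2
```

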