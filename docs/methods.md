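# Methods

## The committor and the variational principle

For two metastable states A and B of a system with potential `U(x)` at
inverse temperature `beta`, the committor `q(x)` is the probability that a
trajectory started at `x` reaches B before A.  It is the natural reaction
coordinate: all of the mechanistic content of a rare transition is encoded
in how `q` interpolates between `q = 0` on A and `q = 1` on B.

The package learns `q` through the Kolmogorov variational principle: among
all fields satisfying the boundary conditions, the committor minimizes

    K[q] = < |grad_u q(x)|^2 >_U,

the Boltzmann average of the squared gradient in mass-scaled coordinates
(`|grad_u q|^2 = sum_i m_i^-1 |grad_{x_i} q|^2`).  Frozen coordinates
(e.g. the anchor atoms of the low-dimensional toys) are excluded from the
norm, since they are not dynamical degrees of freedom.

`q` is parametrized as `q = sigma(p z(x))` with `sigma` the logistic
function and steepness `p` (default 3).  The network output `z` is an
unbounded collective variable carrying the same information as `q` but
without its saturation: near the states `q` is exponentially close to 0 or
1 while `z` remains O(1), which keeps both the optimization and the
bias potentials well conditioned.

## Model architecture

`z` is computed by a SchNet-style message-passing network on a distance
graph over the atoms:

- node features (width 16 by default, 8 in the study presets) are
  initialized from a learned per-species embedding;
- each interaction block computes messages
  `m_ij = W(h_j) * f_F(RBF(d_ij))` — an elementwise (continuous-filter)
  product of a linear transform of the source features with a filter
  generated from the Gaussian radial-basis expansion of the pair distance
  (centers uniform on `[0, rbf_cutoff]`, width `gamma = 1/(2 dmu^2)` from
  the center spacing);
- every message is multiplied by a cosine switching function that vanishes
  with zero slope at the edge cutoff `R_c`, so `z` and the bias forces are
  continuous when atoms cross the cutoff.  Enforced reacting-reacting
  edges bypass the envelope (their purpose is to never be silenced) and
  their possibly-large distances are still RBF-expanded, so the RBF grid
  should cover the largest expected reacting-pair separation;
- aggregation is the neighbor mean, or, with attention enabled, a softmax-
  weighted sum with per-edge scores from a small gate network acting on the
  messages; nodes with no neighbors aggregate the zero vector;
- features update residually, `h <- h + f_M(aggregate)`;
- the final features are averaged over the pool set (the reacting atoms of
  a truncated graph, all nodes otherwise) and passed through a readout MLP
  to give the scalar `z`.

All activations are shifted softplus.  The model, including graph
distances, is written with `autograd`, so coordinate gradients of `q`
(needed by the loss and the biases) and parameter gradients of those
gradients (needed to train) are exact reverse-mode derivatives.  The
chain-rule identity `grad q = p q (1-q) grad z` holds to machine
precision and is used wherever `q`-gradients are required.

A configuration flag restores the option of zero-initializing the last
layer of `f_M` (making the untrained network an identity map on the
embeddings); the default is small random initialization, because a network
that starts exactly position-independent sits on a stationary manifold of
the variational term where training can stall (see "Loss landscape"
below).

## The truncated graph

Atoms are split by the user into reacting atoms (always nodes) and
environment atoms, which enter the graph only if within
`R_t = R_c + delta_b` of a reacting atom.  Edges connect retained atoms
within `R_c`; the buffer `delta_b > 0` guarantees that no atom can acquire
an edge without first having been a node, stabilizing dynamics between
neighbor-list rebuilds (outer list every `nl_stride` steps, edge list
every step).  Only reacting atoms are pooled in the readout of a truncated
graph.  Cells are orthorhombic with the minimum-image convention; the
neighbor search is a brute-force O(N^2) scan, which is its own oracle at
the system sizes targeted here.

## Loss and training

The training loss is

    L = log L_v + alpha1 * L_b + alpha2 * L_r

with `L_v` the weighted sample estimate of `K[q]`, `L_b` the mean squared
boundary violation over A- and B-labeled frames, and `L_r` a hinge
penalty `mean(max(0, |z| - z_r)^2)` limiting the usable `z` range
(default `z_r = 5`).  Frames sampled under a bias `V` carry weights
`w ~ exp(+beta V)`, normalized to mean 1 per dataset (computed with
max-subtraction, so arbitrarily large biases cannot overflow).  Labeled
boundary frames also contribute to `L_v` with their ordinary weights.

### Loss landscape

Two degeneracies of `log L_v` shape the defaults:

1. The constant model (`q = 1/2` everywhere) has `L_v = 0`; with the
   epsilon floor (1e-12) inside the logarithm this is a finite but very
   deep well (~27 units).  `alpha1` must therefore be large enough that
   the boundary-conditioned solution is the global minimum; the default is
   `alpha1 = 100`.
2. With a fixed dataset, a sufficiently expressive model can squeeze the
   entire transition between neighboring data points, driving the *sample*
   estimate `L_v` to zero while the true functional diverges (a perfect
   classifier is a terrible committor).  Two mechanisms counter this:
   a warm-up stage (default 50 epochs) trains only `alpha1 L_b + alpha2
   L_r`, giving a sane boundary-respecting starting point before the
   variational term is switched on; and the self-consistent loop (below)
   repopulates the current transition region with real samples each
   iteration, so the sample estimate cannot be gamed for long.

Optimization is full-batch Adam (learning rate 1e-2 in the study presets,
decayed as `1/(1+iteration)` across loop iterations).  Training is
deterministic given the seed and batch layout.  If a minibatch lacks a
boundary class, one frame of each class is topped up into it.

## Enhanced sampling

Two committor-derived biases act on top of `U`:

- the Kolmogorov bias `V_K = -(1/beta) log(|grad_u q|^2 + eps_g)`
  (`eps_g = 1e-10`), which turns the transition-state region — where the
  committor gradient is localized — into an effective minimum;
- an OPES-style adaptive bias on `z`,
  `V_z = (1 - 1/gamma)(1/beta) log(P(z) + eps)`, built from a weighted
  Gaussian kernel density of the visited `z` values (kernels deposited
  every `deposition_stride` steps with the iterative weights
  `exp(beta V_z)`; no kernel merging, fixed bandwidth 0.25, `gamma = 6`,
  `eps = 1e-4`).  The bias is bounded by
  `(1 - 1/gamma)/beta * |log eps|` by construction.

Bias forces are exact derivatives through the model (including the
second-order term inside `V_K`).  `V_K` forces scale with the sharpness
of the learned committor and can become stiff at the edges of the
transition region; biased runs therefore default to a smaller time step
(2e-3) and clip bias forces at 50 (reduced units) as a numerical guard —
the recorded bias energies are exact, and the clip engages only where an
oversharp intermediate model would otherwise eject the particle.

Saved frames record the instantaneous total bias energy, used for
`exp(+beta V)` reweighting.  Because the kernel density evolves during a
run, reweighting is quasi-static: analyses discard the initial filling
transient (the first third of a run in the acceptance protocol) where the
instantaneous-bias approximation is worst.

## Self-consistent iteration

Training data is generated iteratively, as the variational principle
requires samples where the committor gradient lives:

1. start from labeled unbiased basin runs, optionally augmented with
   transition-region frames from a pre-biasing stage.  At desk scale the
   pre-bias is a high-temperature run at `beta_hot = f * beta`, recorded
   as a biased run with `V = (f - 1) U`, which reweights exactly;
2. train; 3. sample under `U + V_K + V_z`; 4. label and reweight the new
   frames, merge them into the dataset (nothing is discarded); repeat.

Convergence is declared when the reweighted K estimate changes by less
than a relative tolerance over consecutive iterations and the Spearman
correlation of `z` across the dataset between successive models exceeds
0.99.  Seeding the first dataset with transition-region frames reduces the
number of iterations needed — the basin-only start must first discover the
transition region through sampling.

## Transition-state ensemble analysis

The Kolmogorov distribution `p_K ~ exp(-beta U) |grad_u q|^2` weights each
configuration by its contribution to the reactive flux.  Frames are
reweighted to `p_K` by `w_i (|grad_u q(x_i)|^2 + eps_g)`, normalized to
sum 1.  One identity is worth stating because it calibrates expectations:
for the exact committor of overdamped isotropic diffusion the reactive
flux through every isocommittor surface is equal, so `q` is distributed
uniformly under `p_K` — the band `0.2 < q < 0.8` holds exactly 60% of the
mass (and the `p_K`-weighted mean of `q` is exactly 1/2) in any dimension.
`p_K` localization is a statement about configuration space (on the 6 kT
double well, ~95% of the mass lies within |x| < 0.4), not about `q`-space.

TSE modes are found by weighted k-medoids (PAM-style alternation,
k-means++-style seeding, deterministic given the seed) in the latent space
of last-layer node features, with the per-frame vector taken as the mean
over the pool set and the Euclidean metric; cluster masses are summed
`p_K` weights.  `k` is user-chosen, with a silhouette-score helper.

Interpretability tools: node sensitivity `s_i` is the dataset mean of the
Euclidean norm of `dz/dx_i` (componentwise-L1 available as a toggle;
atoms absent from a frame's truncated graph contribute zero), and
attention profiles `Att(r)` average the last-layer attention of selected
(source species -> target) messages in distance bins, min-max normalized
to (0,1) together with the matching pair-distance distribution.

## The finite-difference oracle

Validation references come from solving the steady backward Kolmogorov
equation `div(exp(-beta U) grad q) = 0` on 1D/2D grids: flux-form
second-order finite differences with geometric-mean face weights (which
preserve the discrete maximum principle), Dirichlet values on the state
masks, reflecting outer boundaries, sparse direct solve.  Observed
convergence is second order; the 1D solution also matches the closed form
`q(x) ~ int_a^x exp(beta U)`.  The same grids provide quadratures of
`K[q]` for any field, used to verify the variational bound
(`K[model] >= K[oracle]`) and convergence (`K[model]` within 15% of
`K[oracle]` after the self-consistent loop at the study settings).

## Study systems and scale

- flat potential on [0, 1] (reflecting walls), states at `x <= 0.1` and
  `x >= 0.9`: the committor is exactly linear in between;
- 1D double well `U = h (x^2 - 1)^2`, `h = 6`, `beta = 1` (a 6 kT
  barrier; the enhanced-sampling demonstrations run the same system at
  `beta = 2`, i.e. 12 kT, where unbiased crossings are absent on the
  simulated horizon);
- dimer in a bath: two reacting atoms with a symmetric double-well bond
  potential (minima 1.12 and 1.82, 6 kT barrier) plus 8 WCA particles in
  a periodic box of side 6.5.

The low-dimensional systems carry two (1D) or three (2D) frozen anchor
atoms of distinct species at the domain edges so that a purely
distance-based graph model can resolve the particle position (distances
to the anchors determine it uniquely and break the x -> -x symmetry).
This is a deliberate reduction: it exercises the full graph pipeline on
systems whose exact committor is computable, at the cost of realism —
the anchors have no physical counterpart, and these toys cannot probe
many-body solvation effects.  The dimer-bath system restores a genuine
many-particle graph (permutation invariance, truncation, attention) but
its mechanism is one-dimensional by construction (the bond length), which
is what makes the sensitivity ranking testable.

Dynamics are overdamped Euler-Maruyama or its Leimkuhler-Matthews variant
(low-dimensional toys) or BAOAB (particle systems), all with the Boltzmann
stationary law; reduced units with `k_B = 1` and unit masses unless a mass
map is supplied.  Biased runs default to the Leimkuhler-Matthews scheme
(consecutive-noise averaging, same cost as Euler-Maruyama but O(dt^2)
configurational sampling error): under the stiff committor-derived biases
the O(dt) error of plain Euler-Maruyama concentrates exactly at the edges
of the transition region and visibly distorts reweighted free-energy
profiles at the default time step.  Problem
sizes throughout (hundreds to a few thousand frames, 1e4-4e4 step runs,
8-wide single-interaction models in the presets) are chosen so the full
pipeline — including the four-iteration self-consistent loop — completes
in minutes on one CPU core while leaving clear margins on every
validation tolerance.

## Known limitations

- No molecular force fields, explicit solvent, or MD-engine coupling: the
  conclusions that passing tests support are about the method's
  correctness and self-consistency on the built-in systems, not about its
  behavior on condensed-phase molecular systems.
- Instantaneous-bias reweighting (rather than time-averaged) during
  adaptive biasing; handled by discarding the filling transient.
- The sample variational estimate can be gamed by overfitting between
  data points if the loop is replaced by very long single-dataset
  training; the loop is part of the method, not an optional refinement.
- k-medoids is a local alternation, and the number of TSE modes is
  ultimately a user choice (the silhouette helper only advises).
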