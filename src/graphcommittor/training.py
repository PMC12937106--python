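"""Variational training of the committor model.

The loss is ``L = log L_v + alpha1 * L_b + alpha2 * L_r`` with

- ``L_v``: the weighted sample estimate of the Kolmogorov functional,
  ``(1/N) sum_i w_i |grad_u q(x_i)|^2`` (mass-scaled gradients over the
  mobile atoms); its logarithm is optimized because the functional varies
  over many orders of magnitude during training;
- ``L_b``: the boundary loss pinning q to 0 on A-labeled frames and 1 on
  B-labeled frames (mean squared deviations, one term per state);
- ``L_r``: a hinge penalty ``mean max(0, |z_i| - z_r)^2`` keeping the CV
  range bounded and the optimization balanced.

Statistical weights come from ``w_i ~ exp(+beta * bias_energy_i)``,
normalized to mean 1 per dataset, so biased and unbiased frames can be
mixed freely.  Training is plain Adam on the full loss; all randomness is
seeded.  The self-consistent loop alternates training with committor-biased
sampling, merging the reweighted new frames into the dataset until the
variational estimate stops moving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np
from autograd import grad, value_and_grad
from autograd.misc.flatten import flatten
from scipy.stats import spearmanr

from .model import CommittorModel, batched_z_closure, sigmoid
from .systems import Configuration, StateDefinition, SystemSpec, assign_state_label

__all__ = [
    "LabeledDataset",
    "LossBreakdown",
    "TrainSettings",
    "LoopSettings",
    "reweight_frames",
    "variational_loss",
    "boundary_loss",
    "range_loss",
    "train_committor",
    "self_consistent_loop",
    "TrainingError",
]

EPS_LV = 1e-12  # floor inside log L_v at the degenerate constant-model point


class TrainingError(RuntimeError):
    """Dataset or optimization failures."""


@dataclass
class LossBreakdown:
    L_v: float
    L_b: float
    L_r: float
    alpha1: float
    alpha2: float
    z_r: float

    @property
    def total(self) -> float:
        return float(np.log(self.L_v + EPS_LV) + self.alpha1 * self.L_b
                     + self.alpha2 * self.L_r)


@dataclass
class LabeledDataset:
    """Frames with state labels in {A, B, unlabeled} and statistical weights."""

    frames: list
    labels: list
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.frames) != len(self.labels) or len(self.frames) != len(self.weights):
            raise TrainingError("frames, labels and weights must have equal length")
        if np.any(self.weights < 0):
            raise TrainingError("weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.frames)

    @classmethod
    def from_frames(cls, frames, states: list[StateDefinition] | None,
                    beta: float) -> "LabeledDataset":
        labels = (["unlabeled"] * len(frames) if states is None
                  else [assign_state_label(f, states) for f in frames])
        return cls(list(frames), labels, reweight_frames(frames, beta))

    def merge(self, other: "LabeledDataset") -> "LabeledDataset":
        """Concatenate; weights are re-normalized to mean 1 jointly."""
        w = np.concatenate([self.weights, other.weights])
        w = w / w.mean() if w.mean() > 0 else w
        return LabeledDataset(self.frames + other.frames,
                              self.labels + other.labels, w)

    def counts(self) -> tuple[int, int]:
        return self.labels.count("A"), self.labels.count("B")


def reweight_frames(frames, beta: float) -> np.ndarray:
    """w_i ~ exp(+beta * bias_energy_i), normalized to mean 1.

    Computed with max-subtraction so strongly biased frames never overflow;
    adding any constant to all bias energies leaves the weights unchanged.
    """
    e = np.array([f.bias_energy for f in frames], dtype=float)
    logw = beta * e
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.mean()


# ---------------------------------------------------------------------------
# loss terms (reference implementations; the trainer re-derives them inside
# the autograd trace)


def variational_loss(dataset: LabeledDataset, model: CommittorModel) -> float:
    """Weighted mean of mass-scaled |grad_u q|^2 over the dataset (>= floor)."""
    if len(dataset) == 0:
        raise TrainingError("empty dataset")
    vals = []
    for frame, w in zip(dataset.frames, dataset.weights):
        _, _, gsq = model.gradients(frame)
        vals.append(w * gsq)
    return float(max(np.mean(vals), EPS_LV))


def boundary_loss(dataset: LabeledDataset, model: CommittorModel) -> float:
    qa = [model.q_value(f) for f, l in zip(dataset.frames, dataset.labels) if l == "A"]
    qb = [model.q_value(f) for f, l in zip(dataset.frames, dataset.labels) if l == "B"]
    if not qa or not qb:
        raise TrainingError("boundary loss needs at least one A and one B frame")
    return float(np.mean(np.square(qa)) + np.mean(np.square(np.array(qb) - 1.0)))


def range_loss(z_values, z_r: float) -> float:
    if z_r <= 0:
        raise TrainingError("z_r must be positive")
    z = np.asarray(z_values, dtype=float)
    return float(np.mean(np.maximum(0.0, np.abs(z) - z_r) ** 2))


def loss_breakdown(dataset: LabeledDataset, model: CommittorModel,
                   alpha1: float, alpha2: float, z_r: float) -> LossBreakdown:
    z = [model.z_value(f) for f in dataset.frames]
    return LossBreakdown(
        L_v=variational_loss(dataset, model),
        L_b=boundary_loss(dataset, model),
        L_r=range_loss(z, z_r),
        alpha1=alpha1, alpha2=alpha2, z_r=z_r,
    )


# ---------------------------------------------------------------------------
# trainer


@dataclass
class TrainSettings:
    alpha1: float = 100.0
    alpha2: float = 1.0
    z_r: float = 5.0
    learning_rate: float = 5e-3
    epochs: int = 200
    warmup_epochs: int = 50  # boundary/range-only epochs before log L_v is on
    batch_size: int | None = None  # None: full batch
    seed: int = 0
    shared_topology: bool | None = None  # None: auto-detect


def _frames_share_topology(frames) -> bool:
    first = frames[0]
    return all(
        f.n_atoms == first.n_atoms
        and np.array_equal(f.species, first.species)
        and (f.cell is None) == (first.cell is None)
        for f in frames
    )


def _prepare_batched(model, frames):
    z_fn, graph = batched_z_closure(model, frames[0])
    pos = np.stack([f.positions for f in frames])
    template = frames[0]
    inv_mass = np.where(template.mobile, 1.0 / template.masses, 0.0)
    return z_fn, pos, inv_mass


def _make_loss_fn(model, dataset: LabeledDataset, settings: TrainSettings,
                  indices: np.ndarray, include_variational: bool = True):
    """Total-loss closure over a subset of frames, traceable in the params."""
    frames = [dataset.frames[i] for i in indices]
    weights = dataset.weights[indices]
    labels = [dataset.labels[i] for i in indices]
    a_mask = np.array([l == "A" for l in labels])
    b_mask = np.array([l == "B" for l in labels])
    p = model.config.sigmoid_p
    shared = settings.shared_topology
    if shared is None:
        shared = _frames_share_topology(frames)

    if shared:
        z_fn, pos, inv_mass = _prepare_batched(model, frames)

        def loss_fn(params):
            z = z_fn(pos, params)
            q = sigmoid(z, p)
            if not include_variational:
                return _assemble(z, q, None)
            gz = grad(lambda P: anp.sum(z_fn(P, params)))(pos)
            gsq_z = anp.sum(gz * gz * inv_mass[None, :, None], axis=(1, 2))
            dqdz2 = (p * q * (1.0 - q)) ** 2
            L_v = anp.mean(weights * dqdz2 * gsq_z)
            return _assemble(z, q, L_v)

        def z_eval(params):
            return np.asarray(z_fn(pos, params))
    else:
        closures = []
        for f in frames:
            zf, graphf = model.z_closure(f)
            inv_m = np.where(f.mobile, 1.0 / f.masses, 0.0)
            closures.append((zf, f.positions, inv_m))

        def loss_fn(params):
            zs, gsqs = [], []
            for zf, pos_f, inv_m in closures:
                z_i = zf(pos_f, params)
                zs.append(z_i)
                if include_variational:
                    g_i = grad(lambda P: zf(P, params))(pos_f)
                    gsqs.append(anp.sum(g_i * g_i * inv_m[:, None]))
            z = anp.array(zs)
            q = sigmoid(z, p)
            if not include_variational:
                return _assemble(z, q, None)
            dqdz2 = (p * q * (1.0 - q)) ** 2
            L_v = anp.mean(weights * dqdz2 * anp.array(gsqs))
            return _assemble(z, q, L_v)

        def z_eval(params):
            return np.array([zf(pos_f, params) for zf, pos_f, _ in closures])

    def _assemble(z, q, L_v):
        if a_mask.any():
            L_b = anp.mean(q[a_mask] ** 2)
        else:
            L_b = 0.0
        if b_mask.any():
            L_b = L_b + anp.mean((q[b_mask] - 1.0) ** 2)
        L_r = anp.mean(anp.maximum(0.0, anp.abs(z) - settings.z_r) ** 2)
        penalty = settings.alpha1 * L_b + settings.alpha2 * L_r
        if L_v is None:
            return penalty
        return anp.log(L_v + EPS_LV) + penalty

    def breakdown_from_total(total, params):
        """Recover (L_v, L_b, L_r) from the scalar total plus cheap forwards."""
        z = z_eval(params)
        q = np.asarray(sigmoid(z, p))
        L_b = float(np.mean(q[a_mask] ** 2)) if a_mask.any() else 0.0
        if b_mask.any():
            L_b += float(np.mean((q[b_mask] - 1.0) ** 2))
        L_r = float(np.mean(np.maximum(0.0, np.abs(z) - settings.z_r) ** 2))
        if not include_variational:
            return np.nan, L_b, L_r
        L_v = float(np.exp(total - settings.alpha1 * L_b - settings.alpha2 * L_r)
                    - EPS_LV)
        return L_v, L_b, L_r

    return loss_fn, breakdown_from_total


def train_committor(dataset: LabeledDataset, model: CommittorModel,
                    settings: TrainSettings | None = None):
    """Minimize the three-term loss with Adam; returns (model, history).

    The model is updated in place; ``history`` holds one dict per epoch with
    the loss decomposition.  Deterministic for a fixed seed and batching.
    """
    settings = settings or TrainSettings()
    n_a, n_b = dataset.counts()
    if n_a < 1 or n_b < 1:
        raise TrainingError(
            f"dataset needs labeled frames from both states (N_A={n_a}, N_B={n_b})"
        )
    rng = np.random.default_rng(settings.seed)
    n = len(dataset)
    batch = settings.batch_size or n

    flat, unflatten = flatten(model.params)
    m_t = np.zeros_like(flat)
    v_t = np.zeros_like(flat)
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = settings.learning_rate
    history = []
    last_good = flat.copy()
    step = 0
    for epoch in range(settings.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        aux_acc = []
        for start in range(0, n, batch):
            idx = order[start:start + batch]
            # batches must contain both boundary classes; top up if needed
            if not any(dataset.labels[i] == "A" for i in idx) or \
               not any(dataset.labels[i] == "B" for i in idx):
                extra_a = next(i for i in order if dataset.labels[i] == "A")
                extra_b = next(i for i in order if dataset.labels[i] == "B")
                idx = np.unique(np.concatenate([idx, [extra_a, extra_b]]))
            loss_fn, breakdown = _make_loss_fn(
                model, dataset, settings, idx,
                include_variational=epoch >= settings.warmup_epochs,
            )
            total, g = value_and_grad(
                lambda fp: loss_fn(unflatten(fp))
            )(flat)
            if not np.isfinite(total):
                model.params = unflatten(last_good)
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}; restored last checkpoint"
                )
            last_good = flat.copy()
            aux_acc.append((float(total), *breakdown(float(total), unflatten(flat))))
            step += 1
            m_t = b1 * m_t + (1 - b1) * g
            v_t = b2 * v_t + (1 - b2) * g * g
            mhat = m_t / (1 - b1**step)
            vhat = v_t / (1 - b2**step)
            flat = flat - lr * mhat / (np.sqrt(vhat) + eps)
        model.params = unflatten(flat)
        tot, lv, lb, lr_term = np.mean(aux_acc, axis=0)
        history.append({"epoch": epoch, "total": tot, "L_v": lv,
                        "L_b": lb, "L_r": lr_term})
    model.params = unflatten(flat)
    return model, history


# ---------------------------------------------------------------------------
# self-consistent loop


@dataclass
class LoopSettings:
    max_iterations: int = 3
    min_iterations: int = 1  # early K-convergence stop allowed only after this
    k_rel_tolerance: float = 0.1
    spearman_threshold: float = 0.99
    n_steps: int = 20000
    dt: float = 2e-3  # biased forces are stiffer than the bare potential's
    friction: float = 1.0
    save_stride: int = 50
    bias_stride: int = 1  # recompute bias forces every this many steps
    integrator: str = "overdamped"
    train: TrainSettings = field(default_factory=TrainSettings)
    bias: dict = field(default_factory=dict)  # forwarded to biasing.BiasState
    seed: int = 0


def reweighted_k_estimate(dataset: LabeledDataset, model: CommittorModel) -> float:
    """Weighted variational estimate of K over the dataset (the L_v value)."""
    return variational_loss(dataset, model)


def self_consistent_loop(initial_data: LabeledDataset, spec: SystemSpec,
                         model: CommittorModel,
                         states: list[StateDefinition],
                         start: Configuration,
                         settings: LoopSettings | None = None):
    """Iterate train -> biased sampling -> reweight -> merge until converged.

    Returns ``(model, diagnostics)``; diagnostics has one record per
    iteration with the reweighted K estimate, dataset size, transition count
    of the sampling run, and the convergence flags.
    """
    from .biasing import BiasState, count_transitions, run_biased_sampling

    settings = settings or LoopSettings()
    dataset = initial_data
    diagnostics = []
    prev_k = None
    prev_z = None
    for it in range(settings.max_iterations):
        seed_it = settings.seed + 1000 * it
        overrides = {"seed": seed_it,
                     "learning_rate": settings.train.learning_rate / (1 + it)}
        if it > 0:
            overrides["warmup_epochs"] = 0  # boundary pre-fit only once
        train_settings = TrainSettings(**{**settings.train.__dict__, **overrides})
        model, history = train_committor(dataset, model, train_settings)
        k_est = reweighted_k_estimate(dataset, model)
        z_now = np.array([model.z_value(f) for f in dataset.frames])
        rec = {"iteration": it, "K_estimate": k_est, "n_frames": len(dataset),
               "final_loss": history[-1]["total"]}
        converged = False
        if prev_k is not None:
            rel = abs(k_est - prev_k) / max(prev_k, EPS_LV)
            rho = spearmanr(prev_z[: len(z_now)], z_now[: len(prev_z)]).statistic
            rec["K_rel_change"] = rel
            rec["z_spearman"] = float(rho)
            converged = (rel < settings.k_rel_tolerance
                         and rho > settings.spearman_threshold
                         and it + 1 >= settings.min_iterations)
        prev_k, prev_z = k_est, z_now
        if converged or it == settings.max_iterations - 1:
            rec["converged"] = converged
            diagnostics.append(rec)
            break
        bias_state = BiasState(beta=spec.beta, **settings.bias)
        traj, bias_state = run_biased_sampling(
            spec, model, start, settings.n_steps, seed=seed_it + 1,
            dt=settings.dt, friction=settings.friction,
            save_stride=settings.save_stride, bias_state=bias_state,
            integrator=settings.integrator, bias_stride=settings.bias_stride,
        )
        labels = [assign_state_label(f, states) for f in traj]
        n_trans = count_transitions(labels)
        rec["sampling_transitions"] = n_trans
        if n_trans == 0 and len(set(labels) - {"unlabeled"}) <= 1:
            rec["warning"] = "sampling never left the start basin"
        new = LabeledDataset(traj, labels, reweight_frames(traj, spec.beta))
        dataset = dataset.merge(new)
        rec["converged"] = False
        diagnostics.append(rec)
    return model, dataset, diagnostics
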