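"""SchNet-style message-passing committor model.

The committor is parametrized as ``q(x) = sigma(p * z(x))`` with
``sigma`` the logistic function and ``z`` the scalar output of a
message-passing network over the atom graph:

- per-node features initialized from a learned species embedding;
- interaction blocks with continuous-filter convolutions
  ``m_ij = W(h_j) * f_F(RBF(d_ij))`` (elementwise product), each message
  multiplied by a smooth cosine cutoff envelope that vanishes at ``R_c``
  (enforced reacting-reacting edges bypass the envelope);
- aggregation by the neighbor mean, or by attention weights
  ``alpha_ij = softmax_j g(m_ij)`` when attention is enabled;
- residual feature update ``h <- h + f_M(aggregate)`` with the last layer of
  ``f_M`` zero-initialized so the untrained network is near the identity;
- mean pooling of final features over the pool set followed by a readout MLP
  giving ``z``.

Everything is written with ``autograd.numpy``, so gradients of ``z`` and
``q`` with respect to atomic coordinates — and gradients of those gradients
with respect to the parameters, as required by the variational loss — are
exact reverse-mode derivatives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import autograd.numpy as anp
import numpy as np
from autograd import grad

from .graphs import AtomGraph, build_truncated_graph
from .systems import Configuration

__all__ = [
    "ModelConfig",
    "ModelOutput",
    "CommittorModel",
    "rbf_expand",
    "cutoff_envelope",
    "sigmoid",
    "committor_gradient",
    "ModelError",
]


class ModelError(ValueError):
    """Unknown species, missing attention records, or bad configuration."""


@dataclass
class ModelConfig:
    feature_dim: int = 16
    n_interactions: int = 2
    n_rbf: int = 12
    rbf_cutoff: float = 5.0
    use_attention: bool = False
    readout_widths: tuple = (16,)
    sigmoid_p: float = 3.0
    seed: int = 0
    zero_init_update: bool = True  # last f_M layer zero: untrained net ~ identity

    def __post_init__(self) -> None:
        if min(self.feature_dim, self.n_interactions, self.n_rbf) < 1:
            raise ModelError("feature_dim, n_interactions, n_rbf must be >= 1")
        if self.sigmoid_p <= 0:
            raise ModelError("sigmoid_p must be positive")
        self.readout_widths = tuple(int(w) for w in self.readout_widths)


@dataclass
class ModelOutput:
    z: float
    q: float
    node_features: np.ndarray  # (n_nodes, F) final-layer features
    attention_records: list = field(default_factory=list)  # per layer (n_edges,)
    graph: AtomGraph | None = None


def sigmoid(z, p: float = 1.0):
    """Logistic sigma(p z), written in a form stable for large |z|."""
    return 0.5 * (anp.tanh(0.5 * p * z) + 1.0)


def rbf_expand(d, n_rbf: int, rbf_cutoff: float):
    """Gaussian radial basis: centers uniform on [0, cutoff], width from spacing.

    ``gamma = 1 / (2 dmu^2)`` with ``dmu`` the center spacing; each component
    lies in (0, 1] and equals 1 exactly when d hits a center.
    """
    centers = anp.linspace(0.0, rbf_cutoff, n_rbf)
    dmu = rbf_cutoff / (n_rbf - 1) if n_rbf > 1 else rbf_cutoff
    gamma = 1.0 / (2.0 * dmu * dmu)
    d = anp.reshape(d, (-1, 1))
    return anp.exp(-gamma * (d - centers[None, :]) ** 2)


def cutoff_envelope(d, r_cut: float):
    """Cosine switching function: 1 at d=0, smoothly 0 at d >= r_cut (C^1)."""
    inside = 0.5 * (anp.cos(anp.pi * anp.clip(d, 0.0, r_cut) / r_cut) + 1.0)
    return anp.where(d < r_cut, inside, 0.0)


# ---------------------------------------------------------------------------
# parameter initialization

_SSP_LOG2 = float(np.log(2.0))


def _ssp(x):
    """Shifted softplus ln(0.5 e^x + 0.5); smooth, ssp(0) = 0."""
    return anp.logaddexp(x, 0.0) - _SSP_LOG2


def _dense_init(rng, n_in, n_out, scale=1.0, zero=False):
    if zero:
        w = np.zeros((n_in, n_out))
    else:
        w = rng.standard_normal((n_in, n_out)) * scale / np.sqrt(n_in)
    return {"w": w, "b": np.zeros(n_out)}


def _dense(p, x):
    return anp.dot(x, p["w"]) + p["b"]


def _mlp(layers, x, final_linear=True):
    for k, p in enumerate(layers):
        x = _dense(p, x)
        if k < len(layers) - 1 or not final_linear:
            x = _ssp(x)
    return x


def init_parameters(config: ModelConfig, species_codes) -> tuple[dict, dict]:
    """Create the parameter pytree and the species -> embedding-row map."""
    rng = np.random.default_rng(config.seed)
    codes = sorted(int(s) for s in set(species_codes))
    species_map = {c: k for k, c in enumerate(codes)}
    F, R = config.feature_dim, config.n_rbf
    params: dict = {"embed": rng.standard_normal((len(codes), F))}
    blocks = []
    for _ in range(config.n_interactions):
        block = {
            "W": _dense_init(rng, F, F),
            "filter": [_dense_init(rng, R, F), _dense_init(rng, F, F)],
            "update": [
                _dense_init(rng, F, F),
                _dense_init(rng, F, F, zero=config.zero_init_update),
            ],
        }
        if config.use_attention:
            block["gate"] = [_dense_init(rng, F, F), _dense_init(rng, F, 1)]
        blocks.append(block)
    params["blocks"] = blocks
    widths = [F, *config.readout_widths, 1]
    params["readout"] = [
        _dense_init(rng, widths[k], widths[k + 1]) for k in range(len(widths) - 1)
    ]
    return params, species_map


# ---------------------------------------------------------------------------
# forward pass


def _graph_statics(graph: AtomGraph, species_map: dict) -> dict:
    """Non-differentiable per-graph arrays reused across evaluations."""
    try:
        species_idx = np.array([species_map[int(s)] for s in graph.node_species])
    except KeyError as err:
        raise ModelError(f"species code {err} has no embedding entry") from None
    n, e = graph.n_nodes, graph.n_edges
    incidence = np.zeros((n, max(e, 1)))
    if e:
        incidence[graph.edge_dst, np.arange(e)] = 1.0
    counts = np.maximum(incidence.sum(axis=1), 1.0)
    return {
        "species_idx": species_idx,
        "dst": graph.edge_dst,
        "src": graph.edge_src,
        "shift": graph.edge_shift,
        "enforced": graph.edge_enforced.astype(float),
        "incidence": incidence,
        "counts": counts,
        "pool": graph.pool_set,
    }


def _network_forward(params, node_pos, statics, config: ModelConfig,
                     record_attention=None):
    """Core traceable forward pass: positions of retained nodes -> scalar z."""
    h = params["embed"][statics["species_idx"]]
    n_edges = len(statics["dst"])
    if n_edges:
        disp = node_pos[statics["dst"]] - node_pos[statics["src"]] - statics["shift"]
        d = anp.sqrt(anp.sum(disp * disp, axis=1) + 1e-300)
        rbf = rbf_expand(d, config.n_rbf, config.rbf_cutoff)
        env = cutoff_envelope(d, config.rbf_cutoff)
        env = statics["enforced"] + (1.0 - statics["enforced"]) * env
    for block in params["blocks"]:
        if n_edges == 0:
            agg = anp.zeros_like(h)
        else:
            filt = _mlp(block["filter"], rbf)
            msg = _dense(block["W"], h[statics["src"]]) * filt * env[:, None]
            if config.use_attention:
                logits = _mlp(block["gate"], msg)[:, 0]
                ex = anp.exp(logits - anp.max(logits))
                denom = anp.dot(statics["incidence"], ex)
                alpha = ex / denom[statics["dst"]]
                if record_attention is not None:
                    record_attention.append(alpha)
                agg = anp.dot(statics["incidence"], alpha[:, None] * msg)
            else:
                agg = anp.dot(statics["incidence"], msg) / statics["counts"][:, None]
        h = h + _mlp(block["update"], agg)
    pooled = anp.mean(h[statics["pool"]], axis=0)
    z = _mlp(params["readout"], pooled)[0]
    return z, h


class CommittorModel:
    """Committor model bound to its graph-construction settings.

    ``graph_settings`` carries ``r_cut``, ``delta_b``, ``enforce_reacting_edges``
    and ``truncate`` so that sampling and analysis runs are self-describing.
    """

    def __init__(self, config: ModelConfig, species_codes,
                 graph_settings: dict | None = None, params: dict | None = None):
        self.config = config
        gs = dict(graph_settings or {})
        gs.setdefault("r_cut", config.rbf_cutoff)
        gs.setdefault("delta_b", 1.0)
        gs.setdefault("enforce_reacting_edges", True)
        gs.setdefault("truncate", True)
        self.graph_settings = gs
        if params is None:
            self.params, self.species_map = init_parameters(config, species_codes)
        else:
            self.params = params
            codes = sorted(int(s) for s in set(species_codes))
            self.species_map = {c: k for k, c in enumerate(codes)}

    # -- graph plumbing ----------------------------------------------------
    def build_graph(self, config: Configuration) -> AtomGraph:
        gs = self.graph_settings
        return build_truncated_graph(
            config, gs["r_cut"], gs["delta_b"],
            enforce_reacting_edges=gs["enforce_reacting_edges"],
            truncate=gs["truncate"],
        )

    # -- evaluation --------------------------------------------------------
    def forward(self, config: Configuration, graph: AtomGraph | None = None,
                params: dict | None = None) -> ModelOutput:
        graph = graph or self.build_graph(config)
        statics = _graph_statics(graph, self.species_map)
        attn: list = []
        z, h = _network_forward(
            params or self.params, config.positions[graph.node_atom_ids],
            statics, self.config,
            record_attention=attn if self.config.use_attention else None,
        )
        z = float(z)
        return ModelOutput(
            z=z, q=float(sigmoid(z, self.config.sigmoid_p)),
            node_features=np.asarray(h), attention_records=attn, graph=graph,
        )

    def z_value(self, config: Configuration, graph: AtomGraph | None = None) -> float:
        return self.forward(config, graph).z

    def q_value(self, config: Configuration, graph: AtomGraph | None = None) -> float:
        return self.forward(config, graph).q

    def z_closure(self, config: Configuration, graph: AtomGraph | None = None):
        """Return ``(z_fn, node_ids)`` with ``z_fn`` traceable in full positions.

        ``z_fn(positions, params)`` accepts the full (n_atoms, D) position
        array; atoms outside the truncated graph do not enter and therefore
        get exactly zero gradients.  The graph topology (edges, image shifts)
        is held fixed, which is valid between neighbor-list rebuilds.
        """
        graph = graph or self.build_graph(config)
        statics = _graph_statics(graph, self.species_map)
        ids = graph.node_atom_ids

        def z_fn(positions, params):
            return _network_forward(params, positions[ids], statics, self.config)[0]

        return z_fn, graph

    def gradients(self, config: Configuration, graph: AtomGraph | None = None):
        return committor_gradient(config, self, graph=graph)

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        blob = {
            "model_config": asdict(self.config),
            "graph_settings": self.graph_settings,
            "species_codes": sorted(self.species_map),
            "params": _params_to_jsonable(self.params),
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "CommittorModel":
        with open(path) as fh:
            blob = json.load(fh)
        mc = blob["model_config"]
        mc["readout_widths"] = tuple(mc["readout_widths"])
        config = ModelConfig(**mc)
        model = cls(config, blob["species_codes"], blob["graph_settings"])
        model.params = _params_from_jsonable(blob["params"])
        return model


def _params_to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _params_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return {"__list__": [_params_to_jsonable(v) for v in obj]}
    return np.asarray(obj).tolist()


def _params_from_jsonable(obj):
    if isinstance(obj, dict):
        if "__list__" in obj:
            return [_params_from_jsonable(v) for v in obj["__list__"]]
        return {k: _params_from_jsonable(v) for k, v in obj.items()}
    return np.asarray(obj, dtype=float)


# ---------------------------------------------------------------------------
# batched forward for frame sets sharing one graph topology


def _network_forward_batched(params, pos_batch, statics, config: ModelConfig):
    """Vectorized forward over a (B, n_nodes, D) position stack -> z of shape (B,).

    Valid only when every frame shares the same edge list and image shifts
    (the anchored low-dimensional systems); used to amortize the cost of the
    nested coordinate/parameter gradients in training.
    """
    h = params["embed"][statics["species_idx"]]  # (n, F)
    B = pos_batch.shape[0]
    h = anp.ones((B, 1, 1)) * h[None, :, :]
    dst, src = statics["dst"], statics["src"]
    n_edges = len(dst)
    if n_edges:
        disp = pos_batch[:, dst, :] - pos_batch[:, src, :] - statics["shift"][None]
        d = anp.sqrt(anp.sum(disp * disp, axis=2) + 1e-300)  # (B, E)
        centers = anp.linspace(0.0, config.rbf_cutoff, config.n_rbf)
        dmu = config.rbf_cutoff / (config.n_rbf - 1) if config.n_rbf > 1 else config.rbf_cutoff
        gamma = 1.0 / (2.0 * dmu * dmu)
        rbf = anp.exp(-gamma * (d[:, :, None] - centers[None, None, :]) ** 2)
        env = cutoff_envelope(d, config.rbf_cutoff)
        env = statics["enforced"][None, :] + (1.0 - statics["enforced"][None, :]) * env
    for block in params["blocks"]:
        if n_edges == 0:
            agg = anp.zeros_like(h)
        else:
            filt = _mlp(block["filter"], rbf)  # (B, E, F)
            msg = _dense(block["W"], h[:, src, :]) * filt * env[:, :, None]
            if config.use_attention:
                logits = _mlp(block["gate"], msg)[:, :, 0]  # (B, E)
                ex = anp.exp(logits - anp.max(logits))
                denom = anp.dot(ex, statics["incidence"].T)  # (B, n)
                alpha = ex / denom[:, dst]
                msg = alpha[:, :, None] * msg
                agg = anp.einsum("ne,bef->bnf", statics["incidence"], msg)
            else:
                agg = anp.einsum("ne,bef->bnf", statics["incidence"], msg)
                agg = agg / statics["counts"][None, :, None]
        h = h + _mlp(block["update"], agg)
    pooled = anp.mean(h[:, statics["pool"], :], axis=1)  # (B, F)
    return _mlp(params["readout"], pooled)[:, 0]


def batched_z_closure(model: CommittorModel, template: Configuration):
    """``(z_fn, graph)`` with ``z_fn(pos_batch, params) -> (B,)`` on the
    template's fixed graph topology."""
    graph = model.build_graph(template)
    statics = _graph_statics(graph, model.species_map)
    ids = graph.node_atom_ids

    def z_fn(pos_batch, params):
        return _network_forward_batched(
            params, pos_batch[:, ids, :], statics, model.config
        )

    return z_fn, graph


# ---------------------------------------------------------------------------
# coordinate gradients


def committor_gradient(config: Configuration, model: CommittorModel,
                       graph: AtomGraph | None = None,
                       mass_scaled: bool = True):
    """Coordinate gradients of q and z, plus the mass-scaled squared norm.

    Returns ``(grad_q, grad_z, grad_sq)`` where the gradients have the full
    (n_atoms, D) shape (zero rows for atoms excluded by truncation or frozen
    in the dynamics) and ``grad_sq = sum_i m_i^{-1} |d q / d x_i|^2`` over the
    mobile atoms (plain sum if ``mass_scaled`` is False).
    """
    z_fn, graph = model.z_closure(config, graph)
    grad_z = grad(lambda pos: z_fn(pos, model.params))(config.positions)
    grad_z = np.asarray(grad_z)
    if not np.all(np.isfinite(grad_z)):
        raise ModelError(
            f"non-finite model gradient on frame {config.extra.get('index', '?')}"
        )
    z = float(z_fn(config.positions, model.params))
    p = model.config.sigmoid_p
    q = float(sigmoid(z, p))
    grad_q = p * q * (1.0 - q) * grad_z
    mobile = config.mobile
    sq = np.sum(grad_q[mobile] ** 2, axis=1)
    if mass_scaled:
        sq = sq / config.masses[mobile]
    return grad_q, grad_z, float(np.sum(sq))
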