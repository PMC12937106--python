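"""Transition-state ensemble analysis and model interpretability tools.

The transition-state ensemble (TSE) is defined through the Kolmogorov
distribution ``p_K(x) = exp(-beta U_K(x)) / Z_K`` with
``U_K = U + V_K``; since ``exp(-beta V_K) = |grad_u q|^2``, a set of frames
drawn from the Boltzmann ensemble (weights ``w_i``) is reweighted to p_K by
``w_i * |grad_u q(x_i)|^2``.  p_K measures how much each configuration
contributes to the reactive flux, so its mass concentrates on the
transition-state region rather than on the (much more populated) basins.

Downstream analyses:

- ``tse_modes``: weighted k-medoids clustering of TSE frames in the latent
  space of last-layer node features (Euclidean metric); cluster masses are
  summed p_K weights and estimate the fraction of reactive trajectories
  passing through each transition-state motif;
- ``project_fes``: weighted-histogram free-energy surfaces over named
  collective variables;
- ``node_sensitivity``: per-atom relevance as the dataset mean of the norm
  of dz/dx_i;
- ``attention_profile``: attention scores of selected (source species ->
  target) messages binned by pair distance, against the corresponding pair
  distance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biasing import EPS_GRAD
from .model import CommittorModel
from .oracle import GridCommittor
from .systems import observable

__all__ = [
    "TSEResult",
    "SensitivityReport",
    "AttentionProfile",
    "kolmogorov_weights",
    "kolmogorov_weights_on_grid",
    "tse_modes",
    "project_fes",
    "node_sensitivity",
    "attention_profile",
    "AnalysisError",
]


class AnalysisError(ValueError):
    """Degenerate distributions, bad selectors, or missing model features."""


@dataclass
class TSEResult:
    frame_indices: np.ndarray
    pK_weights: np.ndarray
    mode_assignments: np.ndarray
    medoid_indices: np.ndarray
    mode_masses: np.ndarray


@dataclass
class SensitivityReport:
    per_atom_scores: np.ndarray
    ranking: np.ndarray
    n_graphs: int


@dataclass
class AttentionProfile:
    distance_bin_edges: np.ndarray
    mean_attention_per_bin: np.ndarray
    reference_rdf_per_bin: np.ndarray
    pair_selector: tuple


def kolmogorov_weights(frames, model: CommittorModel, beta: float) -> np.ndarray:
    """Normalized p_K weights: w_i * (|grad_u q|^2 + eps), summing to 1."""
    raw = []
    for f in frames:
        _, _, gsq = model.gradients(f)
        raw.append(f.weight * (gsq + EPS_GRAD))
    raw = np.asarray(raw)
    total = raw.sum()
    if total <= len(frames) * EPS_GRAD * 10:
        raise AnalysisError("all committor gradients vanish; p_K is degenerate")
    return raw / total


def kolmogorov_weights_on_grid(gc: GridCommittor) -> np.ndarray:
    """p_K on a grid from the oracle committor: ~ exp(-beta U) |grad q|^2."""
    grads = np.gradient(gc.q_values, *[a for a in gc.axes], edge_order=2)
    if gc.ndim == 1:
        grads = [grads]
    grad_sq = np.sum([g * g for g in grads], axis=0)
    raw = gc.boltzmann_density() * grad_sq
    return raw / raw.sum()


# ---------------------------------------------------------------------------
# weighted k-medoids (PAM-style alternation)


def _weighted_kmedoids(dist: np.ndarray, weights: np.ndarray, k: int,
                       seed: int, max_iter: int = 100):
    n = dist.shape[0]
    rng = np.random.default_rng(seed)
    # k-means++-style seeding on the distance matrix, weight-aware
    medoids = [int(rng.choice(n, p=weights / weights.sum()))]
    while len(medoids) < k:
        d2 = np.min(dist[:, medoids], axis=1) ** 2 * weights
        if d2.sum() == 0:
            medoids.append(int(rng.integers(n)))
            continue
        medoids.append(int(rng.choice(n, p=d2 / d2.sum())))
    medoids = np.array(medoids)
    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.nonzero(assign == c)[0]
            if len(members) == 0:
                continue
            cost = (weights[members][None, :] * dist[np.ix_(members, members)]).sum(axis=1)
            new_medoids[c] = members[np.argmin(cost)]
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    assign = np.argmin(dist[:, medoids], axis=1)
    return assign, medoids


def frame_features(frames, model: CommittorModel) -> np.ndarray:
    """Per-frame latent vector: pool-set mean of last-layer node features."""
    feats = []
    for f in frames:
        out = model.forward(f)
        feats.append(out.node_features[out.graph.pool_set].mean(axis=0))
    return np.asarray(feats)


def tse_modes(frames, pK_weights, model: CommittorModel | None, k: int,
              features: np.ndarray | None = None, seed: int = 0) -> TSEResult:
    """Cluster TSE frames into k modes in latent space; masses from p_K.

    ``features`` overrides the model-derived latent vectors (useful for
    crafted fixtures); otherwise a model is required.
    """
    pK_weights = np.asarray(pK_weights, dtype=float)
    if k < 1:
        raise AnalysisError("k must be >= 1")
    if k > len(frames):
        raise AnalysisError(f"k={k} exceeds the {len(frames)} frames")
    if abs(pK_weights.sum() - 1.0) > 1e-8:
        pK_weights = pK_weights / pK_weights.sum()
    if features is None:
        if model is None:
            raise AnalysisError("either a model or explicit features are required")
        features = frame_features(frames, model)
    diff = features[:, None, :] - features[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    assign, medoids = _weighted_kmedoids(dist, pK_weights, k, seed)
    masses = np.array([pK_weights[assign == c].sum() for c in range(k)])
    return TSEResult(
        frame_indices=np.arange(len(frames)),
        pK_weights=pK_weights,
        mode_assignments=assign,
        medoid_indices=medoids,
        mode_masses=masses,
    )


def silhouette_k_helper(features: np.ndarray, k_range, seed: int = 0) -> dict:
    """Mean silhouette score per k (Euclidean), to guide the choice of k."""
    from sklearn.metrics import silhouette_score

    scores = {}
    uniform = np.full(len(features), 1.0 / len(features))
    for k in k_range:
        if not 2 <= k < len(features):
            continue
        res = tse_modes(list(range(len(features))), uniform, None, k,
                        features=features, seed=seed)
        if len(set(res.mode_assignments)) < 2:
            continue
        scores[k] = float(silhouette_score(features, res.mode_assignments))
    return scores


# ---------------------------------------------------------------------------
# free-energy projections


def project_fes(frames, weights, cv_names, bin_edges, beta: float):
    """F = -(1/beta) log(weighted histogram), min-shifted; empty bins NaN.

    ``cv_names`` is a list of observable names (see ``systems.observable``)
    or callables; 1 or 2 CVs are supported.  Returns (F, bin_edges).
    """
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise AnalysisError("weights must have positive sum")
    weights = weights / weights.sum()
    cols = []
    for cv in cv_names:
        fn = (lambda f, name=cv: observable(name, f)) if isinstance(cv, str) else cv
        cols.append([fn(f) for f in frames])
    samples = np.asarray(cols).T
    if samples.shape[1] > 2:
        raise AnalysisError("at most two collective variables are supported")
    hist, edges = np.histogramdd(samples, bins=bin_edges, weights=weights)
    if hist.sum() == 0:
        raise AnalysisError("no frame falls inside the grid")
    with np.errstate(divide="ignore"):
        fes = -np.log(hist) / beta
    fes[hist == 0] = np.nan
    fes -= np.nanmin(fes)
    if len(cols) == 1:
        return fes.ravel(), edges[0]
    return fes, edges


# ---------------------------------------------------------------------------
# interpretability


def node_sensitivity(frames, model: CommittorModel,
                     norm: str = "euclidean") -> SensitivityReport:
    """Mean over frames of the per-atom norm of dz/dx (absent atoms count 0).

    ``norm='euclidean'`` (default) or ``'l1'`` for summed componentwise
    absolute values.
    """
    if len(frames) == 0:
        raise AnalysisError("empty dataset")
    n_atoms = frames[0].n_atoms
    acc = np.zeros(n_atoms)
    for f in frames:
        if f.n_atoms != n_atoms:
            raise AnalysisError("frames must share one atom indexing")
        _, grad_z, _ = model.gradients(f)
        if norm == "euclidean":
            acc += np.linalg.norm(grad_z, axis=1)
        elif norm == "l1":
            acc += np.abs(grad_z).sum(axis=1)
        else:
            raise AnalysisError(f"unknown norm {norm!r}")
    scores = acc / len(frames)
    return SensitivityReport(
        per_atom_scores=scores,
        ranking=np.argsort(-scores),
        n_graphs=len(frames),
    )


def _minmax(x: np.ndarray) -> np.ndarray:
    finite = np.isfinite(x)
    if not finite.any():
        return x
    lo, hi = np.min(x[finite]), np.max(x[finite])
    if hi == lo:
        return np.where(finite, 1.0, x)
    return (x - lo) / (hi - lo)


def attention_profile(frames, model: CommittorModel, pair_selector,
                      bin_edges, layer: int = -1) -> AttentionProfile:
    """Distance-resolved mean attention Att(r) for selected messages.

    ``pair_selector = (source_species, target)`` where ``target`` is either a
    species code or the string ``'reacting'``.  Attention of the chosen layer
    (default: last) is averaged within distance bins; the same pairs'
    distance histogram is the reference distribution.  Both curves are
    min-max normalized to (0, 1).
    """
    if not model.config.use_attention:
        raise AnalysisError("model was trained without attention; "
                            "attention_profile requires use_attention=True")
    src_species, target = pair_selector
    bin_edges = np.asarray(bin_edges, dtype=float)
    nbins = len(bin_edges) - 1
    att_sum = np.zeros(nbins)
    att_cnt = np.zeros(nbins)
    rdf_cnt = np.zeros(nbins)
    for f in frames:
        out = model.forward(f)
        g = out.graph
        alpha = out.attention_records[layer]
        d = g.distances(f.positions[g.node_atom_ids])
        src_ok = g.node_species[g.edge_src] == src_species
        if target == "reacting":
            dst_ok = g.reacting_mask[g.edge_dst]
        else:
            dst_ok = g.node_species[g.edge_dst] == int(target)
        sel = src_ok & dst_ok
        if not sel.any():
            continue
        which = np.clip(np.digitize(d[sel], bin_edges) - 1, 0, nbins - 1)
        inside = (d[sel] >= bin_edges[0]) & (d[sel] <= bin_edges[-1])
        np.add.at(att_sum, which[inside], alpha[sel][inside])
        np.add.at(att_cnt, which[inside], 1.0)
        np.add.at(rdf_cnt, which[inside], 1.0)
    if att_cnt.sum() == 0:
        raise AnalysisError(f"selector {pair_selector} matches no edges")
    with np.errstate(invalid="ignore"):
        att = att_sum / att_cnt
    att[att_cnt == 0] = np.nan
    return AttentionProfile(
        distance_bin_edges=bin_edges,
        mean_attention_per_bin=_minmax(att),
        reference_rdf_per_bin=_minmax(rdf_cnt.astype(float)),
        pair_selector=pair_selector,
    )
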