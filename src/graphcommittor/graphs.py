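"""Input-graph construction: neighbor lists and the truncated dual-cutoff graph.

Atoms are split into *reacting* atoms (always graph nodes, always pooled) and
*environment* atoms, which become nodes only if they lie within the outer
cutoff ``R_t = R_c + delta_b`` of some reacting atom.  Edges connect retained
atoms closer than ``R_c`` (minimum image in periodic cells); the buffer
``delta_b > 0`` guarantees that an atom cannot acquire an edge without first
having entered the node list, which stabilizes biased sampling between
neighbor-list rebuilds.  Reacting-reacting edges can additionally be enforced
regardless of distance so the reacting atoms never end up in disconnected
components.

Edges are directed and stored both ways; an edge (i, j) carries the message
from source j to destination i.  Neighbor search is a brute-force O(N^2) scan,
which doubles as its own correctness oracle at the system sizes this package
targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .systems import Configuration, minimum_image

__all__ = ["AtomGraph", "build_neighbor_list", "build_truncated_graph", "GraphError"]


class GraphError(ValueError):
    """Geometry or flag errors during graph construction."""


@dataclass
class AtomGraph:
    """Directed distance graph over the retained atoms of one configuration.

    ``edge_dst[e]``/``edge_src[e]`` index nodes (not original atoms); the
    minimum-image displacement is ``x[dst] - (x[src] + shift[e])`` so distances
    stay differentiable functions of the positions while the topology and
    image shifts are held fixed.
    """

    node_atom_ids: np.ndarray  # (n_nodes,) original atom indices
    node_species: np.ndarray  # (n_nodes,)
    reacting_mask: np.ndarray  # (n_nodes,) bool
    edge_dst: np.ndarray  # (n_edges,) destination node index (i)
    edge_src: np.ndarray  # (n_edges,) source node index (j)
    edge_shift: np.ndarray  # (n_edges, D) periodic image shift for the source
    edge_enforced: np.ndarray  # (n_edges,) bool
    r_cut: float
    r_trunc: float
    pool_set: np.ndarray  # (n_pool,) node indices entering the readout

    @property
    def n_nodes(self) -> int:
        return len(self.node_atom_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_dst)

    def distances(self, positions: np.ndarray) -> np.ndarray:
        """Edge distances for node positions (plain numpy; for inspection)."""
        disp = (
            positions[self.edge_dst]
            - positions[self.edge_src]
            - self.edge_shift
        )
        return np.linalg.norm(disp, axis=1)

    def edge_table(self, positions: np.ndarray | None = None) -> str:
        """Plain-text edge dump ``i j d_ij enforced`` for debugging."""
        lines = ["# i j d_ij enforced"]
        d = None if positions is None else self.distances(positions)
        for e in range(self.n_edges):
            dij = "nan" if d is None else f"{d[e]:.6f}"
            lines.append(
                f"{self.node_atom_ids[self.edge_dst[e]]} "
                f"{self.node_atom_ids[self.edge_src[e]]} {dij} "
                f"{int(self.edge_enforced[e])}"
            )
        return "\n".join(lines)


def _check_cutoff(cell: np.ndarray | None, cutoff: float) -> None:
    if cutoff <= 0:
        raise GraphError("cutoff must be positive")
    if cell is not None and cutoff >= 0.5 * float(np.min(cell)):
        raise GraphError(
            f"cutoff {cutoff} >= half the smallest box length {0.5 * float(np.min(cell))}"
        )


def build_neighbor_list(
    config: Configuration,
    cutoff: float,
    center_subset: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All ordered pairs (i, j), i in the center subset, with min-image d <= cutoff.

    Returns ``(i_idx, j_idx, distances)``.  Brute force over all pairs.
    """
    _check_cutoff(config.cell, cutoff)
    pos = config.positions
    n = config.n_atoms
    centers = np.arange(n) if center_subset is None else np.asarray(center_subset)
    dr = minimum_image(pos[centers][:, None, :] - pos[None, :, :], config.cell)
    dist = np.linalg.norm(dr, axis=2)
    mask = dist <= cutoff
    mask[np.arange(len(centers)), centers] = False  # no self pairs
    ci, jj = np.nonzero(mask)
    return centers[ci], jj, dist[ci, jj]


def build_truncated_graph(
    config: Configuration,
    r_cut: float,
    delta_b: float = 0.0,
    enforce_reacting_edges: bool = True,
    truncate: bool = True,
) -> AtomGraph:
    """Build the dual-neighbor-list truncated graph of a configuration.

    With ``truncate=True`` the node set is the reacting atoms plus environment
    atoms within ``R_t = r_cut + delta_b`` of any reacting atom, and only
    reacting nodes are pooled in the readout; with ``truncate=False`` every
    atom is a node and all nodes are pooled.
    """
    if delta_b < 0:
        raise GraphError("delta_b must be nonnegative")
    reacting_ids = np.nonzero(config.reacting)[0]
    if len(reacting_ids) == 0:
        raise GraphError("configuration has no reacting atoms")
    r_trunc = r_cut + delta_b
    n = config.n_atoms
    if truncate:
        # outer list NL_out: environment atoms within R_t of a reacting atom
        _check_cutoff(config.cell, r_trunc)
        i_out, j_out, _ = build_neighbor_list(config, r_trunc, center_subset=reacting_ids)
        keep = np.zeros(n, dtype=bool)
        keep[reacting_ids] = True
        keep[j_out] = True
        node_atom_ids = np.nonzero(keep)[0]
    else:
        node_atom_ids = np.arange(n)
    atom_to_node = -np.ones(n, dtype=int)
    atom_to_node[node_atom_ids] = np.arange(len(node_atom_ids))

    # inner list NL_graph at R_c among retained atoms
    sub_pos = config.positions[node_atom_ids]
    sub = Configuration(
        sub_pos,
        config.species[node_atom_ids],
        config.reacting[node_atom_ids],
        cell=config.cell,
    )
    ii, jj, _ = build_neighbor_list(sub, r_cut)
    enforced = np.zeros(len(ii), dtype=bool)

    if enforce_reacting_edges and len(reacting_ids) > 1:
        have = {(int(a), int(b)) for a, b in zip(ii, jj)}
        extra_i, extra_j = [], []
        rnodes = atom_to_node[reacting_ids]
        for a in rnodes:
            for b in rnodes:
                if a != b and (int(a), int(b)) not in have:
                    extra_i.append(a)
                    extra_j.append(b)
        if extra_i:
            ii = np.concatenate([ii, np.array(extra_i)])
            jj = np.concatenate([jj, np.array(extra_j)])
            enforced = np.concatenate([enforced, np.ones(len(extra_i), dtype=bool)])

    # image shift for each edge so displacements are differentiable later
    if config.cell is not None:
        raw = sub_pos[ii] - sub_pos[jj]  # dst minus src
        edge_shift = config.cell * np.round(raw / config.cell)
    else:
        edge_shift = np.zeros((len(ii), sub_pos.shape[1]))

    reacting_nodes = atom_to_node[reacting_ids]
    pool = reacting_nodes if truncate else np.arange(len(node_atom_ids))
    return AtomGraph(
        node_atom_ids=node_atom_ids,
        node_species=config.species[node_atom_ids],
        reacting_mask=config.reacting[node_atom_ids],
        edge_dst=ii,
        edge_src=jj,
        edge_shift=edge_shift,
        edge_enforced=enforced,
        r_cut=float(r_cut),
        r_trunc=float(r_trunc),
        pool_set=pool,
    )
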