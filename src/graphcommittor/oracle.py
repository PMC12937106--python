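"""Ground-truth committors on 1D/2D grids by finite differences.

The exact committor solves the steady backward Kolmogorov equation, which in
the overdamped, position-dependent-free case takes the divergence form

    div( exp(-beta U(x)) grad q(x) ) = 0,

with q = 0 on state A and q = 1 on state B and reflecting (no-flux) outer
boundaries.  The discretization uses second-order flux-form finite
differences with face-centered weights ``w = exp(-beta U)`` evaluated at cell
faces, which preserves the discrete maximum principle.  The resulting sparse
linear system is solved directly.

The same grids give quadrature values of the Kolmogorov functional
``K[q] = <|grad q|^2>_U`` used to validate trained models against the
variational bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "GridCommittor",
    "solve_committor_grid",
    "kolmogorov_functional_on_grid",
    "closed_form_committor_1d",
    "OracleError",
]


class OracleError(ValueError):
    """Ill-posed grid committor problems (empty/overlapping masks, etc.)."""


@dataclass
class GridCommittor:
    axes: list  # per-dimension 1D coordinate arrays (uniform spacing)
    potential: np.ndarray
    q_values: np.ndarray
    mask_a: np.ndarray
    mask_b: np.ndarray
    beta: float

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def boltzmann_density(self) -> np.ndarray:
        """Normalized exp(-beta U) on the grid (max-subtracted for stability)."""
        u = self.potential - np.min(self.potential)
        rho = np.exp(-self.beta * u)
        return rho / np.sum(rho)

    def interior(self) -> np.ndarray:
        return ~(self.mask_a | self.mask_b)

    def isocommittor_point(self, level: float = 0.5) -> float:
        """1D only: x where q crosses ``level`` (linear interpolation)."""
        if self.ndim != 1:
            raise OracleError("isocommittor_point is defined for 1D grids")
        x, q = self.axes[0], self.q_values
        idx = np.nonzero((q[:-1] - level) * (q[1:] - level) <= 0)[0]
        if len(idx) == 0:
            raise OracleError(f"q never crosses {level}")
        i = idx[0]
        t = (level - q[i]) / (q[i + 1] - q[i])
        return float(x[i] + t * (x[i + 1] - x[i]))


def _face_weight(wa: np.ndarray, wb: np.ndarray) -> np.ndarray:
    """Geometric-mean face weight: exact for exp(-beta U) at the midpoint of
    a linearly interpolated potential."""
    return np.sqrt(wa * wb)


def solve_committor_grid(axes, potential, mask_a, mask_b, beta) -> GridCommittor:
    """Solve the grid committor problem; supports 1D and 2D uniform grids."""
    axes = [np.asarray(a, dtype=float) for a in axes]
    potential = np.asarray(potential, dtype=float)
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if potential.shape != mask_a.shape or potential.shape != mask_b.shape:
        raise OracleError("potential and masks must share a shape")
    if not mask_a.any() or not mask_b.any():
        raise OracleError("both state masks must be nonempty")
    if (mask_a & mask_b).any():
        raise OracleError("state masks overlap")
    expected = tuple(len(a) for a in axes)
    if potential.shape != expected:
        raise OracleError(f"potential shape {potential.shape} != grid {expected}")

    w = np.exp(-beta * (potential - potential.min()))
    n = potential.size
    shape = potential.shape
    idx = np.arange(n).reshape(shape)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    dirichlet = mask_a | mask_b
    bvals = np.where(mask_b, 1.0, 0.0)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    it = np.ndindex(shape)
    spacings = [a[1] - a[0] for a in axes]
    for point in it:
        r = idx[point]
        if dirichlet[point]:
            add(r, r, 1.0)
            rhs[r] = bvals[point]
            continue
        diag = 0.0
        for dim, h in enumerate(spacings):
            for step in (-1, 1):
                nb = list(point)
                nb[dim] += step
                if nb[dim] < 0 or nb[dim] >= shape[dim]:
                    continue  # reflecting outer boundary: zero flux
                nb = tuple(nb)
                wf = _face_weight(w[point], w[nb]) / (h * h)
                add(r, idx[nb], wf)
                diag -= wf
        add(r, r, diag)
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    try:
        q = spla.spsolve(mat, rhs)
    except RuntimeError as err:  # pragma: no cover - singular systems
        raise OracleError(f"committor system could not be solved: {err}") from err
    if not np.all(np.isfinite(q)):
        raise OracleError("singular committor system (disconnected domain?)")
    q = np.clip(q.reshape(shape), 0.0, 1.0)
    return GridCommittor(axes, potential, q, mask_a, mask_b, float(beta))


def kolmogorov_functional_on_grid(gc: GridCommittor, q: np.ndarray | None = None) -> float:
    """Quadrature of K[q] = <|grad q|^2> over the normalized Boltzmann density.

    Unit masses; central differences for the gradient.  ``q`` defaults to the
    grid committor itself, but any field on the same grid (e.g. a trained
    model evaluated on the grid) can be measured.
    """
    q = gc.q_values if q is None else np.asarray(q, dtype=float)
    grads = np.gradient(q, *[a for a in gc.axes], edge_order=2)
    if gc.ndim == 1:
        grads = [grads]
    grad_sq = np.sum([g * g for g in grads], axis=0)
    rho = gc.boltzmann_density()
    return float(np.sum(grad_sq * rho))


def closed_form_committor_1d(x, potential, beta, mask_a, mask_b) -> np.ndarray:
    """1D closed form q(x) = int_a^x e^{beta U} / int_a^b e^{beta U}.

    ``a``/``b`` are the inner edges of the A and B masks; q is clamped to 0/1
    inside the states.  Trapezoidal quadrature on the given grid.
    """
    x = np.asarray(x, dtype=float)
    u = np.asarray(potential, dtype=float)
    g = np.exp(beta * (u - u.max()))
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * np.diff(x))])
    ia = int(np.nonzero(mask_a)[0].max())
    ib = int(np.nonzero(mask_b)[0].min())
    if ia >= ib:
        raise OracleError("A mask must lie left of B mask on the axis")
    q = (cum - cum[ia]) / (cum[ib] - cum[ia])
    q = np.clip(q, 0.0, 1.0)
    q[np.asarray(mask_a, dtype=bool)] = 0.0
    q[np.asarray(mask_b, dtype=bool)] = 1.0
    return q
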