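"""Toy systems: model potentials, Langevin integrators, and fixture generators.

All quantities are in reduced units with ``k_B = 1``; energies are therefore
measured in units of ``1/beta`` when ``beta = 1``.  Low-dimensional systems
(``flat``, ``double_well_1d``, ``double_well_2d``) describe a single mobile
particle augmented with fixed *anchor* atoms of distinct species placed at the
domain ends, so that a purely distance-based graph model can resolve the
particle position (the distances to the anchors determine it uniquely).
Anchors are frozen: they do not move under the integrator and do not
contribute to mass-scaled gradient norms.

The ``dimer_bath`` system is a 3D periodic particle system: two *reacting*
atoms bound by a double-well bond potential (compact and extended minima)
immersed in a bath of purely repulsive (WCA) particles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SystemSpec",
    "Configuration",
    "StateDefinition",
    "potential_energy",
    "potential_forces",
    "langevin_step",
    "run_langevin",
    "generate_dimer_bath",
    "make_low_dim_configuration",
    "observable",
    "assign_state_label",
    "ConfigurationError",
    "IntegrationError",
    "GenerationError",
    "StateDefinitionError",
]

ANCHOR_SPECIES_OFFSET = 100  # anchor species codes start here; particle is 0


class ConfigurationError(ValueError):
    """Unknown potential or inconsistent system parameters."""


class IntegrationError(RuntimeError):
    """Non-finite forces or positions during Langevin integration."""


class GenerationError(RuntimeError):
    """Random placement failed within the retry budget."""


class StateDefinitionError(ValueError):
    """Overlapping or ill-formed state membership rules."""


@dataclass
class Configuration:
    """A single frame: positions, species, flags and statistical metadata.

    ``positions`` has shape (n_atoms, D) with D in {1, 2, 3}.  ``bias_energy``
    is the total bias potential acting when the frame was sampled (0 for
    unbiased runs) and enters reweighting as ``w ~ exp(+beta * bias_energy)``.
    """

    positions: np.ndarray
    species: np.ndarray
    reacting: np.ndarray
    mobile: np.ndarray | None = None
    masses: np.ndarray | None = None
    cell: np.ndarray | None = None
    bias_energy: float = 0.0
    weight: float = 1.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.species = np.asarray(self.species, dtype=int)
        self.reacting = np.asarray(self.reacting, dtype=bool)
        n = self.positions.shape[0]
        if self.species.shape[0] != n or self.reacting.shape[0] != n:
            raise ConfigurationError(
                f"species/reacting length mismatch: {self.species.shape[0]}, "
                f"{self.reacting.shape[0]} vs {n} atoms"
            )
        if self.mobile is None:
            self.mobile = np.ones(n, dtype=bool)
        else:
            self.mobile = np.asarray(self.mobile, dtype=bool)
        if self.masses is None:
            self.masses = np.ones(n, dtype=float)
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ConfigurationError("masses must be positive")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float)
            if np.any(self.cell <= 0):
                raise ConfigurationError("cell lengths must be positive")
        if self.weight < 0:
            raise ConfigurationError("weight must be nonnegative")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    def copy(self) -> "Configuration":
        return replace(
            self,
            positions=self.positions.copy(),
            species=self.species.copy(),
            reacting=self.reacting.copy(),
            mobile=self.mobile.copy(),
            masses=self.masses.copy(),
            cell=None if self.cell is None else self.cell.copy(),
            extra=dict(self.extra),
        )


@dataclass
class SystemSpec:
    """System definition: potential, its parameters and the thermodynamic state.

    ``parameters`` must be complete for the chosen ``potential_id``:

    - ``flat``: ``lo``, ``hi`` (reflecting walls)
    - ``double_well_1d``: ``barrier`` (h in U = h (x^2 - 1)^2)
    - ``double_well_2d``: ``barrier``, ``k_y`` (harmonic transverse channel)
    - ``dimer_bath``: ``bond_h``, ``bond_r0``, ``bond_w``, ``wca_epsilon``,
      ``wca_sigma``, ``box_length``, ``n_bath``
    """

    dimensionality: int
    potential_id: str
    parameters: dict
    beta: float = 1.0
    masses: dict | None = None  # species code -> mass

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ConfigurationError("beta must be positive")
        if self.potential_id not in _POTENTIALS:
            raise ConfigurationError(
                f"unknown potential_id {self.potential_id!r}; "
                f"known: {sorted(_POTENTIALS)}"
            )
        missing = _REQUIRED_PARAMS[self.potential_id] - set(self.parameters)
        if missing:
            raise ConfigurationError(
                f"potential {self.potential_id!r} missing parameters {sorted(missing)}"
            )

    def mass_of(self, species_code: int) -> float:
        if self.masses is None:
            return 1.0
        return float(self.masses.get(int(species_code), 1.0))


# ---------------------------------------------------------------------------
# potentials


def _particle_coord(config: Configuration) -> np.ndarray:
    """Coordinate vector of the single mobile particle of a low-dim system."""
    return config.positions[0]


def _flat_energy(spec, config):
    return 0.0


def _flat_forces(spec, config):
    return np.zeros_like(config.positions)


def _dw1d_energy(spec, config):
    h = spec.parameters["barrier"]
    x = _particle_coord(config)[0]
    return h * (x * x - 1.0) ** 2


def _dw1d_forces(spec, config):
    h = spec.parameters["barrier"]
    f = np.zeros_like(config.positions)
    x = config.positions[0, 0]
    f[0, 0] = -4.0 * h * x * (x * x - 1.0)
    return f


def _dw2d_energy(spec, config):
    h = spec.parameters["barrier"]
    k_y = spec.parameters["k_y"]
    x, y = _particle_coord(config)[:2]
    return h * (x * x - 1.0) ** 2 + 0.5 * k_y * y * y


def _dw2d_forces(spec, config):
    h = spec.parameters["barrier"]
    k_y = spec.parameters["k_y"]
    f = np.zeros_like(config.positions)
    x, y = config.positions[0, :2]
    f[0, 0] = -4.0 * h * x * (x * x - 1.0)
    f[0, 1] = -k_y * y
    return f


def minimum_image(dr: np.ndarray, cell: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    if cell is None:
        return dr
    return dr - cell * np.round(dr / cell)


def dimer_bond_energy(r: float, h: float, r0: float, w: float) -> float:
    """Symmetric double well in the bond length: minima at r0 and r0 + 2w."""
    u = 1.0 - ((r - r0 - w) / w) ** 2
    return h * u * u


def _dimer_pairs(config):
    n = config.n_atoms
    ii, jj = np.triu_indices(n, k=1)
    dr = minimum_image(config.positions[ii] - config.positions[jj], config.cell)
    d = np.linalg.norm(dr, axis=1)
    return ii, jj, dr, d


def _dimer_energy(spec, config):
    p = spec.parameters
    ii, jj, _, d = _dimer_pairs(config)
    bond_mask = (ii == 0) & (jj == 1)
    e = dimer_bond_energy(float(d[bond_mask][0]), p["bond_h"], p["bond_r0"], p["bond_w"])
    eps, sig = p["wca_epsilon"], p["wca_sigma"]
    rc = 2.0 ** (1.0 / 6.0) * sig
    d_wca = d[~bond_mask]
    close = d_wca < rc
    if np.any(close):
        sr6 = (sig / d_wca[close]) ** 6
        e += float(np.sum(4.0 * eps * (sr6 * sr6 - sr6) + eps))
    return e


def _dimer_forces(spec, config):
    p = spec.parameters
    ii, jj, dr, d = _dimer_pairs(config)
    f = np.zeros_like(config.positions)
    h, r0, w = p["bond_h"], p["bond_r0"], p["bond_w"]
    eps, sig = p["wca_epsilon"], p["wca_sigma"]
    rc = 2.0 ** (1.0 / 6.0) * sig
    for k in range(len(ii)):
        i, j = ii[k], jj[k]
        r = d[k]
        if i == 0 and j == 1:
            u = 1.0 - ((r - r0 - w) / w) ** 2
            dV = h * 2.0 * u * (-2.0 * (r - r0 - w) / w**2)
        elif r < rc:
            sr6 = (sig / r) ** 6
            dV = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        else:
            continue
        fvec = -dV * dr[k] / r  # force on atom i; -fvec on j
        f[i] += fvec
        f[j] -= fvec
    return f


_POTENTIALS = {
    "flat": (_flat_energy, _flat_forces),
    "double_well_1d": (_dw1d_energy, _dw1d_forces),
    "double_well_2d": (_dw2d_energy, _dw2d_forces),
    "dimer_bath": (_dimer_energy, _dimer_forces),
}

_REQUIRED_PARAMS = {
    "flat": {"lo", "hi"},
    "double_well_1d": {"barrier"},
    "double_well_2d": {"barrier", "k_y"},
    "dimer_bath": {"bond_h", "bond_r0", "bond_w", "wca_epsilon", "wca_sigma",
                   "box_length", "n_bath"},
}


def potential_energy(spec: SystemSpec, config: Configuration) -> float:
    """Evaluate U(x) for the system's potential."""
    energy, _ = _POTENTIALS[spec.potential_id]
    return float(energy(spec, config))


def potential_forces(spec: SystemSpec, config: Configuration) -> np.ndarray:
    """-grad U(x), shape (n_atoms, D)."""
    _, forces = _POTENTIALS[spec.potential_id]
    return forces(spec, config)


# ---------------------------------------------------------------------------
# integrators


def _atom_masses(spec: SystemSpec, config: Configuration) -> np.ndarray:
    if spec.masses is None:
        return config.masses
    return np.array([spec.mass_of(s) for s in config.species], dtype=float)


def _reflect(pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect scalar coordinates into [lo, hi] (possibly multiple folds)."""
    span = hi - lo
    y = np.mod(pos - lo, 2.0 * span)
    y = np.where(y > span, 2.0 * span - y, y)
    return lo + y


def langevin_step(
    config: Configuration,
    spec: SystemSpec,
    dt: float,
    friction: float,
    rng: np.random.Generator,
    bias_force: np.ndarray | None = None,
    velocities: np.ndarray | None = None,
    scheme: str = "overdamped",
    zero_temperature: bool = False,
) -> tuple[Configuration, np.ndarray | None]:
    """Advance one Langevin step; the stationary law at zero bias is exp(-beta U).

    ``scheme='overdamped'`` is Euler-Maruyama on the overdamped equation;
    ``scheme='lm'`` is the Leimkuhler-Matthews variant (each step uses the
    average of the previous and current Gaussian variates), which has the
    same cost but O(dt^2) instead of O(dt) configurational sampling error —
    preferable whenever forces are stiff, e.g. under committor-derived
    biases; ``scheme='baoab'`` is the underdamped BAOAB splitting
    (recommended for particle systems).  Frozen atoms never move.  Returns
    the new frame and the integrator carry-over state (velocities for
    BAOAB, the current noise variate for LM).
    """
    if dt <= 0 or friction <= 0:
        raise IntegrationError("dt and friction must be positive")
    force = potential_forces(spec, config)
    if bias_force is not None:
        force = force + bias_force
    if not np.all(np.isfinite(force)):
        raise IntegrationError(f"non-finite force on frame {config.extra.get('index', '?')}")
    masses = _atom_masses(spec, config)[:, None]
    mobile = config.mobile[:, None]
    new = config.copy()
    if scheme in ("overdamped", "lm"):
        drift = force / (friction * masses) * dt
        if zero_temperature:
            noise = 0.0
            vel_out = None
        else:
            sigma = np.sqrt(2.0 * dt / (spec.beta * friction * masses))
            xi = rng.standard_normal(config.positions.shape)
            if scheme == "lm":
                # average consecutive variates: O(dt^2) sampling accuracy
                prev = velocities if velocities is not None else xi
                noise = sigma * 0.5 * (prev + xi)
                vel_out = xi
            else:
                noise = sigma * xi
                vel_out = None
        new.positions = config.positions + np.where(mobile, drift + noise, 0.0)
    elif scheme == "baoab":
        if velocities is None:
            velocities = np.zeros_like(config.positions)
        v = velocities + 0.5 * dt * force / masses
        x = config.positions + 0.5 * dt * v
        c1 = math.exp(-friction * dt)
        if zero_temperature:
            c2 = 0.0
        else:
            c2 = np.sqrt((1.0 - c1 * c1) / (spec.beta * masses))
        v = c1 * v + c2 * rng.standard_normal(v.shape)
        x = x + 0.5 * dt * v
        probe = config.copy()
        probe.positions = np.where(mobile, x, config.positions)
        force2 = potential_forces(spec, probe)
        if bias_force is not None:
            force2 = force2 + bias_force
        v = v + 0.5 * dt * force2 / masses
        new.positions = probe.positions
        vel_out = np.where(mobile, v, 0.0)
    else:
        raise IntegrationError(f"unknown integrator scheme {scheme!r}")
    if spec.potential_id == "flat":
        lo, hi = spec.parameters["lo"], spec.parameters["hi"]
        new.positions[config.mobile] = _reflect(new.positions[config.mobile], lo, hi)
    if config.cell is not None:
        new.positions = np.where(mobile, np.mod(new.positions, config.cell), new.positions)
    if not np.all(np.isfinite(new.positions)):
        raise IntegrationError("non-finite positions after step")
    return new, vel_out


def run_langevin(
    spec: SystemSpec,
    initial: Configuration,
    n_steps: int,
    dt: float,
    friction: float,
    seed: int,
    save_stride: int = 10,
    scheme: str = "overdamped",
    bias_force_fn=None,
) -> list[Configuration]:
    """Unbiased (or externally biased) Langevin trajectory, frames every stride.

    ``bias_force_fn(config) -> (bias_energy, bias_forces)`` lets callers attach
    an arbitrary bias; saved frames then record ``bias_energy`` for reweighting.
    """
    rng = np.random.default_rng(seed)
    config = initial.copy()
    vel = None
    frames: list[Configuration] = []
    for step in range(n_steps):
        if bias_force_fn is not None:
            vbias, fbias = bias_force_fn(config)
        else:
            vbias, fbias = 0.0, None
        config, vel = langevin_step(
            config, spec, dt, friction, rng,
            bias_force=fbias, velocities=vel, scheme=scheme,
        )
        if (step + 1) % save_stride == 0:
            frame = config.copy()
            if bias_force_fn is not None:
                vb, _ = bias_force_fn(frame)
                frame.bias_energy = float(vb)
            else:
                frame.bias_energy = float(vbias)
            frame.extra["index"] = step + 1
            frames.append(frame)
    return frames


# ---------------------------------------------------------------------------
# fixture generators


def make_low_dim_configuration(spec: SystemSpec, coords) -> Configuration:
    """Particle + frozen anchor atoms for a 1D/2D model potential.

    Anchors carry species codes >= ``ANCHOR_SPECIES_OFFSET`` (one code per
    anchor so they are distinguishable) and sit at the corners of the domain;
    the mobile particle has species 0 and is the only reacting atom.
    """
    coords = np.atleast_1d(np.asarray(coords, dtype=float))
    d = spec.dimensionality
    if coords.shape != (d,):
        raise ConfigurationError(f"expected {d} coordinates, got {coords.shape}")
    anchors = _anchor_positions(spec)
    positions = np.vstack([coords[None, :], anchors])
    n_anchor = anchors.shape[0]
    species = np.array([0] + [ANCHOR_SPECIES_OFFSET + k for k in range(n_anchor)])
    reacting = np.array([True] + [False] * n_anchor)
    mobile = np.array([True] + [False] * n_anchor)
    return Configuration(positions, species, reacting, mobile=mobile)


def _anchor_positions(spec: SystemSpec) -> np.ndarray:
    if spec.potential_id == "flat":
        lo, hi = spec.parameters["lo"], spec.parameters["hi"]
    elif spec.potential_id in ("double_well_1d", "double_well_2d"):
        half = spec.parameters.get("anchor_half_width", 2.0)
        lo, hi = -half, half
    else:
        raise ConfigurationError(
            f"anchors are only defined for low-dimensional potentials, "
            f"not {spec.potential_id!r}"
        )
    if spec.dimensionality == 1:
        return np.array([[lo], [hi]])
    if spec.dimensionality == 2:
        return np.array([[lo, lo], [hi, lo], [0.0, hi]])
    raise ConfigurationError("anchored systems support D <= 2")


def generate_dimer_bath(
    n_bath: int,
    box_length: float,
    seed: int,
    spec: SystemSpec | None = None,
    bond_length: float | None = None,
    min_distance: float = 0.95,
    max_retries: int = 2000,
) -> Configuration:
    """Place the dimer plus ``n_bath`` repulsive bath particles in a periodic box.

    Species codes: 1 for the two reacting dimer atoms, 2 for bath.  No pair is
    closer (minimum image) than ``min_distance``.
    """
    if n_bath < 0:
        raise GenerationError("n_bath must be nonnegative")
    rng = np.random.default_rng(seed)
    cell = np.full(3, float(box_length))
    if bond_length is None:
        bond_length = spec.parameters["bond_r0"] if spec is not None else 1.1
    center = cell / 2.0
    axis = np.array([1.0, 0.0, 0.0])
    positions = [center - 0.5 * bond_length * axis, center + 0.5 * bond_length * axis]
    for _ in range(n_bath):
        for attempt in range(max_retries):
            trial = rng.uniform(0.0, box_length, size=3)
            dr = minimum_image(np.asarray(positions) - trial, cell)
            if np.all(np.linalg.norm(dr, axis=1) >= min_distance):
                positions.append(trial)
                break
        else:
            raise GenerationError(
                f"failed to place bath particle after {max_retries} retries "
                f"(n_bath={n_bath}, box={box_length})"
            )
    n = 2 + n_bath
    species = np.array([1, 1] + [2] * n_bath)
    reacting = np.array([True, True] + [False] * n_bath)
    return Configuration(np.asarray(positions), species, reacting, cell=cell)


# ---------------------------------------------------------------------------
# state definitions


def observable(name: str, config: Configuration) -> float:
    """Named scalar observables used by state membership rules."""
    if name == "x":
        return float(config.positions[0, 0])
    if name == "y":
        return float(config.positions[0, 1])
    if name == "bond_length":
        dr = minimum_image(config.positions[0] - config.positions[1], config.cell)
        return float(np.linalg.norm(dr))
    raise StateDefinitionError(f"unknown observable {name!r}")


@dataclass
class StateDefinition:
    """Metastable-state membership as bounds on named scalar observables."""

    label: str  # "A" or "B"
    bounds: dict  # observable name -> (lo, hi); None means unbounded

    def contains(self, config: Configuration) -> bool:
        for name, (lo, hi) in self.bounds.items():
            v = observable(name, config)
            if lo is not None and v < lo:
                return False
            if hi is not None and v > hi:
                return False
        return True


def assign_state_label(config: Configuration, states: list[StateDefinition]) -> str:
    """Return 'A', 'B' or 'unlabeled'; overlapping definitions are an error."""
    labels = [s.label for s in states if s.contains(config)]
    if len(labels) > 1:
        raise StateDefinitionError(f"state rules overlap: frame matches {labels}")
    return labels[0] if labels else "unlabeled"
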