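"""Velocity-Verlet molecular dynamics with a velocity-scaling thermostat.

The engine samples the potential energy surface (PES) of a molecular system
over a pluggable force-field evaluator: velocities are initialised from the
Maxwell distribution at a chosen temperature (default 773.15 K — deliberately
hot, to cover phase space), positions are integrated with the symplectic
velocity Verlet scheme, and the kinetic temperature is held near a target by
rescaling all velocities by sqrt(T_target / T_inst).

Two unit systems are supported.  ``REDUCED`` sets k_B = 1 and is the default
for the toy force fields.  ``PHYSICAL`` uses amu, Å, fs and kcal/mol with a
0.5 fs default time step.
Temperature always uses 3N - 3 degrees of freedom, because the
center-of-mass momentum is removed at initialisation and velocity Verlet with
internal forces conserves it.

A trajectory's potential-energy sample is condensed into a fixed-length
*energy fingerprint*: q equally spaced quantiles of the sampled energies with
the sample minimum subtracted, making the descriptor invariant to a constant
energy offset of the force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forcefields import ForceField

__all__ = [
    "UnitSystem",
    "REDUCED",
    "PHYSICAL",
    "MolecularSystem",
    "MDConfig",
    "MDState",
    "Trajectory",
    "EnergyFingerprint",
    "IntegrationBlowupError",
    "maxwell_velocities",
    "instantaneous_temperature",
    "velocity_scaling",
    "velocity_verlet_step",
    "run_md",
    "energy_fingerprint",
    "read_xyz",
    "write_trajectory_xyz",
    "ATOMIC_MASSES",
]

# Average atomic masses (amu) for XYZ input of organic molecules.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904,
}


@dataclass(frozen=True)
class UnitSystem:
    """Unit conventions for the integrator.

    ``kb`` is Boltzmann's constant in energy units per kelvin;
    ``acceleration_factor`` converts (energy / length / mass) into
    length / time^2 for the chosen units.
    """

    name: str
    kb: float
    acceleration_factor: float

    @property
    def kinetic_factor(self) -> float:
        """Converts mass * velocity^2 into energy units."""
        return 1.0 / self.acceleration_factor


REDUCED = UnitSystem(name="reduced", kb=1.0, acceleration_factor=1.0)
# kcal/mol per K; and kcal/mol/(Å·amu) -> Å/fs²
PHYSICAL = UnitSystem(name="physical", kb=1.987204259e-3,
                      acceleration_factor=4.184e-4)


class IntegrationBlowupError(RuntimeError):
    """Raised when the integrator produces non-finite energies or forces."""


@dataclass(frozen=True)
class MolecularSystem:
    """Particles with masses and Cartesian coordinates."""

    masses: np.ndarray       # (n,)
    coordinates: np.ndarray  # (n, 3)
    labels: tuple = ()

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if masses.size < 1 or np.any(masses <= 0):
            raise ValueError("masses must be positive and non-empty")
        if coords.shape[0] != masses.size:
            raise ValueError("coordinates/masses length mismatch")
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_particles(self) -> int:
        return self.masses.size


@dataclass(frozen=True)
class MDConfig:
    """Simulation settings.

    Defaults follow the physical-units convention for PES sampling: a 0.5 fs
    time step and Maxwell initialisation at 773.15 K (thermostat target
    defaults to the same value).  For reduced-unit toy runs pass dt and
    temperatures in reduced units.
    """

    dt: float = 0.5
    n_steps: int = 1000
    t_init: float = 773.15
    t_target: float | None = None
    thermostat_interval: int | None = 1
    record_interval: int = 1
    seed: int = 0
    units: UnitSystem = PHYSICAL

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_steps < 1 or self.t_init < 0:
            raise ValueError("require dt > 0, n_steps >= 1, t_init >= 0")
        if self.record_interval < 1:
            raise ValueError("record_interval must be >= 1")

    @property
    def target(self) -> float:
        return self.t_init if self.t_target is None else self.t_target


@dataclass
class MDState:
    """Instantaneous integrator state (forces cached between steps)."""

    coordinates: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    potential_energy: float
    step: int = 0


@dataclass(frozen=True)
class Trajectory:
    """Recorded frames of one MD run."""

    coordinates: np.ndarray        # (n_frames, n, 3)
    velocities: np.ndarray         # (n_frames, n, 3)
    potential_energy: np.ndarray   # (n_frames,)
    kinetic_energy: np.ndarray     # (n_frames,)
    temperature: np.ndarray        # (n_frames,)
    config: MDConfig
    labels: tuple = ()

    @property
    def n_frames(self) -> int:
        return self.potential_energy.size


@dataclass(frozen=True)
class EnergyFingerprint:
    """Offset-removed energy-quantile descriptor of one compound's PES."""

    compound_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    @property
    def q(self) -> int:
        return self.values.size


def _kinetic_energy(velocities: np.ndarray, masses: np.ndarray, units: UnitSystem) -> float:
    return 0.5 * units.kinetic_factor * float(np.sum(masses[:, None] * velocities**2))


def maxwell_velocities(
    masses: np.ndarray,
    temperature: float,
    rng: np.random.Generator | int | None = None,
    units: UnitSystem = REDUCED,
) -> np.ndarray:
    """Draw velocities from the Maxwell distribution and remove COM drift.

    Each component is N(0, k_B T / m_i) in the chosen units; the net
    center-of-mass momentum is subtracted afterwards, so the draw satisfies
    sum_i m_i v_i = 0 exactly.
    """
    masses = np.asarray(masses, dtype=float)
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if temperature == 0:
        return np.zeros((masses.size, 3))
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sigma = np.sqrt(units.kb * temperature * units.acceleration_factor / masses)
    v = rng.normal(size=(masses.size, 3)) * sigma[:, None]
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v


def instantaneous_temperature(
    velocities: np.ndarray,
    masses: np.ndarray,
    units: UnitSystem = REDUCED,
) -> float:
    """Kinetic temperature T = 2 KE / (k_B N_dof) with N_dof = 3N - 3."""
    masses = np.asarray(masses, dtype=float)
    n_dof = 3 * masses.size - 3
    if n_dof <= 0:
        raise ValueError("temperature undefined for a single particle with COM removed")
    ke = _kinetic_energy(np.asarray(velocities, dtype=float), masses, units)
    return 2.0 * ke / (units.kb * n_dof)


def velocity_scaling(
    velocities: np.ndarray,
    masses: np.ndarray,
    t_target: float,
    units: UnitSystem = REDUCED,
) -> np.ndarray:
    """Rescale velocities so the kinetic temperature equals ``t_target``."""
    t_current = instantaneous_temperature(velocities, masses, units)
    if t_current == 0.0:
        if t_target == 0.0:
            return np.array(velocities, dtype=float, copy=True)
        raise ValueError("cannot scale zero velocities to a nonzero temperature")
    return np.asarray(velocities, dtype=float) * np.sqrt(t_target / t_current)


def velocity_verlet_step(
    state: MDState,
    force_field: ForceField,
    dt: float,
    masses: np.ndarray,
    units: UnitSystem = REDUCED,
) -> MDState:
    """One velocity-Verlet step with a single new force evaluation.

    x(t+dt) = x + v dt + (f / 2m) dt^2
    v(t+dt) = v + (f(t) + f(t+dt)) / (2m) dt
    """
    m = np.asarray(masses, dtype=float)[:, None]
    acc = state.forces / m * units.acceleration_factor
    x_new = state.coordinates + state.velocities * dt + 0.5 * acc * dt * dt
    e_new, g_new = force_field.evaluate(x_new)
    f_new = -g_new
    if not (np.isfinite(e_new) and np.all(np.isfinite(f_new))):
        raise IntegrationBlowupError(
            f"non-finite energy/forces at step {state.step + 1} "
            f"(field {force_field.name!r})"
        )
    acc_new = f_new / m * units.acceleration_factor
    v_new = state.velocities + 0.5 * (acc + acc_new) * dt
    return MDState(
        coordinates=x_new, velocities=v_new, forces=f_new,
        potential_energy=float(e_new), step=state.step + 1,
    )


def run_md(
    system: MolecularSystem,
    force_field: ForceField,
    config: MDConfig,
) -> Trajectory:
    """Run an MD trajectory; fully reproducible from ``config.seed``.

    Velocities start from the Maxwell distribution at ``t_init``; every
    ``thermostat_interval`` steps (``None`` disables the thermostat, giving an
    NVE run) velocities are rescaled to ``t_target``.  Frames — including the
    initial state — are recorded every ``record_interval`` steps, for
    floor(n_steps / record_interval) + 1 frames in total.
    """
    units = config.units
    rng = np.random.default_rng(config.seed)
    v0 = maxwell_velocities(system.masses, config.t_init, rng, units)
    e0, g0 = force_field.evaluate(system.coordinates)
    if not (np.isfinite(e0) and np.all(np.isfinite(g0))):
        raise IntegrationBlowupError("non-finite energy/forces at step 0")
    state = MDState(
        coordinates=system.coordinates.copy(), velocities=v0, forces=-g0,
        potential_energy=float(e0),
    )

    frames_x, frames_v, epot, ekin, temps = [], [], [], [], []

    def record(s: MDState) -> None:
        frames_x.append(s.coordinates.copy())
        frames_v.append(s.velocities.copy())
        epot.append(s.potential_energy)
        ke = _kinetic_energy(s.velocities, system.masses, units)
        ekin.append(ke)
        temps.append(instantaneous_temperature(s.velocities, system.masses, units))

    record(state)
    for step in range(1, config.n_steps + 1):
        state = velocity_verlet_step(state, force_field, config.dt, system.masses, units)
        if config.thermostat_interval and step % config.thermostat_interval == 0:
            state = replace(
                state,
                velocities=velocity_scaling(
                    state.velocities, system.masses, config.target, units
                ),
            )
        if step % config.record_interval == 0:
            record(state)

    return Trajectory(
        coordinates=np.array(frames_x),
        velocities=np.array(frames_v),
        potential_energy=np.array(epot),
        kinetic_energy=np.array(ekin),
        temperature=np.array(temps),
        config=config,
        labels=system.labels,
    )


def energy_fingerprint(
    trajectory: Trajectory | np.ndarray,
    q: int = 64,
    compound_id: str = "",
) -> EnergyFingerprint:
    """q equally spaced quantiles (0..1 inclusive) of the potential-energy
    sample, shifted so the first element is zero.

    The minimum-offset removal makes fingerprints invariant to constant
    energy shifts of the force field; the values are non-decreasing by
    construction.
    """
    energies = (
        trajectory.potential_energy
        if isinstance(trajectory, Trajectory)
        else np.asarray(trajectory, dtype=float)
    )
    if q < 2:
        raise ValueError("q must be >= 2")
    if energies.size < q:
        raise ValueError(f"need >= {q} recorded frames, got {energies.size}")
    quantiles = np.quantile(energies, np.linspace(0.0, 1.0, q))
    return EnergyFingerprint(compound_id=compound_id, values=quantiles - quantiles[0])


def read_xyz(path) -> MolecularSystem:
    """Read a standard XYZ file (count line, comment line, element x y z)."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() or True]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"{path}: first line must be the atom count") from exc
    labels, coords = [], []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        element = parts[0]
        if element not in ATOMIC_MASSES:
            raise ValueError(f"{path}: unknown element {element!r}")
        labels.append(element)
        coords.append([float(v) for v in parts[1:4]])
    if len(labels) != n:
        raise ValueError(f"{path}: expected {n} atom records, found {len(labels)}")
    masses = np.array([ATOMIC_MASSES[e] for e in labels])
    return MolecularSystem(masses=masses, coordinates=np.array(coords),
                           labels=tuple(labels))


def write_trajectory_xyz(trajectory: Trajectory, path) -> None:
    """Write frames as extended XYZ with per-frame energies in the comment."""
    labels = trajectory.labels or tuple(
        f"X{i}" for i in range(trajectory.coordinates.shape[1])
    )
    with open(path, "w") as fh:
        for i in range(trajectory.n_frames):
            fh.write(f"{len(labels)}\n")
            fh.write(
                f"frame={i} epot={trajectory.potential_energy[i]:.10g} "
                f"ekin={trajectory.kinetic_energy[i]:.10g} "
                f"T={trajectory.temperature[i]:.6g}\n"
            )
            for lab, xyz in zip(labels, trajectory.coordinates[i]):
                fh.write(f"{lab} {xyz[0]:.10g} {xyz[1]:.10g} {xyz[2]:.10g}\n")
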