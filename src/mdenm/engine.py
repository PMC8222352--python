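"""Langevin dynamics on the network potential and the MDeNM protocol.

MDeNM (molecular dynamics with excited normal modes) runs many short MD
replicas; in each replica a fixed random linear combination of the selected
low-frequency normal modes is repeatedly "kinetically excited": a velocity
increment along the combined mode vector is added so that the instantaneous
kinetic temperature rises by a prescribed amount (2 K by default), and the
system then relaxes for a few ps of ordinary Langevin dynamics before the
next kick. A plain-MD arm with Maxwell-Boltzmann initial velocities serves
as the comparison baseline.

Unit system: lengths Å, time ps, energies kcal/mol, masses amu; the single
conversion constant KCAL_TO_AKMA (= 418.4 amu·Å²/ps² per kcal/mol) links
kinetic and potential energy. The integrator is BAOAB with friction gamma
(default 1 ps^-1) and a 2 fs time step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import KB_KCAL, KCAL_TO_AKMA, Ensemble, Structure
from .enm import ModeSet, NetworkPotential

try:  # compiled BAOAB inner loop; a pure-numpy fallback is kept below
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "MDState",
    "ExcitationDirection",
    "ProtocolConfig",
    "DirectionBudgetError",
    "displacement_rmsd",
    "generate_directions",
    "kinetic_temperature",
    "maxwell_boltzmann_velocities",
    "excite",
    "relax",
    "run_mdenm",
    "run_md",
]


@dataclass
class MDState:
    coords: np.ndarray
    velocities: np.ndarray
    time_ps: float = 0.0
    bath_temperature: float = 300.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).ravel()
        self.velocities = np.asarray(self.velocities, dtype=float).ravel()
        if self.coords.size != self.velocities.size:
            raise ValueError("coords and velocities must be conformable")


@dataclass
class ExcitationDirection:
    """A Cartesian direction normalized to the 1 Å-RMSD convention.

    Displacing the coordinates by ``1.0 * vector`` changes them by exactly
    1 Å displacement-RMSD over the Cα atoms (no refit), i.e.
    ||vector|| = sqrt(N_ca). ``source_weights`` are the coefficients over
    the selected modes that produced the direction.
    """

    vector: np.ndarray
    source_weights: np.ndarray

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()
        self.source_weights = np.asarray(self.source_weights, dtype=float)


@dataclass
class ProtocolConfig:
    """Parameters of the MDeNM protocol and the plain-MD comparison arm.

    Defaults mirror the full-scale protocol: 240 excitation directions, 50
    excitations of 2 K per replica with 4 ps relaxations (48 ns of
    excitation-phase time in total), and three 200 ns plain-MD replicas
    (600 ns aggregate). Scaled-down studies override the sizes; the
    schedule arithmetic is independent of scale.
    """

    n_replicas: int = 240
    n_excitations: int = 50
    relaxation_ps: float = 4.0
    delta_T: float = 2.0
    min_pairwise_rmsd: float = 0.3
    dt_ps: float = 0.002
    friction_per_ps: float = 1.0
    bath_temperature: float = 300.0
    seed: int = 0
    md_replicas: int = 3
    md_length_ns: float = 200.0
    md_sample_every_ps: float = 10.0
    sample_every_n_relaxations: int = 2
    equilibration_ps: float = 10.0
    max_direction_attempts: int = 200_000

    def __post_init__(self) -> None:
        for name in (
            "n_replicas", "n_excitations", "relaxation_ps", "delta_T",
            "min_pairwise_rmsd", "dt_ps", "friction_per_ps",
            "bath_temperature", "md_replicas", "md_length_ns",
            "md_sample_every_ps", "sample_every_n_relaxations",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_excitation_time_ns(self) -> float:
        """Aggregate excitation-phase time: replicas x excitations x relax."""
        return self.n_replicas * self.n_excitations * self.relaxation_ps / 1000.0

    @property
    def md_aggregate_time_ns(self) -> float:
        """Aggregate plain-MD time over all replicas."""
        return self.md_replicas * self.md_length_ns


class DirectionBudgetError(RuntimeError):
    def __init__(self, achieved: int, requested: int, attempts: int):
        self.achieved = achieved
        super().__init__(
            f"only {achieved} of {requested} excitation directions satisfied "
            f"the pairwise-RMSD filter within {attempts} attempts; reduce "
            f"n_replicas, lower min_pairwise_rmsd, or select more modes"
        )


def displacement_rmsd(vector: np.ndarray, ca_indices: np.ndarray) -> float:
    """RMSD between coords and coords+vector over the Cα atoms (no refit)."""
    v = np.asarray(vector, dtype=float).reshape(-1, 3)[ca_indices]
    return float(np.sqrt(np.mean(np.sum(v * v, axis=1))))


def _ca_indices(structure: Structure) -> np.ndarray:
    idx = [
        i for i, lab in enumerate(structure.atom_labels) if lab.atom_name == "CA"
    ]
    if not idx:  # non-protein toy systems: use every atom
        idx = list(range(structure.n_atoms))
    return np.asarray(idx, dtype=int)


def generate_directions(
    modes: ModeSet,
    structure: Structure,
    config: ProtocolConfig,
    n: int | None = None,
) -> list[ExcitationDirection]:
    """Draw random mode combinations passing the pairwise-RMSD filter.

    Coefficient vectors are drawn uniformly on the unit sphere in the space
    of the selected modes (so both senses of every combination occur),
    converted to Cartesian displacements and normalized to 1 Å
    displacement-RMSD over the Cα atoms. A candidate is accepted only if
    the structure displaced 1 Å along it lies more than
    ``config.min_pairwise_rmsd`` (RMSD) from the 1 Å-displaced structure of
    every previously accepted direction; with unit-RMSD displacements that
    pairwise RMSD is sqrt(2 - 2 cos theta) for angle theta between the
    directions. Raises :class:`DirectionBudgetError` when the attempt
    budget runs out before ``n`` directions are found.
    """
    if modes.n_modes < 2:
        raise ValueError("need at least 2 selected modes")
    n = config.n_replicas if n is None else n
    rng = np.random.default_rng(config.seed)
    ca = _ca_indices(structure)
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(modes.masses, 3))
    accepted: list[ExcitationDirection] = []
    vecs: list[np.ndarray] = []
    for attempt in range(config.max_direction_attempts):
        w = rng.normal(size=modes.n_modes)
        w /= np.linalg.norm(w)
        u = (modes.eigenvectors @ w) * inv_sqrt_m
        u /= displacement_rmsd(u, ca)
        ok = True
        for v in vecs:
            if displacement_rmsd(u - v, ca) <= config.min_pairwise_rmsd:
                ok = False
                break
        if ok:
            accepted.append(ExcitationDirection(u, w))
            vecs.append(u)
            if len(accepted) == n:
                return accepted
    raise DirectionBudgetError(len(accepted), n, config.max_direction_attempts)


def kinetic_temperature(state: MDState, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature in K (3N degrees of freedom)."""
    m3 = np.repeat(np.asarray(masses, dtype=float), 3)
    ke_akma = 0.5 * float(np.sum(m3 * state.velocities**2))
    n_dof = state.velocities.size
    return 2.0 * ke_akma / (n_dof * KB_KCAL * KCAL_TO_AKMA)


def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Velocity draw in Å/ps at the given temperature."""
    m3 = np.repeat(np.asarray(masses, dtype=float), 3)
    sigma = np.sqrt(KB_KCAL * temperature * KCAL_TO_AKMA / m3)
    return rng.normal(scale=sigma)


def excite(
    state: MDState,
    direction: ExcitationDirection,
    delta_T: float,
    masses: np.ndarray,
) -> MDState:
    """Add a velocity increment along ``direction`` worth exactly ``delta_T``.

    Solves for the scalar lambda > 0 such that the kinetic energy of
    v + lambda*u exceeds that of v by (3N/2) kB dT, i.e. the quadratic
    (1/2 sum m u^2) l^2 + (sum m v.u) l - dKE = 0, and takes the positive
    root (it exists for any dT > 0 and nonzero u, including velocities
    antiparallel to u). The post-kick kinetic temperature equals the
    pre-kick temperature plus delta_T by construction.
    """
    if delta_T <= 0:
        raise ValueError("delta_T must be positive")
    m3 = np.repeat(np.asarray(masses, dtype=float), 3)
    u = direction.vector
    n_dof = state.velocities.size
    d_ke = 0.5 * n_dof * KB_KCAL * delta_T * KCAL_TO_AKMA
    a = 0.5 * float(np.sum(m3 * u * u))
    b = float(np.sum(m3 * state.velocities * u))
    disc = b * b + 4.0 * a * d_ke
    assert disc > 0 and a > 0, "no positive excitation root"
    lam = (-b + math.sqrt(disc)) / (2.0 * a)
    return replace(state, velocities=state.velocities + lam * u)


if _HAVE_NUMBA:

    @numba.njit(cache=False)
    def _baoab_chunk(x, v, pi, pj, kk, rest, inv_m3, dt, c1, noise):
        """Integrate len(noise) BAOAB steps in place; noise is pre-scaled."""
        n = x.size
        n_pairs = pi.size
        f = np.zeros(n)
        for p in range(n_pairs):
            a, b = 3 * pi[p], 3 * pj[p]
            dx, dy, dz = x[a] - x[b], x[a + 1] - x[b + 1], x[a + 2] - x[b + 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            c = -kk[p] * (r - rest[p]) / r
            f[a] += c * dx; f[a + 1] += c * dy; f[a + 2] += c * dz
            f[b] -= c * dx; f[b + 1] -= c * dy; f[b + 2] -= c * dz
        for s in range(noise.shape[0]):
            for d in range(n):
                v[d] += 0.5 * dt * f[d] * inv_m3[d]
                x[d] += 0.5 * dt * v[d]
                v[d] = c1 * v[d] + noise[s, d]
                x[d] += 0.5 * dt * v[d]
                f[d] = 0.0
            for p in range(n_pairs):
                a, b = 3 * pi[p], 3 * pj[p]
                dx, dy, dz = (
                    x[a] - x[b], x[a + 1] - x[b + 1], x[a + 2] - x[b + 2]
                )
                r = math.sqrt(dx * dx + dy * dy + dz * dz)
                c = -kk[p] * (r - rest[p]) / r
                f[a] += c * dx; f[a + 1] += c * dy; f[a + 2] += c * dz
                f[b] -= c * dx; f[b + 1] -= c * dy; f[b + 2] -= c * dz
            for d in range(n):
                v[d] += 0.5 * dt * f[d] * inv_m3[d]


def _baoab_chunk_numpy(x, v, potential, inv_m3, dt, c1, noise):
    f = potential.forces(x)
    for s in range(noise.shape[0]):
        v += 0.5 * dt * f * inv_m3
        x += 0.5 * dt * v
        v *= c1
        v += noise[s]
        x += 0.5 * dt * v
        f = potential.forces(x)
        v += 0.5 * dt * f * inv_m3


#: steps integrated per pre-generated noise block
_CHUNK_STEPS = 2000


def relax(
    state: MDState,
    potential: NetworkPotential,
    masses: np.ndarray,
    duration_ps: float,
    config: ProtocolConfig,
    rng: np.random.Generator,
    sample_every_ps: float | None = None,
) -> tuple[MDState, np.ndarray]:
    """BAOAB Langevin dynamics for ``duration_ps`` at the bath temperature.

    Returns the final state and the frames sampled every
    ``sample_every_ps`` (none when omitted). The noise stream comes from
    ``rng`` in fixed-size blocks, so trajectories are reproducible for a
    given generator state. Raises on non-finite coordinates, which
    indicates a too-large time step.
    """
    dt = config.dt_ps
    n_steps = int(round(duration_ps / dt))
    if abs(n_steps * dt - duration_ps) > 1e-9:
        raise ValueError("dt_ps must divide duration_ps into integer steps")
    m3 = np.repeat(np.asarray(masses, dtype=float), 3)
    inv_m3 = KCAL_TO_AKMA / m3  # force (kcal/mol/Å) -> acceleration (Å/ps²)
    c1 = math.exp(-config.friction_per_ps * dt)
    noise_sigma = np.sqrt(
        (1.0 - c1 * c1) * KB_KCAL * config.bath_temperature * KCAL_TO_AKMA / m3
    )
    sample_stride = (
        None if sample_every_ps is None else max(1, int(round(sample_every_ps / dt)))
    )
    x = state.coords.copy()
    v = state.velocities.copy()
    frames = []
    done = 0
    while done < n_steps:
        take = min(_CHUNK_STEPS, n_steps - done)
        if sample_stride is not None:
            # align chunk ends with sampling points
            take = min(take, sample_stride - done % sample_stride)
        noise = rng.normal(size=(take, x.size)) * noise_sigma
        if _HAVE_NUMBA:
            _baoab_chunk(
                x, v, potential.pairs_i, potential.pairs_j,
                potential.spring_k, potential.rest_lengths,
                inv_m3, dt, c1, noise,
            )
        else:  # pragma: no cover - exercised only without numba
            _baoab_chunk_numpy(x, v, potential, inv_m3, dt, c1, noise)
        done += take
        if sample_stride is not None and done % sample_stride == 0:
            frames.append(x.copy())
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(
            "non-finite coordinates during Langevin relaxation; reduce dt_ps"
        )
    final = MDState(
        x, v, state.time_ps + duration_ps, config.bath_temperature
    )
    return final, (np.array(frames) if frames else np.empty((0, x.size)))


def _equilibrate(
    structure: Structure,
    potential: NetworkPotential,
    config: ProtocolConfig,
    rng: np.random.Generator,
) -> MDState:
    v0 = maxwell_boltzmann_velocities(
        structure.masses, config.bath_temperature, rng
    )
    state = MDState(structure.coords.copy(), v0, 0.0, config.bath_temperature)
    if config.equilibration_ps > 0:
        state, _ = relax(
            state, potential, structure.masses, config.equilibration_ps,
            config, rng,
        )
    return state


def run_mdenm(
    structure: Structure,
    potential: NetworkPotential,
    modes: ModeSet,
    config: ProtocolConfig,
    log: list | None = None,
) -> Ensemble:
    """Full MDeNM protocol: one replica per excitation direction.

    Each replica starts from an equilibrated state, keeps its direction
    fixed, and performs ``n_excitations`` cycles of (2 K kick, relax). A
    frame is recorded after every ``sample_every_n_relaxations``-th
    relaxation phase (every second one by default). ``log``, if given,
    collects (replica, cycle, pre_T, post_T) tuples. Fully deterministic
    given (structure, config.seed).
    """
    directions = generate_directions(modes, structure, config)
    masses = structure.masses
    seeds = np.random.SeedSequence(config.seed).spawn(len(directions))
    all_frames, sources, reps, times = [], [], [], []
    for rep, (direction, ss) in enumerate(zip(directions, seeds)):
        rng = np.random.default_rng(ss)
        state = _equilibrate(structure, potential, config, rng)
        state = replace(state, time_ps=0.0)
        for cycle in range(1, config.n_excitations + 1):
            pre_T = kinetic_temperature(state, masses)
            state = excite(state, direction, config.delta_T, masses)
            if log is not None:
                log.append(
                    (rep, cycle, pre_T, kinetic_temperature(state, masses))
                )
            state, _ = relax(
                state, potential, masses, config.relaxation_ps, config, rng
            )
            if cycle % config.sample_every_n_relaxations == 0:
                all_frames.append(state.coords.copy())
                sources.append("MDeNM")
                reps.append(rep)
                times.append(state.time_ps)
    return Ensemble(
        frames=np.array(all_frames),
        source=sources,
        replica=np.array(reps),
        time_ps=np.array(times),
    )


def run_md(
    structure: Structure,
    potential: NetworkPotential,
    config: ProtocolConfig,
) -> Ensemble:
    """Plain-MD comparison arm: independent seeded Langevin replicas.

    Each of ``md_replicas`` runs for ``md_length_ns`` with
    Maxwell-Boltzmann initial velocities at the bath temperature; frames
    are saved every ``md_sample_every_ps``.
    """
    masses = structure.masses
    seeds = np.random.SeedSequence((config.seed, 1)).spawn(config.md_replicas)
    ensembles = []
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        state = _equilibrate(structure, potential, config, rng)
        state = replace(state, time_ps=0.0)
        _, frames = relax(
            state, potential, masses, config.md_length_ns * 1000.0,
            config, rng, sample_every_ps=config.md_sample_every_ps,
        )
        n = frames.shape[0]
        ensembles.append(
            Ensemble(
                frames=frames,
                source=["MD"] * n,
                replica=np.full(n, rep),
                time_ps=(np.arange(1, n + 1)) * config.md_sample_every_ps,
            )
        )
    return Ensemble.concatenate(ensembles)
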