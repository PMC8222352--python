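"""Elastic-network potential, mass-weighted normal modes and mode selection.

The network is the standard Cα-level harmonic model: every atom pair within
a distance cutoff is joined by a spring whose rest length equals the pair's
separation in the input structure, so the input configuration is an exact
energy minimum. Normal modes are eigenpairs of the mass-weighted Hessian
M^(-1/2) H M^(-1/2); frequencies are reported in sqrt(kcal/mol/amu)/Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import KB_KCAL, Structure

__all__ = [
    "NetworkPotential",
    "ModeSet",
    "build_network",
    "hessian",
    "compute_modes",
    "mode_rmsf_contribution",
    "select_modes",
    "predicted_rmsf",
]

#: Frequency below which a mode is treated as rigid-body (zero) motion.
RIGID_BODY_FREQ_TOL = 1e-6


@dataclass
class NetworkPotential:
    """Pair-spring potential E = sum_p k_p/2 (|r_i - r_j| - L_p)^2."""

    pairs_i: np.ndarray
    pairs_j: np.ndarray
    rest_lengths: np.ndarray
    spring_k: np.ndarray
    cutoff: float
    uniform_k: float

    def __post_init__(self) -> None:
        self.pairs_i = np.asarray(self.pairs_i, dtype=int)
        self.pairs_j = np.asarray(self.pairs_j, dtype=int)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float)
        self.spring_k = np.asarray(self.spring_k, dtype=float)
        if np.any(self.pairs_i >= self.pairs_j):
            raise ValueError("pairs must satisfy i < j")
        if np.any(self.rest_lengths <= 0):
            raise ValueError("rest lengths must be positive")

    @property
    def n_pairs(self) -> int:
        return self.pairs_i.size

    def energy(self, coords: np.ndarray) -> float:
        xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
        d = xyz[self.pairs_i] - xyz[self.pairs_j]
        r = np.linalg.norm(d, axis=1)
        return float(0.5 * np.sum(self.spring_k * (r - self.rest_lengths) ** 2))

    @property
    def _incidence(self) -> "scipy.sparse.csr_matrix":
        """Signed pair-atom incidence matrix, cached for fast force evals."""
        inc = getattr(self, "_incidence_cache", None)
        if inc is None:
            n_atoms = int(self.pairs_j.max()) + 1
            rows = np.repeat(np.arange(self.n_pairs), 2)
            cols = np.column_stack([self.pairs_i, self.pairs_j]).ravel()
            vals = np.tile([1.0, -1.0], self.n_pairs)
            inc = scipy.sparse.csr_matrix(
                (vals, (rows, cols)), shape=(self.n_pairs, n_atoms)
            )
            self._incidence_cache = inc
        return inc

    def forces(self, coords: np.ndarray) -> np.ndarray:
        """Cartesian forces (kcal/mol/Å), flattened to 3N."""
        xyz = np.asarray(coords, dtype=float).reshape(-1, 3)
        inc = self._incidence
        d = inc @ xyz
        r = np.sqrt(np.einsum("ij,ij->i", d, d))
        coef = -self.spring_k * (r - self.rest_lengths) / r
        return (inc.T @ (coef[:, None] * d)).ravel()


def build_network(
    structure: Structure, cutoff: float = 8.0, uniform_k: float = 1.0,
    spring_scale: np.ndarray | None = None,
) -> NetworkPotential:
    """Connect all atom pairs within ``cutoff`` Å by springs at rest.

    ``spring_scale`` optionally gives a per-atom stiffness scale; a pair's
    spring constant is ``uniform_k`` times the smaller of its two atoms'
    scales (used by the synthetic gated receptor to soften its loops).
    Raises if the resulting network is not a single connected component.
    """
    if structure.n_atoms < 2:
        raise ValueError("need at least 2 atoms to build a network")
    xyz = structure.xyz
    tree = cKDTree(xyz)
    pairs = np.array(sorted(tree.query_pairs(cutoff)), dtype=int)
    if pairs.size == 0:
        raise ValueError(
            f"no atom pairs within {cutoff} Å; increase the cutoff"
        )
    i, j = pairs[:, 0], pairs[:, 1]
    rest = np.linalg.norm(xyz[i] - xyz[j], axis=1)
    k = np.full(i.size, float(uniform_k))
    if spring_scale is not None:
        scale = np.asarray(spring_scale, dtype=float)
        k = k * np.minimum(scale[i], scale[j])
    n = structure.n_atoms
    adj = scipy.sparse.coo_matrix(
        (np.ones(i.size), (i, j)), shape=(n, n)
    )
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise ValueError(
            f"network disconnected at cutoff {cutoff} Å "
            f"({n_comp} components); increase the cutoff"
        )
    return NetworkPotential(i, j, rest, k, float(cutoff), float(uniform_k))


def hessian(potential: NetworkPotential, structure: Structure) -> np.ndarray:
    """Analytic 3N x 3N Hessian of the pair-spring energy at rest.

    At the rest configuration each spring contributes the rank-one block
    k * r̂ r̂ᵀ on the (i,i)/(j,j) diagonal and its negative off-diagonal,
    which makes H symmetric positive semidefinite with the six rigid-body
    vectors in its null space.
    """
    xyz = structure.xyz
    n = structure.n_atoms
    h = np.zeros((3 * n, 3 * n))
    d = xyz[potential.pairs_i] - xyz[potential.pairs_j]
    r = np.linalg.norm(d, axis=1)
    units = d / r[:, None]
    blocks = potential.spring_k[:, None, None] * (
        units[:, :, None] * units[:, None, :]
    )
    for b, i, j in zip(blocks, potential.pairs_i, potential.pairs_j):
        sl_i = slice(3 * i, 3 * i + 3)
        sl_j = slice(3 * j, 3 * j + 3)
        h[sl_i, sl_i] += b
        h[sl_j, sl_j] += b
        h[sl_i, sl_j] -= b
        h[sl_j, sl_i] -= b
    return h


@dataclass
class ModeSet:
    """Mass-weighted normal modes.

    ``eigenvectors`` has orthonormal columns in mass-weighted coordinates;
    ``frequencies`` are omega = sqrt(eigenvalue) in sqrt(kcal/mol/amu)/Å,
    ascending within the internal block; rigid-body modes are flagged.
    """

    eigenvectors: np.ndarray
    frequencies: np.ndarray
    rigid_body_flags: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.rigid_body_flags = np.asarray(self.rigid_body_flags, dtype=bool)
        self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def internal(self) -> "ModeSet":
        keep = ~self.rigid_body_flags
        return ModeSet(
            self.eigenvectors[:, keep],
            self.frequencies[keep],
            np.zeros(keep.sum(), dtype=bool),
            self.masses,
        )

    def cartesian_mode(self, m: int) -> np.ndarray:
        """Mode m converted from mass-weighted to Cartesian displacement."""
        inv_sqrt_m = 1.0 / np.sqrt(np.repeat(self.masses, 3))
        return self.eigenvectors[:, m] * inv_sqrt_m

    def subset(self, indices: np.ndarray) -> "ModeSet":
        indices = np.asarray(indices, dtype=int)
        return ModeSet(
            self.eigenvectors[:, indices],
            self.frequencies[indices],
            self.rigid_body_flags[indices],
            self.masses,
        )


def compute_modes(hess: np.ndarray, masses: np.ndarray) -> ModeSet:
    """Solve the mass-weighted eigenproblem of a network Hessian.

    Eigenvalues below -1e-6 indicate the structure is not at a minimum and
    raise; small negative round-off is clamped to zero. Modes with frequency
    below :data:`RIGID_BODY_FREQ_TOL` are flagged as rigid-body motion.
    """
    masses = np.asarray(masses, dtype=float)
    inv_sqrt = 1.0 / np.sqrt(np.repeat(masses, 3))
    mw = hess * inv_sqrt[:, None] * inv_sqrt[None, :]
    mw = 0.5 * (mw + mw.T)
    evals, evecs = scipy.linalg.eigh(mw)
    if np.any(evals < -1e-6):
        raise ValueError(
            f"not at a minimum: eigenvalue {evals.min():.3g} < -1e-6"
        )
    evals = np.clip(evals, 0.0, None)
    freqs = np.sqrt(evals)
    flags = freqs < RIGID_BODY_FREQ_TOL
    return ModeSet(evecs, freqs, flags, masses)


def mode_rmsf_contribution(
    modes: ModeSet, temperature: float = 300.0
) -> np.ndarray:
    """Thermal per-mode, per-atom displacement amplitudes in Å.

    For a harmonic mode of frequency omega, equipartition gives a
    mass-weighted amplitude sqrt(kB T)/omega, so atom i moves by
    sqrt(kB T)/omega * |v_i| / sqrt(m_i). Shape: (n_modes, n_atoms).
    Rigid-body modes must be excluded first (omega = 0 raises).
    """
    if np.any(modes.frequencies < RIGID_BODY_FREQ_TOL):
        raise ValueError("zero-frequency mode passed; exclude rigid-body modes")
    n_atoms = modes.masses.size
    v = modes.eigenvectors.T.reshape(modes.n_modes, n_atoms, 3)
    per_atom_norm = np.linalg.norm(v, axis=2)
    amp = np.sqrt(KB_KCAL * temperature) / modes.frequencies
    return amp[:, None] * per_atom_norm / np.sqrt(modes.masses)[None, :]


def select_modes(
    modes: ModeSet,
    temperature: float = 300.0,
    n: int = 3,
    statistic: str = "max",
) -> ModeSet:
    """Pick the low-frequency modes contributing most to atomic fluctuation.

    Internal modes are restricted to the lowest-frequency quartile (at least
    ``n`` candidates), ranked by their per-atom thermal amplitude reduced by
    ``statistic`` ('max' over atoms by default, 'sum' as the alternative),
    and the top ``n`` are returned sorted by ascending frequency. Ties break
    toward the lower frequency, so the selection is deterministic.
    """
    internal = modes.internal
    if n > internal.n_modes:
        raise ValueError(
            f"requested {n} modes but only {internal.n_modes} internal modes"
        )
    order = np.argsort(internal.frequencies, kind="stable")
    n_candidates = max(n, int(np.ceil(internal.n_modes / 4)))
    candidates = order[:n_candidates]
    contrib = mode_rmsf_contribution(internal.subset(candidates), temperature)
    if statistic == "max":
        score = contrib.max(axis=1)
    elif statistic == "sum":
        score = contrib.sum(axis=1)
    else:
        raise ValueError("statistic must be 'max' or 'sum'")
    # stable sort on -score keeps ascending-frequency order within ties
    picked = candidates[np.argsort(-score, kind="stable")[:n]]
    picked = np.sort(picked)
    return internal.subset(picked)


def predicted_rmsf(modes: ModeSet, temperature: float = 300.0) -> np.ndarray:
    """Equipartition RMSF per atom from all internal modes (Å)."""
    contrib = mode_rmsf_contribution(modes.internal, temperature)
    return np.sqrt(np.sum(contrib**2, axis=0))
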