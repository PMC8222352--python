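"""Synthetic inputs with known ground truth.

The generators emulate the study's three kinds of input at desk scale:

* a "gated receptor" — a Cα-bead cup with three floppy loops (L1 "Lip",
  L2, L3 "Cap") arching over a concave pocket, whose softest normal modes
  swing the loop tips and thereby open/close the two gate distances;
* gate-distance ensembles with a prescribed correlation between d(L1,L2)
  and d(L1,L3);
* docked-pose tables with exactly known competent-pose counts and an
  engineered per-ligand MD-vs-MDeNM best-energy split.

Every generator is deterministic under its seed and returns a
:class:`SyntheticTruth` record with the realized quantities, so any
downstream operation can be scored without re-derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import GateDistanceSeries
from .core import AtomLabel, Ensemble, SelectionSpec, Structure
from .enm import NetworkPotential, build_network

__all__ = [
    "ToyReceptorSpec",
    "SyntheticTruth",
    "make_gated_receptor",
    "make_correlated_distances",
    "make_pose_table",
    "make_arm_split_table",
    "make_split_ensemble",
]

#: Bead mass in amu. Each bead is a coarse dynamical unit, not a residue;
#: the large renormalized mass places the soft gate modes in the
#: overdamped regime at the 1 ps^-1 bath friction (diffusive loop gating,
#: as in solvated proteins) while keeping their thermal amplitudes below
#: ~1 Å. Equilibrium ensembles and all static analyses are
#: mass-independent; only kinetics — which the excitation protocol
#: exercises — depend on it.
_BEAD_MASS = 8000.0

#: Extra softness of the L3 "Cap" relative to the core: its spring scale
#: is gate_softness times this ratio, making the Cap-opening motions the
#: lowest-frequency (and selected) modes of the receptor.
_CAP_SOFTNESS_RATIO = 0.06

#: Softness of the L1 "Lip" hinge: springs crossing the Lip/core boundary
#: are scaled by gate_softness times this ratio while the Lip's internal
#: springs stay core-stiff, so the Lip swings as a nearly rigid flap. Its
#: delocalized swing moves both gate distances together (the source of the
#: positive d(L1,L2)-d(L1,L3) correlation in unbiased sampling) yet has a
#: lower per-atom amplitude than the floppy Cap, so mode selection still
#: picks the Cap trio for excitation.
_LIP_HINGE_RATIO = 0.2


@dataclass
class ToyReceptorSpec:
    """Parameters of the toy gated receptor.

    ``gate_softness`` scales the spring constants of every pair touching a
    loop bead (1.0 = as stiff as the core); the L3 "Cap" loop is softened
    by a further fixed ratio so that the softest internal modes open and
    close the d(L1,L3) gate, mirroring the Cap-gating of the enzyme the
    toy stands in for.
    """

    n_core: int = 450
    loop_lengths: tuple[int, int, int] = (5, 5, 5)
    gate_softness: float = 1.0
    seed: int = 0
    radius: float = 9.0
    cutoff: float = 6.0
    uniform_k: float = 25.0
    jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.n_core < 12:
            raise ValueError("n_core must be at least 12")
        if any(l < 3 for l in self.loop_lengths):
            raise ValueError("each loop needs at least 3 beads")
        if not 0 < self.gate_softness <= 1:
            raise ValueError("gate_softness must be in (0, 1]")


@dataclass
class SyntheticTruth:
    """Ground-truth record shipped with every generated dataset."""

    parameters: dict
    realized: dict = field(default_factory=dict)


def _cup_points(n: int, radius: float, open_polar: float) -> np.ndarray:
    """Roughly even points on the sphere below the polar angle ``open_polar``
    (golden-spiral construction), leaving an opening around +z."""
    cos_open = np.cos(open_polar)
    k = np.arange(n)
    # z spans the cup portion of the sphere only
    z = cos_open - (cos_open + 1.0) * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(1.0 - z * z)
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _core_shell(n: int, radius: float, open_polar: float) -> np.ndarray:
    """Two concentric cups plus radial cross-links' geometry.

    A single thin bead shell has soft bending modes that would hybridize
    with the gate loops; a sandwich of two layers ~3 Å apart is rigid
    against bending, leaving the loops as the only soft elements.
    """
    r_in = radius - 3.0
    frac_out = radius**2 / (radius**2 + r_in**2)
    n_out = int(round(n * frac_out))
    outer = _cup_points(n_out, radius, open_polar)
    inner = _cup_points(n - n_out, r_in, open_polar)
    return np.vstack([outer, inner])


def _loop_beads(
    azimuth: float, radius: float, open_polar: float, n_beads: int
) -> np.ndarray:
    """Arch of beads spanning the cup rim, leaning in over the pocket.

    Each loop is anchored near two rim points (so its transverse motion is
    braced, avoiding free-cantilever modes) and its apex — the loop tip —
    leans inward and upward over the opening. The middle bead is the tip.
    The span widens with loop length so the bead spacing stays near 3 Å
    (closely spaced beads in a soft loop would put transverse fluctuations
    in the anharmonic regime of the pair springs).
    """
    rim_rho = radius * np.sin(open_polar)
    rim_z = radius * np.cos(open_polar)
    half_span = np.deg2rad(40.0) * max(1.0, (n_beads - 1) / 4.0) ** 0.9
    apex_rho, apex_z = 0.74 * rim_rho, rim_z + 0.35 * radius
    t = np.linspace(0.0, 1.0, n_beads)
    bump = np.sin(np.pi * t)  # 0 at anchors, 1 at the apex
    az = azimuth + half_span * (2.0 * t - 1.0)
    rho = rim_rho + (apex_rho - rim_rho) * bump
    zz = rim_z + (apex_z - rim_z) * bump
    return np.column_stack([rho * np.cos(az), rho * np.sin(az), zz])


def make_gated_receptor(
    spec: ToyReceptorSpec | None = None,
) -> tuple[Structure, SelectionSpec, NetworkPotential]:
    """Build the toy gated receptor and its elastic network.

    The core is a rigid two-layer spherical cup (opening at +z) of
    ``n_core`` beads; three loops arch over the pocket from the rim at
    azimuths 90°/210°/330°, their apex beads serving as the gate tips,
    and the pocket selection is the cup lining below the equator. L2
    springs are scaled by ``gate_softness``; the L3 "Cap" is softened by
    a further fixed ratio so that the softest (selected) modes open and
    close d(L1,L3); the L1 "Lip" is a stiff flap on a soft hinge whose
    delocalized swing couples the two gate distances in unbiased
    sampling. Deterministic per seed (a small seeded jitter breaks the
    construction's symmetries).
    """
    spec = spec or ToyReceptorSpec()
    open_polar = np.deg2rad(55.0)
    core = _core_shell(spec.n_core, spec.radius, open_polar)
    rng = np.random.default_rng(spec.seed)

    coords_list = [core]
    loop_of_bead = [0] * spec.n_core  # 0 = core, 1..3 = loop id
    azimuths = np.deg2rad([90.0, 210.0, 330.0])
    for loop_id, (az, n_beads) in enumerate(
        zip(azimuths, spec.loop_lengths), start=1
    ):
        beads = _loop_beads(az, spec.radius, open_polar, n_beads)
        coords_list.append(beads)
        loop_of_bead += [loop_id] * n_beads
    xyz = np.vstack(coords_list)
    xyz = xyz + rng.normal(scale=spec.jitter, size=xyz.shape)
    loop_of_bead = np.array(loop_of_bead)

    labels = []
    for i, loop in enumerate(loop_of_bead):
        resname = "COR" if loop == 0 else f"LP{loop}"
        labels.append(AtomLabel(i + 1, resname, "CA"))
    n = len(labels)
    structure = Structure(
        labels, xyz.ravel(), np.full(n, _BEAD_MASS), ["C"] * n
    )

    spring_scale = np.ones(n)
    spring_scale[loop_of_bead == 2] = spec.gate_softness
    spring_scale[loop_of_bead == 3] = spec.gate_softness * _CAP_SOFTNESS_RATIO
    potential = build_network(
        structure, spec.cutoff, spec.uniform_k, spring_scale=spring_scale
    )
    # L1 "Lip": stiff flap on a soft hinge — soften only the springs that
    # cross the Lip/core boundary
    hinge_pairs = (loop_of_bead[potential.pairs_i] == 1) ^ (
        loop_of_bead[potential.pairs_j] == 1
    )
    potential.spring_k[hinge_pairs] *= spec.gate_softness * _LIP_HINGE_RATIO

    tips = {}
    for loop_id, loop_name in ((1, "L1"), (2, "L2"), (3, "L3")):
        beads = np.where(loop_of_bead == loop_id)[0]
        tip_bead = int(beads[beads.size // 2])  # the apex of the arch
        tips[loop_name] = (tip_bead + 1, "CA")
    pocket_beads = np.where((loop_of_bead == 0) & (xyz[:, 2] < -0.3 * spec.radius))[0]
    selection = SelectionSpec(
        pocket=[(int(i) + 1, "CA") for i in pocket_beads],
        tips=tips,
    )
    return structure, selection, potential


def make_correlated_distances(
    n: int,
    rho: float,
    means: tuple[float, float] = (8.0, 9.0),
    sds: tuple[float, float] = (0.8, 0.8),
    seed: int = 0,
) -> tuple[GateDistanceSeries, SyntheticTruth]:
    """Bivariate-normal gate distances with prescribed correlation.

    Draws are redrawn while non-positive (truncation at 0, immaterial for
    realistic means); the truth records the realized sample correlation
    and moments after truncation.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    if min(sds) <= 0:
        raise ValueError("sds must be positive")
    rng = np.random.default_rng(seed)
    cov = np.array(
        [
            [sds[0] ** 2, rho * sds[0] * sds[1]],
            [rho * sds[0] * sds[1], sds[1] ** 2],
        ]
    )
    draws = rng.multivariate_normal(means, cov, size=n, method="svd")
    bad = np.any(draws <= 0, axis=1)
    while bad.any():
        draws[bad] = rng.multivariate_normal(
            means, cov, size=int(bad.sum()), method="svd"
        )
        bad = np.any(draws <= 0, axis=1)
    series = GateDistanceSeries(draws[:, 0], draws[:, 1])
    realized_r = float(np.corrcoef(draws[:, 0], draws[:, 1])[0, 1])
    truth = SyntheticTruth(
        parameters={"n": n, "rho": rho, "means": means, "sds": sds, "seed": seed},
        realized={
            "correlation": realized_r,
            "means": draws.mean(axis=0).tolist(),
            "sds": draws.std(axis=0).tolist(),
        },
    )
    return series, truth


def make_pose_table(
    n_ligands: int = 5,
    n_conformations: int = 4,
    competent_fraction: float = 0.5,
    be_range: tuple[float, float] = (-12.0, -2.0),
    seed: int = 0,
    arm: str = "MD",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Pose table with an exactly known number of distance-competent poses.

    Exactly ``round(fraction * n_poses)`` poses get an acceptor-sulfate
    distance below 5 Å (drawn in [2.5, 4.5]); the rest land in [5.5, 9].
    Binding energies are uniform in ``be_range``. The truth records the
    pass counts for every filter combination at the default thresholds.
    """
    if not 0.0 <= competent_fraction <= 1.0:
        raise ValueError("competent_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_poses = n_ligands * n_conformations
    n_close = int(round(competent_fraction * n_poses))
    dists = np.concatenate(
        [
            rng.uniform(2.5, 4.5, size=n_close),
            rng.uniform(5.5, 9.0, size=n_poses - n_close),
        ]
    )
    rng.shuffle(dists)
    be = rng.uniform(be_range[0], be_range[1], size=n_poses)
    sulfate = np.array([0.0, 0.0, 0.0])
    direction = rng.normal(size=(n_poses, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    acceptor = sulfate + dists[:, None] * direction
    ligs = np.repeat([f"lig{i:03d}" for i in range(n_ligands)], n_conformations)
    confs = np.tile([f"conf{i:03d}" for i in range(n_conformations)], n_ligands)
    df = pd.DataFrame(
        {
            "ligand_id": ligs,
            "conformation_id": confs,
            "arm": arm,
            "binding_energy": be,
            "acceptor_kind": rng.choice(["O", "N"], size=n_poses),
            "ax": acceptor[:, 0],
            "ay": acceptor[:, 1],
            "az": acceptor[:, 2],
            "sx": sulfate[0],
            "sy": sulfate[1],
            "sz": sulfate[2],
        }
    )
    pass_dist = dists < 5.0
    pass_be = be < -5.0
    truth = SyntheticTruth(
        parameters={
            "n_ligands": n_ligands,
            "n_conformations": n_conformations,
            "competent_fraction": competent_fraction,
            "be_range": be_range,
            "seed": seed,
        },
        realized={
            "n_poses": n_poses,
            "n_pass_distance": int(pass_dist.sum()),
            "n_pass_be": int(pass_be.sum()),
            "n_pass_both": int((pass_dist & pass_be).sum()),
        },
    )
    return df, truth


def make_arm_split_table(
    n_exceeding: int = 21,
    n_favor_mdenm: int = 17,
    n_below: int = 10,
    threshold: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Pose table engineered to a known MD-vs-MDeNM best-energy split.

    ``n_exceeding`` ligands get |ΔBE| = |bestBE_MD - bestBE_MDeNM| above
    ``threshold``, of which ``n_favor_mdenm`` favor the MDeNM arm
    (ΔBE > 0); ``n_below`` further ligands stay within the threshold.
    All poses are made distance- and energy-competent so filters keep them.
    """
    if n_favor_mdenm > n_exceeding:
        raise ValueError("n_favor_mdenm cannot exceed n_exceeding")
    rng = np.random.default_rng(seed)
    rows = []
    n_total = n_exceeding + n_below
    base = rng.uniform(-10.0, -7.0, size=n_total)
    for i in range(n_total):
        lig = f"lig{i:03d}"
        if i < n_favor_mdenm:
            delta = rng.uniform(threshold + 0.1, threshold + 2.0)
        elif i < n_exceeding:
            delta = -rng.uniform(threshold + 0.1, threshold + 2.0)
        else:
            delta = rng.uniform(-0.9 * threshold, 0.9 * threshold)
        be_mdenm = base[i] - max(delta, 0.0)
        be_md = base[i] + min(delta, 0.0)
        # bestBE_MD - bestBE_MDeNM = delta by construction
        for arm, be in (("MD", be_md), ("MDeNM", be_mdenm)):
            rows.append(
                {
                    "ligand_id": lig,
                    "conformation_id": f"{arm}-conf000",
                    "arm": arm,
                    "binding_energy": be,
                    "acceptor_kind": "O",
                    "ax": 3.0, "ay": 0.0, "az": 0.0,
                    "sx": 0.0, "sy": 0.0, "sz": 0.0,
                }
            )
    df = pd.DataFrame(rows)
    truth = SyntheticTruth(
        parameters={
            "n_exceeding": n_exceeding,
            "n_favor_mdenm": n_favor_mdenm,
            "n_below": n_below,
            "threshold": threshold,
            "seed": seed,
        },
        realized={
            "n_ligands": n_total,
            "n_exceeding": n_exceeding,
            "favor_mdenm": n_favor_mdenm,
            "favor_md": n_exceeding - n_favor_mdenm,
        },
    )
    return df, truth


def make_split_ensemble(
    n: int = 100,
    split: float = 0.85,
    separation: float = 5.0,
    spread: float = 0.2,
    seed: int = 0,
    n_atoms: int = 20,
) -> tuple[Ensemble, SyntheticTruth]:
    """Two-blob conformational ensemble with a known cluster split.

    ``round(split * n)`` frames jitter (isotropic Gaussian, ``spread`` Å
    per coordinate) about a reference conformation; the rest jitter about
    a copy displaced by ``separation`` Å RMSD. Requires
    ``separation > 2 * spread`` so QT at a diameter between the blob
    diameter and the separation must recover the split exactly.
    """
    if not 0.0 <= split <= 1.0:
        raise ValueError("split must be in [0, 1]")
    if separation <= 2 * spread:
        raise ValueError("separation must exceed 2 x spread")
    rng = np.random.default_rng(seed)
    base = rng.uniform(-10.0, 10.0, size=3 * n_atoms)
    # displacement normalized so the second blob sits at `separation` Å RMSD
    shift_dir = rng.normal(size=3 * n_atoms)
    shift_dir /= np.sqrt(np.sum(shift_dir**2) / n_atoms)
    other = base + separation * shift_dir
    n_a = int(round(split * n))
    frames = np.empty((n, 3 * n_atoms))
    frames[:n_a] = base + rng.normal(scale=spread, size=(n_a, 3 * n_atoms))
    frames[n_a:] = other + rng.normal(scale=spread, size=(n - n_a, 3 * n_atoms))
    truth = SyntheticTruth(
        parameters={
            "n": n, "split": split, "separation": separation,
            "spread": spread, "seed": seed, "n_atoms": n_atoms,
        },
        realized={"n_major": n_a, "n_minor": n - n_a, "split": n_a / n},
    )
    return Ensemble(frames=frames), truth
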