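# Methods

This note documents the models, numerical choices and design decisions
behind `mdenm`. The package implements, at desk scale, a complete
normal-mode-excited sampling pipeline for gated receptors — elastic-network
normal modes, the MDeNM excitation protocol with a plain-MD baseline,
ensemble analytics (RMSD/RMSF, gate distances, free-energy landscapes, QT
clustering, pseudo-uniform selection) and ensemble-docking post-processing —
together with synthetic generators that provide every input with known
ground truth.

## Unit system

Lengths are in Å, energies in kcal/mol, masses in amu and time in ps, with
`KB_KCAL = 0.0019872041` kcal/(mol·K) and the single conversion constant
`KCAL_TO_AKMA = 418.4` amu·Å²/ps² per kcal/mol linking kinetic and
potential energy. Velocities are Å/ps.

## Elastic-network surrogate

The sampling engine runs on a harmonic pair-spring network: every atom
pair within a cutoff (default 8 Å at the Cα level) is joined by a spring
with rest length equal to its separation in the input structure, so the
input is an exact energy minimum and no minimizer is needed. The default
uniform spring constant is 1 kcal/mol/Å²; callers may supply per-atom
stiffness scales (the toy receptor uses them to soften its loops). Normal
modes are eigenpairs of the mass-weighted Hessian `M^(-1/2) H M^(-1/2)`
(dense `scipy.linalg.eigh`); modes with frequency below 1e-6 are flagged
as rigid-body motion, and exactly six such modes exist for any
non-collinear 3-D network. Frequencies are reported in
sqrt(kcal/mol/amu)/Å; multiplying by sqrt(418.4) ≈ 20.45 converts to
ps⁻¹.

Mode selection follows the protocol's phrase "low-frequency modes
contributing the most to the highest RMSF": internal modes are restricted
to the lowest-frequency quartile (never fewer than the requested count),
ranked by their maximum per-atom thermal amplitude
`sqrt(kB T)/omega × |v_i|/sqrt(m_i)` (equipartition of a harmonic mode),
and the top `n` (default 3) are returned. Ties break toward the lower
frequency, making selection deterministic. The reduction over atoms
("max") is exposed as a config switch (`statistic="sum"` is the
alternative) because the source phrasing does not pin it down; "max"
couples the selection directly to the most mobile site, which is the
gate in every system this package targets.

## Langevin dynamics

`relax` integrates Langevin dynamics with the BAOAB splitting at the bath
temperature (default 300 K) and friction 1 ps⁻¹. The default time step is
0.002 ps; for the heavy-bead toy receptor (below) the analyses use 0.01 ps,
which keeps `omega_max * dt < 0.05` — far inside the accuracy regime —
at a fifth of the cost. The noise stream is drawn from a
`numpy.random.Generator` in fixed-size blocks, so every trajectory is
bit-reproducible given (structure, config, seed). The inner loop is
compiled with numba; a pure-numpy fallback implements the identical
update. Kinetic temperature uses all 3N degrees of freedom (the surrogate
has no constraints).

## The MDeNM protocol

Excitation directions are random linear combinations of the selected
modes: coefficient vectors drawn uniformly on the unit sphere (both senses
of every combination occur), converted to Cartesian displacements and
normalized so that displacing the structure by the vector produces exactly
1 Å displacement-RMSD over the Cα atoms. The normalization and the
pairwise filter use the displacement-space RMSD (no refit), under which
two unit-RMSD displacements at angle theta sit `sqrt(2 - 2 cos theta)`
apart — the closed form the tests check. A candidate direction is accepted
only if its 1 Å-displaced structure lies more than 0.3 Å RMSD from that of
every previously accepted direction (greedy accept, deterministic under
the seed); exhausting the attempt budget raises an error reporting the
achievable count. In a 3-mode space the sphere can hold only on the order
of a hundred directions at the 0.3 Å spacing, so the full-scale target of
240 directions presumes more selected modes or a higher-dimensional
combination space; the scaled studies here use up to ~50.

Each replica keeps its direction fixed for all excitation cycles. A cycle
adds a velocity increment `lambda * u` with `lambda > 0` solving the
quadratic that raises the kinetic energy by exactly `(3N/2) kB dT`
(default dT = 2 K) — the positive root exists for any dT > 0, including
velocities antiparallel to the direction — and then relaxes for 4 ps.
Frames are recorded after every second relaxation. The full-scale
schedule (240 replicas × 50 excitations × 4 ps = 48 ns of
excitation-phase time, against 3 × 200 ns = 600 ns of plain MD) is pure
configuration arithmetic and is reported by `ProtocolConfig` properties;
scaled studies change the sizes, not the logic. The plain-MD arm draws
Maxwell-Boltzmann velocities at the bath temperature and saves frames
every 10 ps by default.

## Ensemble analytics

Gate distances d(L1,L2) and d(L1,L3) are Euclidean tip-tip distances
(internal coordinates; no superposition). The free-energy landscape is
the Boltzmann inversion `dG = -kB T ln(P/Pmax)` of their 2-D histogram,
with a default bin width of 0.25 Å (not stated by the protocol;
exposed as a parameter), the most populated bin as the zero of free
energy, and unsampled bins carried as NaN sentinels rather than a large
finite value. Renormalizing `exp(-dG/kBT)` over occupied bins reproduces
the empirical bin probabilities exactly, which the tests assert.

QT clustering uses the classic greedy variant: for every unassigned seed
frame a candidate cluster grows by repeatedly adding the frame that keeps
the candidate diameter smallest while staying within the threshold
(default 1.1 Å); the largest candidate is committed (ties to the lowest
seed id) and the process repeats. The metric is superposed RMSD over a
caller-supplied selection — the binding pocket in the pipeline — with
superposition on that same selection. Published QT implementations differ
in candidate construction; correctness here is defined by an independent
transparent re-implementation that the tests compare against on 200 random
small ensembles. Centroids minimize the summed RMSD to co-members.
Pseudo-uniform selection is a deterministic greedy sweep in frame order
keeping frames at least `spacing` (default 1.1 Å) from every kept frame.

## Docking post-processing

Pose tables carry per-pose ligand and receptor-conformation ids, the
sampling arm, the docking score (kcal/mol) and the coordinates of the
ligand acceptor atom and co-factor sulfate sulfur. Catalytic competence
uses strict inequalities — acceptor-sulfate distance < 5 Å and, when
energy filtering is on, score < -5 kcal/mol — matching the "less
than"/"lower than" wording of the criteria; substrate stability over a
trajectory instead uses "within", i.e. distance <= 5 Å, and calls a run
stable when at least 90% of frames qualify (the required fraction is not
stated by the source protocol and is exposed as config). The ΔBE sign
convention is `bestBE_MD - bestBE_MDeNM`, positive meaning the MDeNM arm
found the more favorable energy. Predicted affinities average the best
per-conformation scores over the 10 best conformations (fewer are
averaged, flagged, when fewer exist); agreement with experimental
affinities is reported as squared Pearson R².

## The toy gated receptor

The synthetic receptor emulates a three-loop gated enzyme pocket with
known ground truth. Its core is a sandwich of two concentric spherical
cups (default outer radius 9 Å, 450 beads, opening at +z): a single thin
bead shell would have soft bending modes that hybridize with the gate,
whereas the double layer is rigid, leaving the loops as the only soft
elements. Three five-bead arches span the rim at azimuths 90°/210°/330°,
each anchored near two rim points with its apex — the loop tip — leaning
over the pocket; the pocket selection is the cup lining below the
equator. The three loops play distinct mechanical roles:

* **L3, the "Cap"**, carries springs at 0.06 × the core constant
  (further scaled by `gate_softness`), so the three lowest-frequency
  internal modes are ~99% Cap motion and change d(L1,L3) strongly while
  leaving d(L1,L2) nearly untouched. At `gate_softness = 0.1` a 1 Å-RMSD
  displacement along at least one selected mode moves d(L1,L3) by well
  over 0.5 Å — part of the generator's tested contract.
* **L1, the "Lip"**, is a stiff flap on a soft hinge: its internal
  springs are core-stiff but the springs crossing the Lip/core boundary
  are scaled by 0.2 (× `gate_softness`). Its delocalized swing moves the
  Lip tip relative to both other tips at once, which is what gives
  unbiased sampling its positive d(L1,L2)-d(L1,L3) correlation; because
  the swing is spread over the whole flap, its per-atom amplitude stays
  below the floppy Cap's and mode selection does not pick it.
* **L2** carries `gate_softness` uniformly and mostly anchors d(L1,L2).

Beads carry a mass of 8000 amu. They are coarse dynamical units, not
residues: with the protocol's 1 ps⁻¹ friction, this renormalized mass
places the Cap modes in the overdamped/critically damped regime
(relaxation times of tens of ps, like diffusive loop gating in solvated
proteins) while keeping their thermal amplitudes near 1 Å, where the
harmonic mode picture remains accurate. Equilibrium ensembles are
mass-independent; mass only sets kinetics, which is precisely what the
excitation protocol exercises. Under these conditions repeated 2 K kicks
along a fixed direction accumulate displacement between relaxations,
so the MDeNM arm systematically widens the sampled d(L1,L3) range and,
because the pumped variance is Cap-specific, lowers the d(L1,L2)-d(L1,L3)
correlation relative to equal-wall-time plain MD — the qualitative
contrast the full-scale study reports. At desk scale the kick energy
`(3N/2) kB * 2 K` is only of order kBT (it grows with system size), so
the contrast is an ordering, not the large separation seen at full scale.

What the toy does not emulate: real protein anharmonicity (multiple
basins, barrier crossings), side-chain chemistry, solvent structure, and
any sequence-specific energetics. Passing tests therefore demonstrate the
correctness of the protocol logic, the estimators and the analytics —
not force-field realism.

Other generators: correlated gate-distance series are bivariate normal
draws (redrawn while non-positive) with the realized sample correlation
recorded; pose tables place an exact count of acceptor-sulfate distances
below 5 Å (drawn in [2.5, 4.5] vs [5.5, 9]) with uniform scores, and an
"arm-split" variant engineers a chosen number of ligands whose best-score
difference exceeds a threshold in favor of either arm; two-blob ensembles
jitter frames around two conformations separated by a prescribed RMSD so
QT must recover the split exactly.

## Problem sizes used in the validation studies

The shipped studies are scaled down from the full protocol: direction
filters are exercised with up to 50 directions; the excitation contract
with 100 random states; the headline MDeNM-vs-MD comparison with 20
replicas × 10 excitations × 4 ps against the same total time of plain MD
(two 0.4 ns replicas) on the default toy receptor; equipartition checks
run a few ns of Langevin dynamics. These sizes keep every study within a
few minutes on one CPU while leaving the protocol arithmetic — which is
what the full-scale totals (48 ns, 600 ns) test — exact at any scale.

## Known limitations

* The harmonic network cannot ratchet into new basins; MDeNM gains appear
  as variance inflation along the excited modes rather than discovery of
  genuinely new conformers.
* The pairwise-RMSD direction filter becomes infeasible near ~100
  directions in a 3-mode space (sphere packing); the full 240-direction
  protocol needs a larger mode set.
* QT clustering is O(n²)–O(n³) in frames; intended for the few hundred
  representatives of a scaled study, not raw trajectories.
* Pearson correlation of gate distances is estimated from autocorrelated
  samples; with slow gate modes its sampling error at scaled run lengths
  is of order ±0.1, which is why the MDeNM-vs-MD contrast is asserted as
  an ordering under a fixed seed.
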