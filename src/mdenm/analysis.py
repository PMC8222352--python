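"""Gate-distance analytics, free-energy landscapes, QT clustering and
pseudo-uniform conformation selection.

The two monitored "gate" distances are the loop-tip separations
d(L1,L2) and d(L1,L3); they are internal coordinates and need no
superposition. The free-energy landscape is the Boltzmann inversion of
their 2-D histogram, dG = -kB T ln(P/Pmax), with the most populated bin
as the zero reference and unsampled bins reported as NaN sentinels.

Clustering uses the quality-threshold (QT) algorithm: for every unassigned
frame a candidate cluster is grown greedily (always adding the frame that
keeps the candidate diameter smallest while staying within the threshold),
the largest candidate is committed, and the procedure repeats on the
remainder. The metric is pairwise RMSD over a caller-supplied selection,
with superposition on that same selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import KB_KCAL, Ensemble, SelectionSpec, Structure, rmsd

__all__ = [
    "GateDistanceSeries",
    "FELGrid",
    "Cluster",
    "ClusterSet",
    "gate_distances",
    "distance_correlation",
    "fel",
    "pairwise_rmsd_matrix",
    "qt_cluster",
    "coverage_fraction",
    "pseudo_uniform_select",
]


@dataclass
class GateDistanceSeries:
    """Per-frame gate distances d(L1,L2) and d(L1,L3) in Å."""

    d12: np.ndarray
    d13: np.ndarray
    frame_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d12 = np.asarray(self.d12, dtype=float).ravel()
        self.d13 = np.asarray(self.d13, dtype=float).ravel()
        if self.d12.size != self.d13.size:
            raise ValueError("d12 and d13 must have equal length")
        if np.any(self.d12 <= 0) or np.any(self.d13 <= 0):
            raise ValueError("gate distances must be positive")
        if self.frame_ids is None:
            self.frame_ids = np.arange(self.d12.size)
        self.frame_ids = np.asarray(self.frame_ids)

    @property
    def n_frames(self) -> int:
        return self.d12.size


def gate_distances(
    ensemble: Ensemble, selection: SelectionSpec, structure: Structure
) -> GateDistanceSeries:
    """Euclidean tip-tip distances per frame (no superposition)."""
    tips = selection.tip_indices(structure)
    xyz = ensemble.frames.reshape(ensemble.n_frames, -1, 3)
    p1 = xyz[:, tips["L1"]]
    d12 = np.linalg.norm(p1 - xyz[:, tips["L2"]], axis=1)
    d13 = np.linalg.norm(p1 - xyz[:, tips["L3"]], axis=1)
    return GateDistanceSeries(d12, d13)


def distance_correlation(series: GateDistanceSeries) -> float:
    """Sample Pearson correlation between the two gate distances."""
    if series.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation")
    if np.std(series.d12) == 0 or np.std(series.d13) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, _ = stats.pearsonr(series.d12, series.d13)
    return float(r)


@dataclass
class FELGrid:
    """Free-energy landscape over the (d12, d13) plane.

    ``delta_G`` is in kcal/mol with 0 at the most populated bin; bins with
    no samples hold NaN (an explicit "unsampled" sentinel, not 0).
    """

    bin_edges_x: np.ndarray
    bin_edges_y: np.ndarray
    counts: np.ndarray
    delta_G: np.ndarray
    temperature: float

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


def fel(
    series: GateDistanceSeries,
    bin_width: float = 0.25,
    temperature: float = 300.0,
) -> FELGrid:
    """Boltzmann inversion of the 2-D gate-distance histogram.

    dG(bin) = -kB T ln(count / max count); the most populated bin is the
    zero of free energy and unsampled bins are NaN.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if series.n_frames < 1:
        raise ValueError("need at least one frame")

    def edges(v: np.ndarray) -> np.ndarray:
        lo = np.floor(v.min() / bin_width) * bin_width
        n = max(1, int(np.ceil((v.max() - lo) / bin_width + 1e-12)))
        return lo + bin_width * np.arange(n + 1)

    ex, ey = edges(series.d12), edges(series.d13)
    counts, _, _ = np.histogram2d(series.d12, series.d13, bins=(ex, ey))
    counts = counts.astype(int)
    dg = np.full(counts.shape, np.nan)
    occ = counts > 0
    dg[occ] = -KB_KCAL * temperature * np.log(counts[occ] / counts.max())
    return FELGrid(ex, ey, counts, dg, float(temperature))


# ---------------------------------------------------------------------------
# Pairwise-RMSD metric and QT clustering
# ---------------------------------------------------------------------------

def pairwise_rmsd_matrix(
    frames: np.ndarray, selection: np.ndarray
) -> np.ndarray:
    """All-pairs superposed RMSD over ``selection`` (batched Kabsch)."""
    sel = np.asarray(selection, dtype=int)
    n = frames.shape[0]
    pts = frames.reshape(n, -1, 3)[:, sel, :]
    pts = pts - pts.mean(axis=1, keepdims=True)
    sq = np.sum(pts * pts, axis=(1, 2))
    out = np.zeros((n, n))
    for i in range(n):
        # correlation matrices of frame i against frames i+1..n-1
        h = np.einsum("ka,nkb->nab", pts[i], pts[i + 1 :])
        u, s, vt = np.linalg.svd(h)
        det = np.linalg.det(u @ vt)
        s[:, -1] *= np.sign(det)  # proper rotations only
        e = sq[i] + sq[i + 1 :] - 2.0 * s.sum(axis=1)
        out[i, i + 1 :] = out[i + 1 :, i] = np.sqrt(
            np.clip(e, 0.0, None) / sel.size
        )
    return out


@dataclass
class Cluster:
    members: np.ndarray
    centroid: int
    diameter: float


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    max_diameter: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> np.ndarray:
        return np.array([c.members.size for c in self.clusters])


def _grow_candidate(
    seed: int, available: np.ndarray, dist: np.ndarray, max_diameter: float
) -> np.ndarray:
    """Greedy QT candidate: repeatedly add the frame that keeps the
    candidate's diameter smallest while within the threshold; ties break
    toward the lowest frame id."""
    members = [seed]
    rest = [f for f in available if f != seed]
    diam = 0.0
    while rest:
        best_f, best_d = None, None
        for f in rest:
            d = max(diam, max(dist[f, m] for m in members))
            if d <= max_diameter and (best_d is None or d < best_d):
                best_f, best_d = f, d
        if best_f is None:
            break
        members.append(best_f)
        rest.remove(best_f)
        diam = best_d
    return np.array(sorted(members), dtype=int)


def qt_cluster(
    ensemble_or_frames: Ensemble | np.ndarray,
    selection: np.ndarray,
    max_diameter: float = 1.1,
) -> ClusterSet:
    """Quality-threshold clustering of an ensemble.

    Classic QT: grow one greedy candidate per unassigned seed frame,
    commit the largest candidate (ties: lowest seed id), remove its
    members, repeat. Clusters are returned sorted by size descending;
    each centroid is the member minimizing its summed RMSD to co-members.
    """
    frames = (
        ensemble_or_frames.frames
        if isinstance(ensemble_or_frames, Ensemble)
        else np.atleast_2d(ensemble_or_frames)
    )
    n = frames.shape[0]
    if n == 0:
        return ClusterSet([], max_diameter)
    dist = pairwise_rmsd_matrix(frames, selection)
    unassigned = list(range(n))
    clusters: list[Cluster] = []
    while unassigned:
        avail = np.array(unassigned)
        best = None
        for seed in unassigned:  # ascending ids: first largest wins ties
            cand = _grow_candidate(seed, avail, dist, max_diameter)
            if best is None or cand.size > best.size:
                best = cand
        sub = dist[np.ix_(best, best)]
        centroid = int(best[np.argmin(sub.sum(axis=1))])
        clusters.append(Cluster(best, centroid, float(sub.max())))
        unassigned = [f for f in unassigned if f not in set(best.tolist())]
    clusters.sort(key=lambda c: (-c.members.size, c.members[0]))
    return ClusterSet(clusters, max_diameter)


def coverage_fraction(
    clusters: ClusterSet, top_k: int, total_frames: int
) -> float:
    """Fraction of all frames inside the top_k most populated clusters."""
    if top_k > clusters.n_clusters:
        raise ValueError("top_k exceeds the number of clusters")
    sizes = np.sort(clusters.sizes())[::-1]
    return float(sizes[:top_k].sum() / total_frames)


def pseudo_uniform_select(
    ensemble_or_frames: Ensemble | np.ndarray,
    selection: np.ndarray,
    spacing: float = 1.1,
) -> np.ndarray:
    """Greedy sweep keeping frames pairwise >= ``spacing`` apart in RMSD.

    Frames are visited in order; a frame is kept iff its superposed RMSD
    over ``selection`` to every already-kept frame is at least ``spacing``.
    Deterministic; the first frame is always kept.
    """
    frames = (
        ensemble_or_frames.frames
        if isinstance(ensemble_or_frames, Ensemble)
        else np.atleast_2d(ensemble_or_frames)
    )
    kept: list[int] = []
    for k in range(frames.shape[0]):
        if all(
            rmsd(frames[k], frames[j], selection) >= spacing for j in kept
        ):
            kept.append(k)
    return np.array(kept, dtype=int)
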