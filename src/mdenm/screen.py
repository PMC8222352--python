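"""Post-processing of ensemble-docking pose tables.

Poses arrive as delimited tables with one row per docked pose:
(ligand_id, conformation_id, arm, binding_energy, acceptor_kind,
ax, ay, az, sx, sy, sz), where (ax..az) is the ligand acceptor atom
(hydroxyl O or amine N) and (sx..sz) the co-factor sulfate sulfur.
A pose is catalytically competent when the acceptor sits within the
distance criterion of the sulfate (strictly < 5 Å) and, optionally,
its binding energy beats the threshold (strictly < -5 kcal/mol).

The ΔBE sign convention everywhere is bestBE_MD - bestBE_MDeNM:
positive means the MDeNM arm found the more favorable (lower) energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "POSE_COLUMNS",
    "read_pose_table",
    "write_pose_table",
    "acceptor_sulfate_distance",
    "competence_filter",
    "best_be",
    "arm_comparison",
    "ArmComparison",
    "predicted_be",
    "experimental_correlation",
    "substrate_stability",
]

POSE_COLUMNS = [
    "ligand_id", "conformation_id", "arm", "binding_energy",
    "acceptor_kind", "ax", "ay", "az", "sx", "sy", "sz",
]


def read_pose_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pose table missing columns: {missing}")
    if not np.all(np.isfinite(df["binding_energy"])):
        raise ValueError("non-finite binding energies in pose table")
    return df


def write_pose_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False)


def acceptor_sulfate_distance(poses: pd.DataFrame) -> pd.Series:
    """Distance between the ligand acceptor atom and the sulfate S, in Å."""
    d = poses[["ax", "ay", "az"]].to_numpy() - poses[["sx", "sy", "sz"]].to_numpy()
    return pd.Series(np.linalg.norm(d, axis=1), index=poses.index, name="d_as")


def competence_filter(
    poses: pd.DataFrame,
    max_dist: float = 5.0,
    max_be: float = -5.0,
    require_be: bool = True,
) -> pd.DataFrame:
    """Keep catalytically competent poses (strict inequalities).

    A pose passes when its acceptor-sulfate distance is < ``max_dist`` and,
    if ``require_be``, its binding energy is < ``max_be``.
    """
    keep = acceptor_sulfate_distance(poses) < max_dist
    if require_be:
        keep &= poses["binding_energy"] < max_be
    return poses[keep]


def best_be(
    poses: pd.DataFrame,
    by: tuple[str, ...] = ("ligand_id", "arm"),
    all_ligands: pd.Index | None = None,
) -> pd.DataFrame:
    """Minimum binding energy per group with the witnessing conformation.

    Groups with no pose (possible when ``all_ligands`` lists ligands that
    lost every pose to a filter) are kept as rows flagged
    ``no_competent_pose`` rather than silently dropped.
    """
    if poses.empty and all_ligands is None:
        return pd.DataFrame(
            columns=list(by) + ["binding_energy", "conformation_id",
                                "no_competent_pose"]
        )
    idx = poses.groupby(list(by), sort=True)["binding_energy"].idxmin()
    out = poses.loc[idx, list(by) + ["binding_energy", "conformation_id"]]
    out = out.reset_index(drop=True)
    out["no_competent_pose"] = False
    if all_ligands is not None and "ligand_id" in by:
        present = set(out["ligand_id"])
        missing = [lig for lig in all_ligands if lig not in present]
        if missing:
            rows = pd.DataFrame({
                "ligand_id": missing,
                "binding_energy": np.nan,
                "conformation_id": None,
                "no_competent_pose": True,
            })
            if "arm" in by:
                rows["arm"] = None
            out = pd.concat([out, rows], ignore_index=True)
    return out


@dataclass
class ArmComparison:
    """Ligand counts exceeding each |ΔBE| threshold, split by favored arm."""

    delta_be: pd.Series  # per ligand, bestBE_MD - bestBE_MDeNM
    counts: dict
    n_excluded: int


def arm_comparison(
    best: pd.DataFrame, thresholds: tuple[float, ...] = (0.5, 1.0)
) -> ArmComparison:
    """Compare per-ligand best binding energies between the MD and MDeNM arms.

    ``best`` must be a best_be table grouped by (ligand_id, arm). Ligands
    missing either arm are excluded and counted in ``n_excluded``. For each
    threshold the result reports how many ligands have |ΔBE| above it and,
    of those, how many favor each arm (ΔBE > 0 favors MDeNM).
    """
    wide = best[~best["no_competent_pose"]].pivot_table(
        index="ligand_id", columns="arm", values="binding_energy",
        aggfunc="min",
    )
    for arm in ("MD", "MDeNM"):
        if arm not in wide.columns:
            wide[arm] = np.nan
    complete = wide.dropna(subset=["MD", "MDeNM"])
    n_excluded = len(wide) - len(complete)
    delta = (complete["MD"] - complete["MDeNM"]).rename("delta_be")
    counts = {}
    for t in thresholds:
        exceed = delta[np.abs(delta) > t]
        counts[t] = {
            "n_exceeding": int(len(exceed)),
            "favor_mdenm": int((exceed > 0).sum()),
            "favor_md": int((exceed < 0).sum()),
        }
    return ArmComparison(delta, counts, n_excluded)


def predicted_be(
    poses: pd.DataFrame, n_best: int = 10
) -> pd.DataFrame:
    """Predicted binding energy: mean of the best per-conformation scores.

    For each (ligand, arm) the score of a conformation is its best (lowest)
    pose energy; the prediction averages the ``n_best`` lowest conformation
    scores. When fewer conformations are available the mean is taken over
    what exists and the row is flagged ``fewer_than_requested``.
    """
    per_conf = (
        poses.groupby(["ligand_id", "arm", "conformation_id"], sort=True)
        ["binding_energy"].min().reset_index()
    )
    rows = []
    for (lig, arm), grp in per_conf.groupby(["ligand_id", "arm"], sort=True):
        scores = np.sort(grp["binding_energy"].to_numpy())
        rows.append({
            "ligand_id": lig,
            "arm": arm,
            "predicted_be": float(scores[:n_best].mean()),
            "n_conformations_used": int(min(n_best, scores.size)),
            "fewer_than_requested": scores.size < n_best,
        })
    return pd.DataFrame(rows)


def experimental_correlation(
    predicted: pd.Series, experimental: pd.Series
) -> float:
    """Squared Pearson correlation R² between predicted and experimental BE.

    Both series are indexed by ligand id; an id present in one but not the
    other raises with the offending ids listed.
    """
    unmatched = set(predicted.index) ^ set(experimental.index)
    if unmatched:
        raise ValueError(f"unmatched ligand ids: {sorted(unmatched)}")
    if len(predicted) < 3:
        raise ValueError("need at least 3 paired ligands")
    exp = experimental.loc[predicted.index]
    r, _ = stats.pearsonr(predicted.to_numpy(), exp.to_numpy())
    return float(r * r)


def substrate_stability(
    trajectory_distances: np.ndarray,
    cutoff: float = 5.0,
    stability_fraction: float = 0.9,
) -> tuple[bool, float]:
    """Is the substrate's acceptor held near the sulfate along a trajectory?

    Returns (stable, fraction_within): the fraction of frames with
    acceptor-sulfate distance <= ``cutoff`` ("within"), and stability as
    that fraction reaching ``stability_fraction``.
    """
    d = np.asarray(trajectory_distances, dtype=float).ravel()
    if d.size < 1:
        raise ValueError("need at least one frame")
    frac = float(np.mean(d <= cutoff))
    return frac >= stability_fraction, frac
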