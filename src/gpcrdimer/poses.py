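"""Post-processing of rigid-body docking poses for membrane proteins.

A docking run holds one protomer (the *target*) fixed in a membrane frame
(z-axis = membrane normal, membrane center at z = 0) and samples rigid
placements of a second protomer (the *probe*).  Each pose is a proper
rotation plus translation applied to the probe's reference coordinates,
with a docking score (higher = better).

The operations here reproduce the standard post-docking funnel for
transmembrane complexes:

- *membrane-topology filter*: a pose is physical only if the probe stays
  membrane-embedded, i.e. its tilt away from the membrane normal is at most
  0.4 rad and the displacement of its geometric center along the normal is
  at most 6.0 Å (both thresholds configurable); the best 4000 poses by
  score enter the filter.
- *leader clustering* at a 3 Å Cα RMSD cutoff, computed in the fixed target
  frame without re-superposition (pose differences are physical).
- *interface contacts*: residue pairs across the interface with minimum
  heavy-atom distance within a cutoff (default 4.5 Å).
- *arrestin pose filter*: receptor-arrestin poses are retained only when
  the arrestin finger-loop anchor (residue 71 Cα) sits within a cutoff of
  the receptor's conserved DRY arginine (residue 132 Cα).
- *Tilt/Rot indices* describing an arrestin's inclination relative to the
  receptor main axis and its rotation parallel to the membrane plane.
- *steric clash counting* for stoichiometry checks (e.g. whether two
  effector copies can dock simultaneously).

Hydrogens are ignored in all distance operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, ClusterMixin

from .structures import StructureModel

__all__ = [
    "DockPose",
    "TopologyMetrics",
    "TopologyFilterConfig",
    "ArrestinFilterConfig",
    "ClusterSet",
    "TiltRotResult",
    "ClashReport",
    "compute_topology",
    "filter_poses",
    "pose_rmsd",
    "cluster_poses",
    "PoseLeaderClusterer",
    "interface_contacts",
    "arrestin_pose_filter",
    "tilt_rot_indices",
    "clash_check",
    "poses_to_frame",
    "poses_from_frame",
]

_Z = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class DockPose:
    """A rigid placement ``x -> R @ x + t`` of the probe, with its score."""

    pose_id: int
    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,), Å
    score: float

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6:
            raise ValueError(f"pose {self.pose_id}: rotation is not orthonormal")
        if np.linalg.det(R) <= 0:
            raise ValueError(f"pose {self.pose_id}: rotation is not proper (det <= 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class TopologyMetrics:
    tilt_rad: float
    z_offset_A: float


@dataclass(frozen=True)
class TopologyFilterConfig:
    tilt_max_rad: float = 0.4
    z_offset_max_A: float = 6.0
    keep_best: int = 4000

    def __post_init__(self):
        if self.tilt_max_rad <= 0 or self.z_offset_max_A <= 0 or self.keep_best <= 0:
            raise ValueError("thresholds and keep_best must be positive")


@dataclass(frozen=True)
class ArrestinFilterConfig:
    """Anchor-distance rule for receptor-arrestin poses.

    The conserved DRY arginine at the cytosolic end of receptor helix 3
    (residue 132) must be engaged by the arrestin finger loop (residue 71);
    poses whose anchor Cα-Cα distance exceeds ``max_distance_A`` are
    discarded.
    """

    receptor_anchor_res: int = 132
    receptor_anchor_chain: str | None = None
    arrestin_anchor_res: int = 71
    arrestin_anchor_chain: str | None = None
    max_distance_A: float = 12.0

    def __post_init__(self):
        if self.max_distance_A <= 0:
            raise ValueError("max_distance_A must be positive")


@dataclass(frozen=True)
class ClusterSet:
    """Leader clusters over a ranked pose list."""

    clusters: list = field(default_factory=list)  # (center_pose_id, [member_pose_ids])
    rmsd_cutoff_A: float = 3.0

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def center_ids(self) -> list:
        return [c for c, _ in self.clusters]


@dataclass(frozen=True)
class TiltRotResult:
    tilt_index_deg: float  # in [0, 180]
    rot_index_deg: float  # in (-180, 180]; NaN when the axis is along +/-z


@dataclass(frozen=True)
class ClashReport:
    n_clashing_pairs: int
    clash_distance_A: float
    pair_threshold: int
    verdict: str  # "compatible" | "clashing"


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------


def compute_topology(pose: DockPose, probe: StructureModel) -> TopologyMetrics:
    """Tilt and z-offset of a posed probe relative to the membrane frame.

    Tilt is the angle between the probe's rotated z-axis and the membrane
    normal, ``arccos((R @ z) . z)``; z-offset is the displacement of the
    probe's Cα geometric center along the normal.
    """
    cos_tilt = np.clip(pose.rotation[2, 2], -1.0, 1.0)
    c = probe.ca_center
    z_off = (pose.rotation @ c + pose.translation - c)[2]
    return TopologyMetrics(tilt_rad=float(np.arccos(cos_tilt)), z_offset_A=float(z_off))


def _rank(poses: list[DockPose]) -> list[DockPose]:
    """Score descending, pose_id ascending on ties."""
    return sorted(poses, key=lambda p: (-p.score, p.pose_id))


def filter_poses(
    poses: list[DockPose],
    probe: StructureModel,
    config: TopologyFilterConfig | None = None,
) -> tuple[list[DockPose], pd.DataFrame]:
    """Apply the membrane-topology filter to a scored pose list.

    The best ``keep_best`` poses by score are retained, then poses with
    ``tilt <= tilt_max`` and ``|z_offset| <= z_offset_max`` are kept, in
    score order.  Returns the accepted poses and a per-pose metrics table
    (for all ranked poses, with an ``accepted`` flag).
    """
    config = config or TopologyFilterConfig()
    ranked = _rank(poses)[: config.keep_best]
    records = []
    accepted = []
    for p in ranked:
        m = compute_topology(p, probe)
        ok = m.tilt_rad <= config.tilt_max_rad and abs(m.z_offset_A) <= config.z_offset_max_A
        if ok:
            accepted.append(p)
        records.append(
            {
                "pose_id": p.pose_id,
                "score": p.score,
                "tilt_rad": m.tilt_rad,
                "z_offset_A": m.z_offset_A,
                "accepted": ok,
            }
        )
    return accepted, pd.DataFrame(
        records, columns=["pose_id", "score", "tilt_rad", "z_offset_A", "accepted"]
    )


# ---------------------------------------------------------------------------
# RMSD and clustering
# ---------------------------------------------------------------------------


def pose_rmsd(a: DockPose, b: DockPose, probe: StructureModel) -> float:
    """Cα RMSD between two placements of the same probe, no re-superposition.

    The target fixes the frame, so the difference between two poses is
    physically meaningful; a pure translation by d gives RMSD exactly d.
    """
    ca = probe.ca_coords
    diff = a.apply(ca) - b.apply(ca)
    return float(np.sqrt((diff**2).sum(axis=1).mean()))


class PoseLeaderClusterer(ClusterMixin, BaseEstimator):
    """Greedy leader clustering of ranked poses under a Cα RMSD cutoff.

    The highest-scored unclustered pose becomes a cluster center; every
    unclustered pose within ``rmsd_cutoff_A`` of it joins; repeat until all
    poses are clustered.  Centers therefore sit pairwise at or beyond the
    cutoff, in formation (score) order.

    Parameters
    ----------
    probe : StructureModel
        Reference probe whose Cα atoms define the RMSD.
    rmsd_cutoff_A : float, default 3.0

    Attributes
    ----------
    labels_ : cluster index per input pose (input order)
    cluster_set_ : ClusterSet with centers and members by pose_id
    """

    def __init__(self, probe: StructureModel | None = None, rmsd_cutoff_A: float = 3.0):
        self.probe = probe
        self.rmsd_cutoff_A = rmsd_cutoff_A

    def fit(self, X: list[DockPose], y=None):
        if self.probe is None:
            raise ValueError("probe structure is required")
        if self.rmsd_cutoff_A <= 0:
            raise ValueError("rmsd_cutoff_A must be positive")
        poses = list(X)
        order = sorted(range(len(poses)), key=lambda i: (-poses[i].score, poses[i].pose_id))
        ca = self.probe.ca_coords
        placed = np.stack([poses[i].apply(ca) for i in order]) if poses else np.empty((0, 0, 3))
        n = len(poses)
        labels_sorted = np.full(n, -1, dtype=int)
        clusters: list[tuple[int, list[int]]] = []
        for i in range(n):
            if labels_sorted[i] != -1:
                continue
            cid = len(clusters)
            members = [i]
            labels_sorted[i] = cid
            for j in range(i + 1, n):
                if labels_sorted[j] != -1:
                    continue
                rmsd = np.sqrt(((placed[j] - placed[i]) ** 2).sum(axis=1).mean())
                if rmsd <= self.rmsd_cutoff_A:
                    labels_sorted[j] = cid
                    members.append(j)
            clusters.append(
                (poses[order[i]].pose_id, [poses[order[j]].pose_id for j in members])
            )
        labels = np.empty(n, dtype=int)
        for rank_idx, orig_idx in enumerate(order):
            labels[orig_idx] = labels_sorted[rank_idx]
        self.labels_ = labels
        self.cluster_set_ = ClusterSet(clusters, self.rmsd_cutoff_A)
        return self


def cluster_poses(
    poses: list[DockPose], probe: StructureModel, rmsd_cutoff_A: float = 3.0
) -> ClusterSet:
    """Leader-cluster filtered poses; centers returned in score order."""
    est = PoseLeaderClusterer(probe=probe, rmsd_cutoff_A=rmsd_cutoff_A).fit(poses)
    return est.cluster_set_


# ---------------------------------------------------------------------------
# contacts, anchors and clashes
# ---------------------------------------------------------------------------


def interface_contacts(
    target: StructureModel,
    posed_probe: StructureModel,
    cutoff_A: float = 4.5,
) -> pd.DataFrame:
    """Residue pairs across the interface within a heavy-atom cutoff.

    Returns a table (target_res_id, probe_res_id, min_distance_A) of residue
    pairs whose minimum non-hydrogen interatomic distance is at most
    ``cutoff_A``, sorted by distance.
    """
    t_mask = target.heavy_mask
    p_mask = posed_probe.heavy_mask
    t_xyz = target.atoms.coord[t_mask]
    p_xyz = posed_probe.atoms.coord[p_mask]
    t_res = target.atoms.res_id[t_mask]
    p_res = posed_probe.atoms.res_id[p_mask]
    cols = ["target_res_id", "probe_res_id", "min_distance_A"]
    if len(t_xyz) == 0 or len(p_xyz) == 0:
        return pd.DataFrame(columns=cols)
    pairs = cKDTree(t_xyz).query_ball_tree(cKDTree(p_xyz), cutoff_A)
    best: dict[tuple[int, int], float] = {}
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(t_xyz[i] - p_xyz[j]))
            if d <= cutoff_A:
                key = (int(t_res[i]), int(p_res[j]))
                if d < best.get(key, np.inf):
                    best[key] = d
    df = pd.DataFrame(
        [(tr, pr, d) for (tr, pr), d in best.items()], columns=cols
    )
    return df.sort_values("min_distance_A", kind="stable", ignore_index=True)


def arrestin_pose_filter(
    poses: list[DockPose],
    receptor: StructureModel,
    arrestin: StructureModel,
    config: ArrestinFilterConfig | None = None,
) -> tuple[list[DockPose], pd.DataFrame]:
    """Keep receptor-arrestin poses satisfying the anchor-distance rule.

    For each pose the arrestin anchor Cα (finger loop, residue 71 by
    default) is transformed and its distance to the receptor anchor Cα (DRY
    arginine, residue 132) is compared against ``max_distance_A``.
    """
    config = config or ArrestinFilterConfig()
    r_anchor = receptor.anchor_ca(config.receptor_anchor_res, config.receptor_anchor_chain)
    a_anchor = arrestin.anchor_ca(config.arrestin_anchor_res, config.arrestin_anchor_chain)
    records, accepted = [], []
    for p in _rank(poses):
        d = float(np.linalg.norm(p.rotation @ a_anchor + p.translation - r_anchor))
        ok = d <= config.max_distance_A
        if ok:
            accepted.append(p)
        records.append(
            {"pose_id": p.pose_id, "score": p.score, "anchor_distance_A": d, "accepted": ok}
        )
    return accepted, pd.DataFrame(
        records, columns=["pose_id", "score", "anchor_distance_A", "accepted"]
    )


def tilt_rot_indices(
    receptor: StructureModel,
    posed_arrestin: StructureModel,
    receptor_anchor_res: int = 132,
    receptor_anchor_chain: str | None = None,
    degeneracy_tol: float = 1e-6,
) -> TiltRotResult:
    """Inclination and in-plane rotation of an arrestin against its receptor.

    The arrestin principal axis is the dominant principal component of its
    Cα cloud, sign-fixed to point toward the N-domain centroid (first half
    of the residues in sequence order).  The Tilt index is the angle between
    this axis and the receptor main axis (the membrane normal, +z).  The Rot
    index is the signed angle, measured about +z, from the receptor
    reference vector (anchor-residue Cα toward the receptor Cα centroid,
    projected in-plane) to the in-plane projection of the arrestin axis.
    """
    ca = posed_arrestin.ca_coords
    centered = ca - ca.mean(axis=0)
    cov = centered.T @ centered / len(ca)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] - evals[-2] <= degeneracy_tol * max(evals[-1], 1.0):
        raise ValueError("degenerate principal axis: Ca cloud has no dominant direction")
    axis = evecs[:, -1]
    res_ids = posed_arrestin.atoms.res_id[posed_arrestin.ca_mask]
    n_half = np.unique(res_ids)[: max(1, len(np.unique(res_ids)) // 2)]
    n_centroid = ca[np.isin(res_ids, n_half)].mean(axis=0)
    if axis @ (n_centroid - ca.mean(axis=0)) < 0:
        axis = -axis
    tilt = np.degrees(np.arccos(np.clip(axis @ _Z, -1.0, 1.0)))

    ref = receptor.ca_center - receptor.anchor_ca(receptor_anchor_res, receptor_anchor_chain)
    ref_xy, ax_xy = ref[:2], axis[:2]
    if np.linalg.norm(ref_xy) <= degeneracy_tol:
        raise ValueError("receptor reference vector has no in-plane component")
    if np.linalg.norm(ax_xy) <= degeneracy_tol:
        # arrestin axis parallel to the membrane normal: rotation undefined
        return TiltRotResult(tilt_index_deg=float(tilt), rot_index_deg=float("nan"))
    rot = np.degrees(
        np.arctan2(
            ref_xy[0] * ax_xy[1] - ref_xy[1] * ax_xy[0], ref_xy @ ax_xy
        )
    )
    if rot <= -180.0:
        rot += 360.0
    return TiltRotResult(tilt_index_deg=float(tilt), rot_index_deg=float(rot))


def _count_close_pairs(a: np.ndarray, b: np.ndarray, cutoff: float) -> int:
    """Heavy-atom pairs strictly below cutoff between two coordinate sets."""
    if len(a) == 0 or len(b) == 0:
        return 0
    pairs = cKDTree(a).query_ball_tree(cKDTree(b), cutoff)
    n = 0
    for i, js in enumerate(pairs):
        for j in js:
            if np.linalg.norm(a[i] - b[j]) < cutoff:
                n += 1
    return n


def clash_check(
    dimer: StructureModel,
    effector_copies: list[StructureModel],
    clash_distance_A: float = 2.5,
    pair_threshold: int = 10,
) -> ClashReport:
    """Count steric clashes in a receptor-dimer / effector assembly.

    Counts heavy-atom pairs closer than ``clash_distance_A`` between every
    pair of effector copies and between each copy and the receptor dimer.
    The assembly is judged ``clashing`` when the pair count exceeds
    ``pair_threshold`` — used e.g. to test whether a 2:2 stoichiometry is
    sterically possible.
    """
    if not effector_copies:
        raise ValueError("at least one effector copy is required")
    coords = [c.heavy_coords for c in effector_copies]
    dimer_xyz = dimer.heavy_coords
    n = 0
    for i in range(len(coords)):
        n += _count_close_pairs(coords[i], dimer_xyz, clash_distance_A)
        for j in range(i + 1, len(coords)):
            n += _count_close_pairs(coords[i], coords[j], clash_distance_A)
    verdict = "clashing" if n > pair_threshold else "compatible"
    return ClashReport(n, clash_distance_A, pair_threshold, verdict)


# ---------------------------------------------------------------------------
# pose table I/O
# ---------------------------------------------------------------------------

_POSE_COLUMNS = (
    ["pose_id", "score"]
    + [f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]
    + ["tx", "ty", "tz"]
)


def poses_to_frame(poses: list[DockPose]) -> pd.DataFrame:
    """Serialize poses to the flat TSV layout (r11..r33 row-major)."""
    rows = []
    for p in poses:
        rows.append(
            [p.pose_id, p.score] + list(p.rotation.ravel()) + list(p.translation)
        )
    return pd.DataFrame(rows, columns=_POSE_COLUMNS)


def poses_from_frame(df: pd.DataFrame) -> list[DockPose]:
    missing = [c for c in _POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pose table is missing columns: {missing}")
    poses = []
    for _, row in df.iterrows():
        R = row[[f"r{i}{j}" for i in (1, 2, 3) for j in (1, 2, 3)]].to_numpy(
            dtype=float
        ).reshape(3, 3)
        t = row[["tx", "ty", "tz"]].to_numpy(dtype=float)
        poses.append(DockPose(int(row["pose_id"]), R, t, float(row["score"])))
    return poses
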