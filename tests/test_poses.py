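"""Pose topology, RMSD clustering, contacts, anchors, indices and clashes."""

import itertools

import numpy as np
import pytest

from gpcrdimer.poses import (
    ArrestinFilterConfig,
    DockPose,
    TopologyFilterConfig,
    arrestin_pose_filter,
    clash_check,
    cluster_poses,
    compute_topology,
    filter_poses,
    interface_contacts,
    pose_rmsd,
    poses_from_frame,
    poses_to_frame,
    tilt_rot_indices,
)
from gpcrdimer.simulate import PoseSimConfig, simulate_poses
from gpcrdimer.structures import StructureModel


def rot_x(a):
    return np.array(
        [[1, 0, 0], [0, np.cos(a), -np.sin(a)], [0, np.sin(a), np.cos(a)]], dtype=float
    )


def rot_z(a):
    return np.array(
        [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]], dtype=float
    )


IDENTITY = np.eye(3)
ZERO = np.zeros(3)


# ---------------------------------------------------------------------------
# topology metrics
# ---------------------------------------------------------------------------


def test_identity_pose_has_zero_topology(probe):
    m = compute_topology(DockPose(0, IDENTITY, ZERO, 1.0), probe)
    assert m.tilt_rad == 0.0
    assert m.z_offset_A == pytest.approx(0.0, abs=1e-4)


def test_rotation_about_z_leaves_tilt_zero(probe):
    m = compute_topology(DockPose(0, rot_z(np.pi / 2), ZERO, 1.0), probe)
    assert m.tilt_rad == pytest.approx(0.0, abs=1e-12)


def test_tilt_and_zoffset_closed_form():
    # probe with Ca center at the origin: tilt = rotation angle about x,
    # z-offset = translation z-component
    probe = StructureModel.from_arrays(np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]))
    m = compute_topology(DockPose(0, rot_x(0.5), np.array([0.0, 0.0, 7.0]), 1.0), probe)
    assert m.tilt_rad == pytest.approx(0.5, abs=1e-7)
    assert m.z_offset_A == pytest.approx(7.0, abs=1e-7)


def test_tilt_invariances(probe, rng):
    """Tilt is unchanged by extra spins about z and by any translation."""
    base = DockPose(0, rot_x(0.3), ZERO, 1.0)
    t0 = compute_topology(base, probe).tilt_rad
    for _ in range(5):
        spun = DockPose(
            1, base.rotation @ rot_z(rng.uniform(0, 2 * np.pi)), rng.normal(size=3), 1.0
        )
        assert compute_topology(spun, probe).tilt_rad == pytest.approx(t0, abs=1e-9)


def test_non_orthonormal_rotation_rejected():
    with pytest.raises(ValueError, match="orthonormal"):
        DockPose(0, np.eye(3) * 1.1, ZERO, 1.0)
    with pytest.raises(ValueError, match="proper"):
        DockPose(0, np.diag([1.0, 1.0, -1.0]), ZERO, 1.0)


# ---------------------------------------------------------------------------
# membrane-topology filter
# ---------------------------------------------------------------------------


def _pose_with(tilt, z, pose_id=0, score=1.0):
    return DockPose(pose_id, rot_x(tilt), np.array([0.0, 0.0, z]), score)


@pytest.mark.parametrize(
    "tilt,z,accepted",
    [
        (0.39, 5.9, True),  # inside both bounds
        (0.41, 0.0, False),  # tilt too large
        (0.0, 6.5, False),  # |z| too large
        (0.4, 6.0, True),  # thresholds are inclusive
        (0.0, -5.9, True),  # threshold applies to |z|
    ],
)
def test_filter_boundary_cases(tilt, z, accepted):
    probe = StructureModel.from_arrays(np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]]))
    got, metrics = filter_poses([_pose_with(tilt, z)], probe)
    assert (len(got) == 1) is accepted
    assert metrics["accepted"].iloc[0] == accepted


def test_filter_matches_ground_truth_exactly(probe):
    poses, truth = simulate_poses(PoseSimConfig(n_poses=1000, seed=1), probe)
    accepted, metrics = filter_poses(poses, probe)
    got_ids = sorted(p.pose_id for p in accepted)
    true_ids = sorted(np.flatnonzero(truth.accept).tolist())
    assert got_ids == true_ids


def test_filter_is_monotone_in_both_thresholds(probe):
    poses, _ = simulate_poses(PoseSimConfig(n_poses=300, seed=2), probe)
    base, _ = filter_poses(poses, probe, TopologyFilterConfig(0.4, 6.0))
    base_ids = {p.pose_id for p in base}
    for tilt_max, z_max in [(0.5, 6.0), (0.4, 8.0), (0.6, 10.0)]:
        wider, _ = filter_poses(poses, probe, TopologyFilterConfig(tilt_max, z_max))
        assert base_ids <= {p.pose_id for p in wider}


def test_filter_keep_best_truncates_by_score(probe):
    poses, _ = simulate_poses(
        PoseSimConfig(n_poses=100, tilt_range=(0.0, 0.0), zoffset_range=(0.0, 0.0), seed=3)
    )
    accepted, metrics = filter_poses(poses, probe, TopologyFilterConfig(keep_best=10))
    assert len(metrics) == 10
    # scores are monotone decreasing in pose index, so the top 10 are ids 0-9
    assert sorted(p.pose_id for p in accepted) == list(range(10))
    scores = [p.score for p in accepted]
    assert scores == sorted(scores, reverse=True)


# ---------------------------------------------------------------------------
# pose RMSD
# ---------------------------------------------------------------------------


def test_rmsd_identity_and_symmetry(probe, rng):
    poses, _ = simulate_poses(PoseSimConfig(n_poses=4, seed=5), probe)
    for a, b in itertools.combinations(poses, 2):
        assert pose_rmsd(a, b, probe) == pytest.approx(pose_rmsd(b, a, probe))
    for p in poses:
        assert pose_rmsd(p, p, probe) == 0.0


def test_rmsd_of_pure_translation_is_the_distance(probe):
    a = DockPose(0, IDENTITY, ZERO, 1.0)
    b = DockPose(1, IDENTITY, np.array([3.0, 0.0, 0.0]), 1.0)
    assert pose_rmsd(a, b, probe) == pytest.approx(3.0, abs=1e-6)


def test_rmsd_matches_direct_arithmetic():
    coords = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 3], [1, 1, 1]], dtype=float
    )
    toy = StructureModel.from_arrays(coords)
    a = DockPose(0, rot_z(0.7), np.array([1.0, -2.0, 0.5]), 1.0)
    b = DockPose(1, rot_x(0.3), np.array([0.0, 1.0, -1.0]), 1.0)
    pa = coords @ a.rotation.T + a.translation
    pb = coords @ b.rotation.T + b.translation
    expected = np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1)))
    assert pose_rmsd(a, b, toy) == pytest.approx(expected, abs=1e-6)


# ---------------------------------------------------------------------------
# leader clustering
# ---------------------------------------------------------------------------


def test_far_apart_poses_form_singletons(probe):
    poses = [
        DockPose(i, IDENTITY, np.array([20.0 * i, 0.0, 0.0]), 10.0 - i) for i in range(4)
    ]
    cs = cluster_poses(poses, probe, 3.0)
    assert cs.n_clusters == 4
    assert all(len(m) == 1 for _, m in cs.clusters)


def test_close_pair_clusters_on_better_score(probe):
    a = DockPose(0, IDENTITY, ZERO, score=5.0)
    b = DockPose(1, IDENTITY, np.array([1.0, 0.0, 0.0]), score=9.0)
    cs = cluster_poses([a, b], probe, 3.0)
    assert cs.n_clusters == 1
    center, members = cs.clusters[0]
    assert center == 1  # higher score leads
    assert sorted(members) == [0, 1]


def test_constructed_groups_are_recovered(probe, rng):
    """Three jittered groups (intra < 1 A, inter > 10 A) cluster exactly."""
    poses = []
    group_of = {}
    pid = 0
    for g, offset in enumerate([0.0, 50.0, 100.0]):
        for _ in range(17 if g < 2 else 16):
            jitter = rng.uniform(-0.3, 0.3, size=3)  # RMSD of a translation = |d| < 1
            poses.append(
                DockPose(pid, IDENTITY, np.array([offset, 0.0, 0.0]) + jitter, rng.uniform())
            )
            group_of[pid] = g
            pid += 1
    cs = cluster_poses(poses, probe, 3.0)
    assert cs.n_clusters == 3
    for center, members in cs.clusters:
        assert {group_of[m] for m in members} == {group_of[center]}
    assert sum(len(m) for _, m in cs.clusters) == 50


def test_members_within_cutoff_of_center(probe):
    poses, _ = simulate_poses(PoseSimConfig(n_poses=60, seed=8), probe)
    cs = cluster_poses(poses, probe, 3.0)
    by_id = {p.pose_id: p for p in poses}
    seen = []
    for center, members in cs.clusters:
        for m in members:
            assert pose_rmsd(by_id[center], by_id[m], probe) <= 3.0 + 1e-9
        seen.extend(members)
    assert sorted(seen) == sorted(by_id)  # clusters partition the input
    # centers are pairwise >= cutoff apart, in formation order
    for (c1, _), (c2, _) in itertools.combinations(cs.clusters, 2):
        assert pose_rmsd(by_id[c1], by_id[c2], probe) >= 3.0


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def test_distant_structures_have_no_contacts():
    a = StructureModel.from_arrays(np.zeros((1, 3)))
    b = StructureModel.from_arrays(np.array([[100.0, 0.0, 0.0]]))
    assert len(interface_contacts(a, b)) == 0


def test_single_pair_contact_distance():
    a = StructureModel.from_arrays(np.zeros((1, 3)), res_id=np.array([7]))
    b = StructureModel.from_arrays(np.array([[3.0, 0.0, 0.0]]), res_id=np.array([9]))
    df = interface_contacts(a, b, cutoff_A=4.5)
    assert len(df) == 1
    row = df.iloc[0]
    assert (row.target_res_id, row.probe_res_id) == (7, 9)
    assert row.min_distance_A == pytest.approx(3.0)


def test_contacts_match_all_pairs_bruteforce(rng):
    na, nb = 30, 25
    a = StructureModel.from_arrays(
        rng.uniform(0, 15, size=(na, 3)), res_id=rng.integers(1, 6, size=na)
    )
    b = StructureModel.from_arrays(
        rng.uniform(5, 20, size=(nb, 3)), res_id=rng.integers(1, 6, size=nb)
    )
    df = interface_contacts(a, b, cutoff_A=4.5)
    got = {(r.target_res_id, r.probe_res_id): r.min_distance_A for r in df.itertuples()}
    # brute force over all atom pairs
    expected = {}
    for i in range(na):
        for j in range(nb):
            d = np.linalg.norm(a.coords[i] - b.coords[j])
            key = (a.atoms.res_id[i], b.atoms.res_id[j])
            if d <= 4.5 and d < expected.get(key, np.inf):
                expected[key] = d
    assert set(got) == set(expected)
    for key in got:
        assert got[key] == pytest.approx(expected[key], abs=1e-5)
    assert df["min_distance_A"].is_monotonic_increasing


def test_hydrogens_are_ignored_in_contacts():
    a = StructureModel.from_arrays(np.zeros((1, 3)), element="C")
    b = StructureModel.from_arrays(np.array([[1.0, 0.0, 0.0]]), element="H")
    assert len(interface_contacts(a, b)) == 0


# ---------------------------------------------------------------------------
# arrestin anchor filter
# ---------------------------------------------------------------------------


def _anchor_structures():
    receptor = StructureModel.from_arrays(
        np.array([[0.0, 0.0, 0.0], [4.0, 0.0, 0.0]]), res_id=np.array([132, 133])
    )
    arrestin = StructureModel.from_arrays(
        np.array([[0.0, 0.0, 0.0], [0.0, 5.0, 0.0]]), res_id=np.array([71, 72])
    )
    return receptor, arrestin


@pytest.mark.parametrize("dist,accepted", [(8.0, True), (30.0, False), (12.0, True)])
def test_anchor_distance_rule(dist, accepted):
    receptor, arrestin = _anchor_structures()
    pose = DockPose(0, IDENTITY, np.array([dist, 0.0, 0.0]), 1.0)
    got, table = arrestin_pose_filter([pose], receptor, arrestin)
    assert (len(got) == 1) is accepted
    assert table["anchor_distance_A"].iloc[0] == pytest.approx(dist)


def test_anchor_filter_matches_bruteforce(rng):
    receptor, arrestin = _anchor_structures()
    poses, _ = simulate_poses(PoseSimConfig(n_poses=200, zoffset_range=(-5.0, 5.0), seed=4))
    got, _ = arrestin_pose_filter(poses, receptor, arrestin)
    a71 = arrestin.anchor_ca(71)
    r132 = receptor.anchor_ca(132)
    expected = {
        p.pose_id
        for p in poses
        if np.linalg.norm(p.rotation @ a71 + p.translation - r132) <= 12.0
    }
    assert {p.pose_id for p in got} == expected


def test_missing_anchor_names_residue():
    receptor, arrestin = _anchor_structures()
    cfg = ArrestinFilterConfig(receptor_anchor_res=999)
    with pytest.raises(ValueError, match="999"):
        arrestin_pose_filter([DockPose(0, IDENTITY, ZERO, 1.0)], receptor, arrestin, cfg)


# ---------------------------------------------------------------------------
# tilt / rot indices
# ---------------------------------------------------------------------------


def _receptor_for_indices():
    # anchor at (10, 0, 0); Ca centroid on the -x side -> reference vector -x
    return StructureModel.from_arrays(
        np.array([[10.0, 0.0, 0.0], [0.0, 0.0, 5.0], [0.0, 0.0, -5.0], [-10.0, 0.0, 0.0]]),
        res_id=np.array([132, 1, 2, 3]),
    )


def _rod(axis, n=20, length=30.0):
    """Ca rod along a given axis; N-half at the far (+axis) end."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    s = np.linspace(length, 0.0, n)  # residue 1 at the +axis tip
    return StructureModel.from_arrays(np.outer(s, axis))


def test_tilt_index_zero_for_axis_along_membrane_normal():
    res = tilt_rot_indices(_receptor_for_indices(), _rod([0, 0, 1]))
    assert res.tilt_index_deg == pytest.approx(0.0, abs=1e-5)
    assert np.isnan(res.rot_index_deg)  # no in-plane component to rotate


def test_inplane_axis_along_reference_gives_tilt90_rot0():
    receptor = _receptor_for_indices()
    ref = np.array([-1.0, 0.0, 0.0])  # anchor -> centroid direction
    res = tilt_rot_indices(receptor, _rod(ref))
    assert res.tilt_index_deg == pytest.approx(90.0, abs=1e-5)
    assert res.rot_index_deg == pytest.approx(0.0, abs=1e-5)


def test_rot_index_tracks_rotation_about_z():
    receptor = _receptor_for_indices()
    for angle in (30.0, -45.0, 120.0):
        c, s = np.cos(np.radians(angle)), np.sin(np.radians(angle))
        axis = np.array([-c, -s, 0.0])  # reference direction rotated by `angle`
        res = tilt_rot_indices(receptor, _rod(axis))
        assert res.rot_index_deg == pytest.approx(angle, abs=1e-5)


def test_degenerate_cloud_rejected(rng):
    # points on a sphere: no dominant principal axis
    v = rng.normal(size=(200, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    sphere = StructureModel.from_arrays(10.0 * v)
    with pytest.raises(ValueError, match="degenerate"):
        tilt_rot_indices(_receptor_for_indices(), sphere, degeneracy_tol=0.5)


# ---------------------------------------------------------------------------
# clash check
# ---------------------------------------------------------------------------


def test_separated_copies_are_compatible():
    dimer = StructureModel.from_arrays(np.zeros((3, 3)) + [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
    c1 = StructureModel.from_arrays(np.array([[50.0, 0.0, 0.0]]))
    c2 = StructureModel.from_arrays(np.array([[100.0, 0.0, 0.0]]))
    rep = clash_check(dimer, [c1, c2])
    assert rep.n_clashing_pairs == 0
    assert rep.verdict == "compatible"


def test_superposed_copies_clash_per_atom():
    coords = np.arange(36, dtype=float).reshape(12, 3) * 5.0
    copy = StructureModel.from_arrays(coords)
    dimer = StructureModel.from_arrays(np.array([[1000.0, 0.0, 0.0]]))
    rep = clash_check(dimer, [copy, copy])
    assert rep.n_clashing_pairs == 12  # each atom self-pairs across copies at distance 0
    assert rep.verdict == "clashing"


def test_constructed_clash_count_and_threshold():
    # 15 atom pairs at exactly 2.0 A (< 2.5), everything else far away
    base = np.array([[10.0 * i, 0.0, 0.0] for i in range(15)])
    c1 = StructureModel.from_arrays(base)
    c2 = StructureModel.from_arrays(base + [0.0, 2.0, 0.0])
    dimer = StructureModel.from_arrays(np.array([[0.0, 0.0, 500.0]]))
    rep = clash_check(dimer, [c1, c2], clash_distance_A=2.5, pair_threshold=10)
    assert rep.n_clashing_pairs == 15
    assert rep.verdict == "clashing"
    relaxed = clash_check(dimer, [c1, c2], clash_distance_A=2.5, pair_threshold=20)
    assert relaxed.verdict == "compatible"


def test_clash_requires_a_copy():
    dimer = StructureModel.from_arrays(np.zeros((1, 3)))
    with pytest.raises(ValueError):
        clash_check(dimer, [])


# ---------------------------------------------------------------------------
# pose table round trip
# ---------------------------------------------------------------------------


def test_pose_table_roundtrip(probe):
    poses, _ = simulate_poses(PoseSimConfig(n_poses=5, seed=6), probe)
    back = poses_from_frame(poses_to_frame(poses))
    for p, q in zip(poses, back):
        assert p.pose_id == q.pose_id
        np.testing.assert_allclose(p.rotation, q.rotation)
        np.testing.assert_allclose(p.translation, q.translation)
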