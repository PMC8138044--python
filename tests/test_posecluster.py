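"""Procrustes superposition, pose similarity measures, clique clustering."""

from itertools import combinations

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.transform import Rotation

from nodkey.posecluster import (
    ClusterSet,
    DegenerateGeometryError,
    DimerPose,
    cluster_poses,
    find_clusters,
    kabsch,
    pick_representative,
    pose_angle,
    pose_min_correlation,
    pose_similarity,
    similarity_matrix,
    superpose_poses,
)
from nodkey.simulate import PoseFamilySpec, gen_dimer_poses


def _pose(pid, ref, mob):
    return DimerPose(pose_id=pid, allele="x", ref_atoms=np.asarray(ref, float),
                     mob_atoms=np.asarray(mob, float))


def _rigid(rng):
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------

class TestKabsch:
    def test_identity_for_identical_clouds(self, rng):
        P = rng.normal(size=(8, 3))
        R, t = kabsch(P, P)
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0, atol=1e-10)

    def test_recovers_known_rigid_transform(self, rng):
        P = rng.normal(size=(10, 3))
        R0 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t0 = np.array([1.0, 2.0, 3.0])
        Q = P @ R0.T + t0
        R, t = kabsch(P, Q)
        rmsd = np.sqrt(((P @ R.T + t - Q) ** 2).sum(axis=1).mean())
        assert rmsd < 1e-8
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_agrees_with_scipy_orthogonal_procrustes(self, rng):
        # independent route: scipy solves the centered rotation problem
        P = rng.normal(size=(12, 3))
        R0, t0 = _rigid(rng)
        Q = P @ R0.T + t0
        R, _ = kabsch(P, Q)
        Pc, Qc = P - P.mean(0), Q - Q.mean(0)
        W, _ = orthogonal_procrustes(Pc, Qc)
        assert np.allclose(R, W.T, atol=1e-8)

    def test_collinear_reference_rejected(self):
        line = np.array([[float(i), 0.0, 0.0] for i in range(5)])
        with pytest.raises(DegenerateGeometryError):
            kabsch(line, line)

    def test_never_returns_reflection(self, rng):
        for _ in range(50):
            P = rng.normal(size=(6, 3))
            Q = rng.normal(size=(6, 3))
            R, _ = kabsch(P, Q)
            assert np.linalg.det(R) == pytest.approx(1.0)


class TestSuperposePoses:
    def test_restores_scrambled_copies(self, rng):
        ref = rng.normal(size=(10, 3))
        mob = rng.normal(size=(10, 3)) + np.array([15.0, 0.0, 0.0])
        poses = [_pose("p0", ref, mob)]
        for k in range(1, 4):
            R, t = _rigid(rng)
            poses.append(_pose(f"p{k}", ref @ R.T + t, mob @ R.T + t))
        aligned = superpose_poses(poses, "p0")
        for pose in aligned:
            assert np.allclose(pose.ref_atoms, ref, atol=1e-8)
            assert np.allclose(pose.mob_atoms, mob, atol=1e-8)

    def test_mismatched_atom_counts_name_pose(self, rng):
        poses = [
            _pose("ok", rng.normal(size=(5, 3)), rng.normal(size=(5, 3))),
            _pose("bad", rng.normal(size=(6, 3)), rng.normal(size=(5, 3))),
        ]
        with pytest.raises(ValueError, match="bad"):
            superpose_poses(poses, "ok")

    def test_unknown_reference_rejected(self, rng):
        poses = [_pose("p", rng.normal(size=(4, 3)), rng.normal(size=(4, 3)))]
        with pytest.raises(KeyError):
            superpose_poses(poses, "ghost")


# --------------------------------------------------------------------------
# similarity measures
# --------------------------------------------------------------------------

class TestPoseAngle:
    def test_self_angle_is_zero(self, rng):
        p = _pose("p", rng.normal(size=(5, 3)), rng.normal(size=(5, 3)) + 10)
        # arccos loses ~1e-8 precision at cos=1, i.e. microdegrees
        assert pose_angle(p, p) == pytest.approx(0.0, abs=1e-4)

    def test_orthogonal_centroids(self):
        ref = np.array([[0.1, 0, 0], [-0.1, 0, 0], [0, 0.1, 0], [0, -0.1, 0]])
        a = _pose("a", ref, np.tile([1.0, 0, 0], (4, 1)) + ref)
        b = _pose("b", ref, np.tile([0, 1.0, 0], (4, 1)) + ref)
        assert pose_angle(a, b, vertex=np.zeros(3)) == pytest.approx(90.0)

    def test_antiparallel_centroids(self):
        ref = np.array([[0.1, 0, 0], [-0.1, 0, 0], [0, 0.1, 0], [0, -0.1, 0]])
        a = _pose("a", ref, np.tile([1.0, 0, 0], (4, 1)) + ref)
        b = _pose("b", ref, np.tile([-1.0, 0, 0], (4, 1)) + ref)
        assert pose_angle(a, b, vertex=np.zeros(3)) == pytest.approx(180.0)

    def test_coincident_centroid_rejected(self, rng):
        ref = rng.normal(size=(4, 3))
        ref -= ref.mean(0)
        a = _pose("a", ref, ref)  # mobile centroid == reference centroid
        with pytest.raises(ValueError):
            pose_angle(a, a, vertex=ref.mean(0))


class TestPoseMinCorrelation:
    def test_identical_mobile_subunits(self, rng):
        mob = rng.normal(size=(6, 3))
        p = _pose("p", rng.normal(size=(4, 3)), mob)
        assert pose_min_correlation(p, p) == pytest.approx(1.0)

    def test_mirrored_axis_gives_minus_one(self, rng):
        mob = rng.normal(size=(6, 3))
        mirrored = mob.copy()
        mirrored[:, 1] = 2 * mob[:, 1].mean() - mob[:, 1]
        a = _pose("a", rng.normal(size=(4, 3)), mob)
        b = _pose("b", a.ref_atoms, mirrored)
        assert pose_min_correlation(a, b) == pytest.approx(-1.0)

    def test_matches_explicit_pearson_formula(self, rng):
        # 4-atom toy checked against the raw sum formula, axis by axis
        A = rng.normal(size=(4, 3))
        B = rng.normal(size=(4, 3))
        expected = []
        for ax in range(3):
            x, y = A[:, ax], B[:, ax]
            n = len(x)
            num = n * (x * y).sum() - x.sum() * y.sum()
            den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
                n * (y**2).sum() - y.sum() ** 2
            )
            expected.append(num / den)
        a = _pose("a", rng.normal(size=(4, 3)), A)
        b = _pose("b", a.ref_atoms, B)
        assert pose_min_correlation(a, b) == pytest.approx(min(expected))

    def test_constant_axis_handling(self, rng):
        flat = np.zeros((5, 3))
        flat[:, 0] = np.arange(5)  # x varies, y and z constant
        a = _pose("a", rng.normal(size=(4, 3)), flat)
        with pytest.warns(UserWarning):
            assert pose_min_correlation(a, a) == pytest.approx(1.0)
        other = flat.copy()
        other[:, 1] = np.arange(5)  # y now varies in one pose only
        b = _pose("b", a.ref_atoms, other)
        with pytest.warns(UserWarning):
            assert pose_min_correlation(a, b) == 0.0


class TestSimilarityThresholds:
    def _pair(self, rng, angle_deg):
        ref = rng.normal(size=(6, 3))
        ref -= ref.mean(0)
        mob = rng.normal(size=(8, 3))
        mob -= mob.mean(0)
        d = 20.0
        a = _pose("a", ref, mob + np.array([d, 0, 0]))
        rad = np.radians(angle_deg)
        b = _pose("b", ref, mob + d * np.array([np.cos(rad), np.sin(rad), 0]))
        return a, b

    def test_strict_inequalities_on_both_measures(self, rng):
        a, b = self._pair(rng, 30.0)
        vertex = np.zeros(3)
        s = pose_similarity(a, b, vertex)
        assert s.angle_deg == pytest.approx(30.0)
        assert s.similar  # angle 30 < 45, corr 1 > 0.5
        # exactly at the angle bound -> dissimilar (strict "<")
        assert not pose_similarity(a, b, vertex, angle_max=s.angle_deg).similar
        # exactly at the correlation bound -> dissimilar (strict ">")
        assert not pose_similarity(
            a, b, vertex, corr_min=s.min_axis_corr
        ).similar

    def test_wide_angle_dissimilar_despite_high_correlation(self, rng):
        a, b = self._pair(rng, 50.0)
        s = pose_similarity(a, b, np.zeros(3))
        assert s.min_axis_corr > 0.9
        assert not s.similar

    def test_measures_symmetric(self, rng):
        a, b = self._pair(rng, 37.0)
        vertex = np.zeros(3)
        assert pose_angle(a, b, vertex) == pytest.approx(
            pose_angle(b, a, vertex)
        )
        assert pose_min_correlation(a, b) == pytest.approx(
            pose_min_correlation(b, a)
        )


def test_angles_and_verdicts_invariant_to_global_rigid_transform(rng):
    """Rotating/shifting the whole input must not change the clustering.

    The inter-centroid angle is frame-free.  Per-axis correlations are
    computed in the frame of the chosen reference pose, which rotates with
    the input, so only the similarity verdicts — not the raw correlations —
    are asserted; on planted well-separated families they are stable.
    """
    poses, _ = gen_dimer_poses(
        PoseFamilySpec(n_clusters=2, poses_per_cluster=4, n_singletons=2,
                       atoms_per_subunit=10, noise_sd=0.3, seed=9)
    )
    sim0, table0 = similarity_matrix(superpose_poses(poses, poses[0].pose_id))
    R, t = _rigid(rng)
    moved = [
        DimerPose(p.pose_id, p.allele, p.ref_atoms @ R.T + t,
                  p.mob_atoms @ R.T + t)
        for p in poses
    ]
    sim1, table1 = similarity_matrix(superpose_poses(moved, moved[0].pose_id))
    assert np.allclose(table0["angle_deg"], table1["angle_deg"], atol=1e-6)
    assert np.array_equal(sim0, sim1)


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def brute_force_clusters(sim: np.ndarray, ids: list[str], min_group: int):
    """Oracle: exhaustive clique enumeration plus transitive merging."""
    n = len(ids)
    nodes = list(range(n))
    all_cliques = []
    for size in range(min_group, n + 1):
        for sub in combinations(nodes, size):
            if all(sim[i, j] for i, j in combinations(sub, 2)):
                all_cliques.append(set(sub))
    maximal = [
        c for c in all_cliques
        if not any(c < other for other in all_cliques)
    ]
    merged = [set(c) for c in maximal]
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                if merged[i] & merged[j]:
                    merged[i] |= merged.pop(j)
                    changed = True
                    break
            if changed:
                break
    clusters = {frozenset(ids[i] for i in c) for c in merged}
    clustered = set().union(*merged) if merged else set()
    unclustered = frozenset(ids[i] for i in set(nodes) - clustered)
    return clusters, unclustered


def _random_sim(rng, n, p):
    m = rng.random((n, n)) < p
    m = np.triu(m, 1)
    return m | m.T


class TestFindClusters:
    def _ids(self, n):
        return [f"p{i}" for i in range(n)]

    def _from_edges(self, n, edges):
        m = np.zeros((n, n), dtype=bool)
        for i, j in edges:
            m[i, j] = m[j, i] = True
        return m

    def test_triangle_below_minimum_group_size(self):
        sim = self._from_edges(3, [(0, 1), (0, 2), (1, 2)])
        cs = find_clusters(sim, self._ids(3), min_group=4)
        assert cs.clusters == ()
        assert cs.unclustered == frozenset(self._ids(3))

    def test_two_disjoint_five_cliques(self):
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        edges += [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
        cs = find_clusters(self._from_edges(10, edges), self._ids(10))
        assert {frozenset(c) for c in cs.clusters} == {
            frozenset(f"p{i}" for i in range(5)),
            frozenset(f"p{i}" for i in range(5, 10)),
        }
        assert cs.unclustered == frozenset()

    def test_overlapping_cliques_merge_to_one_cluster(self):
        # two 4-cliques sharing poses 2 and 3 -> one merged cluster of 6
        a = [0, 1, 2, 3]
        b = [2, 3, 4, 5]
        edges = [(i, j) for i, j in combinations(a, 2)]
        edges += [(i, j) for i, j in combinations(b, 2)]
        cs = find_clusters(self._from_edges(6, edges), self._ids(6))
        assert len(cs.clusters) == 1
        assert cs.clusters[0] == frozenset(self._ids(6))

    def test_empty_input(self):
        cs = find_clusters(np.zeros((0, 0), dtype=bool), [], min_group=4)
        assert cs == ClusterSet((), frozenset(), {})

    def test_asymmetric_matrix_rejected(self):
        m = np.zeros((2, 2), dtype=bool)
        m[0, 1] = True
        with pytest.raises(ValueError):
            find_clusters(m, self._ids(2))

    @pytest.mark.parametrize("min_group", [2, 3, 4])
    def test_matches_brute_force_oracle(self, rng, min_group):
        for _ in range(60):
            n = int(rng.integers(4, 13))
            sim = _random_sim(rng, n, rng.uniform(0.2, 0.8))
            ids = self._ids(n)
            cs = find_clusters(sim, ids, min_group=min_group)
            expected_clusters, expected_unclustered = brute_force_clusters(
                sim, ids, min_group
            )
            assert {frozenset(c) for c in cs.clusters} == expected_clusters
            assert cs.unclustered == expected_unclustered

    def test_clusters_pairwise_disjoint(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 13))
            sim = _random_sim(rng, n, 0.6)
            cs = find_clusters(sim, self._ids(n), min_group=3)
            seen = set()
            for c in cs.clusters:
                assert not (seen & c)
                seen |= c


class TestRepresentative:
    def test_deterministic_under_seed(self):
        cluster = frozenset(f"p{i}" for i in range(7))
        picks = {pick_representative(cluster, 42) for _ in range(10)}
        assert len(picks) == 1

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            pick_representative(frozenset(), 0)

    def test_uniform_within_three_standard_errors(self):
        cluster = frozenset(f"p{i}" for i in range(5))
        rng = np.random.default_rng(7)
        draws = [pick_representative(cluster, rng) for _ in range(10_000)]
        counts = {p: draws.count(p) for p in cluster}
        expect = 10_000 / 5
        se = np.sqrt(10_000 * 0.2 * 0.8)
        for c in counts.values():
            assert abs(c - expect) < 3 * se


def test_planted_clusters_recovered_with_moderate_noise():
    spec = PoseFamilySpec(n_clusters=3, poses_per_cluster=5, n_singletons=4,
                          atoms_per_subunit=20, noise_sd=0.5, seed=123)
    poses, labels = gen_dimer_poses(spec)
    cs, _, _ = cluster_poses(poses, seed=0)
    truth = {}
    for pose, lab in zip(poses, labels):
        truth.setdefault(lab, set()).add(pose.pose_id)
    expected = {frozenset(v) for k, v in truth.items() if k >= 0}
    assert {frozenset(c) for c in cs.clusters} == expected
    assert cs.unclustered == frozenset(truth.get(-1, set()))
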