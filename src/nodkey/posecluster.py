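"""Clustering of receptor-heterodimer docking poses.

Rigid-body docking of the Sym10 ectodomain onto a fixed LykX ectodomain yields
tens of candidate heterodimer poses per allele.  To reduce them to a few
distinct binding modes, every pose is first superposed on a common LykX frame
by Procrustes analysis (proper rotation + translation, no scaling), so that
all variability is concentrated in the Sym10 placement.  Two poses are then
compared by two measures:

* the angle at the LykX centroid between the vectors pointing to the two
  Sym10 centroids, and
* the minimum over X/Y/Z of the Pearson correlation between corresponding
  Sym10 atom coordinates.

Poses are *similar* when the angle is strictly below ``angle_max`` (45° by
default) and the minimal correlation strictly above ``corr_min`` (0.5).
Clusters are groups of at least ``min_group`` pairwise-similar poses (maximal
cliques of the similarity graph); overlapping groups are merged until the
clusters are disjoint, and one representative pose per cluster is drawn
uniformly at random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DimerPose:
    """One docking pose: reference (LykX) and mobile (Sym10) point sets in Å."""

    pose_id: str
    allele: str
    ref_atoms: np.ndarray
    mob_atoms: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.ref_atoms, dtype=float)
        mob = np.asarray(self.mob_atoms, dtype=float)
        if ref.ndim != 2 or ref.shape[1] != 3:
            raise ValueError(f"pose {self.pose_id}: ref_atoms must be (n, 3)")
        if mob.ndim != 2 or mob.shape[1] != 3:
            raise ValueError(f"pose {self.pose_id}: mob_atoms must be (m, 3)")
        if ref.shape[0] < 3:
            raise ValueError(f"pose {self.pose_id}: need >= 3 reference atoms")
        object.__setattr__(self, "ref_atoms", ref)
        object.__setattr__(self, "mob_atoms", mob)


@dataclass(frozen=True)
class PoseSimilarity:
    angle_deg: float
    min_axis_corr: float
    similar: bool


@dataclass(frozen=True)
class ClusterSet:
    clusters: tuple[frozenset[str], ...]
    unclustered: frozenset[str]
    representatives: dict[int, str]


class DegenerateGeometryError(ValueError):
    """Raised when reference atoms are collinear and superposition is ill-posed."""


def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid map ``x -> R @ x + t`` taking `moving` onto `target`.

    The rotation is forced proper (det = +1) by sign-correcting the smallest
    singular direction; reflections are never returned.  Collinear point sets
    make the rotation about the degenerate axis undefined and raise
    :class:`DegenerateGeometryError`.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point sets differ in shape: {P.shape} vs {Q.shape}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    scale = max(S[0], 1e-12)
    if S[1] / scale < 1e-8:
        raise DegenerateGeometryError(
            "reference atoms are (nearly) collinear; rigid superposition "
            "is ill-conditioned"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def superpose_poses(
    poses: list[DimerPose], reference_pose_id: str
) -> list[DimerPose]:
    """Superpose every pose on the reference pose's LykX subunit.

    Each pose is rigidly transformed so that its ref_atoms best match the
    reference pose's ref_atoms in the least-squares sense; mob_atoms are
    carried along by the same rigid map.
    """
    by_id = {p.pose_id: p for p in poses}
    if reference_pose_id not in by_id:
        raise KeyError(f"unknown reference pose {reference_pose_id!r}")
    ref = by_id[reference_pose_id]
    n_ref = ref.ref_atoms.shape[0]
    out = []
    for pose in poses:
        if pose.ref_atoms.shape[0] != n_ref:
            raise ValueError(
                f"pose {pose.pose_id}: {pose.ref_atoms.shape[0]} reference "
                f"atoms, expected {n_ref}"
            )
        R, t = kabsch(pose.ref_atoms, ref.ref_atoms)
        out.append(
            replace(
                pose,
                ref_atoms=pose.ref_atoms @ R.T + t,
                mob_atoms=pose.mob_atoms @ R.T + t,
            )
        )
    return out


def pose_angle(
    pose_i: DimerPose, pose_j: DimerPose, vertex: np.ndarray | None = None
) -> float:
    """Angle (degrees) at the LykX centroid between the two Sym10 centroids.

    Poses must already be superposed on a common LykX frame.  The vertex
    defaults to the centroid of ``pose_i``'s reference subunit (all reference
    copies nearly coincide after superposition).
    """
    if vertex is None:
        vertex = pose_i.ref_atoms.mean(axis=0)
    u = pose_i.mob_atoms.mean(axis=0) - vertex
    v = pose_j.mob_atoms.mean(axis=0) - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise ValueError("Sym10 centroid coincides with the LykX centroid")
    cosang = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def pose_min_correlation(pose_i: DimerPose, pose_j: DimerPose) -> float:
    """Minimum over X/Y/Z of the Pearson correlation of Sym10 coordinates.

    Correlations pair corresponding atoms, so both poses must list their
    mobile atoms in the same order.  An axis with zero variance in either
    pose has no defined Pearson correlation: if both axes are constant and
    equal it contributes 1, otherwise 0, and a warning is emitted.
    """
    A, B = pose_i.mob_atoms, pose_j.mob_atoms
    if A.shape != B.shape:
        raise ValueError(
            f"poses {pose_i.pose_id} and {pose_j.pose_id} have different "
            "mobile atom counts"
        )
    corrs = []
    for ax in range(3):
        a, b = A[:, ax], B[:, ax]
        sa, sb = a.std(), b.std()
        if sa < 1e-12 or sb < 1e-12:
            warnings.warn(
                f"zero-variance axis {ax} between poses "
                f"{pose_i.pose_id} and {pose_j.pose_id}",
                stacklevel=2,
            )
            corrs.append(1.0 if (sa < 1e-12 and sb < 1e-12
                                 and np.allclose(a, b)) else 0.0)
        else:
            corrs.append(float(np.corrcoef(a, b)[0, 1]))
    return min(corrs)


def pose_similarity(
    pose_i: DimerPose,
    pose_j: DimerPose,
    vertex: np.ndarray | None = None,
    angle_max: float = 45.0,
    corr_min: float = 0.5,
) -> PoseSimilarity:
    """Two-measure similarity verdict; thresholds are strict inequalities."""
    angle = pose_angle(pose_i, pose_j, vertex)
    corr = pose_min_correlation(pose_i, pose_j)
    return PoseSimilarity(
        angle_deg=angle,
        min_axis_corr=corr,
        similar=(angle < angle_max) and (corr > corr_min),
    )


def similarity_matrix(
    poses: list[DimerPose],
    angle_max: float = 45.0,
    corr_min: float = 0.5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Symmetric boolean similarity matrix plus the pairwise measure table.

    Poses must be pre-superposed; the angle vertex is the first pose's LykX
    centroid.  The diagonal is False (a pose is not its own cluster partner).
    """
    n = len(poses)
    vertex = poses[0].ref_atoms.mean(axis=0) if n else None
    sim = np.zeros((n, n), dtype=bool)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            s = pose_similarity(poses[i], poses[j], vertex, angle_max, corr_min)
            sim[i, j] = sim[j, i] = s.similar
            rows.append(
                (poses[i].pose_id, poses[j].pose_id,
                 s.angle_deg, s.min_axis_corr, s.similar)
            )
    table = pd.DataFrame(
        rows, columns=["pose_i", "pose_j", "angle_deg", "min_axis_corr", "similar"]
    )
    return sim, table


def find_clusters(
    sim: np.ndarray,
    pose_ids: list[str],
    min_group: int = 4,
    seed: int | np.random.Generator = 0,
) -> ClusterSet:
    """Groups of >= `min_group` pairwise-similar poses, merged until disjoint.

    Maximal cliques of the similarity graph with at least `min_group` members
    are enumerated; cliques sharing any pose are merged transitively, so the
    returned clusters are pairwise disjoint.  Remaining poses are unclustered.
    A representative per cluster is drawn uniformly using `seed`.
    """
    sim = np.asarray(sim, dtype=bool)
    n = len(pose_ids)
    if sim.shape != (n, n):
        raise ValueError("similarity matrix shape does not match pose ids")
    if not np.array_equal(sim, sim.T):
        raise ValueError("similarity matrix must be symmetric")

    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(zip(*np.nonzero(np.triu(sim, k=1))))
    cliques = [frozenset(c) for c in nx.find_cliques(g) if len(c) >= min_group]

    # merge cliques with non-empty intersection until a fixed point:
    # connected components of the clique-overlap graph.
    overlap = nx.Graph()
    overlap.add_nodes_from(range(len(cliques)))
    for a in range(len(cliques)):
        for b in range(a + 1, len(cliques)):
            if cliques[a] & cliques[b]:
                overlap.add_edge(a, b)
    merged = []
    for comp in nx.connected_components(overlap):
        members: set[int] = set()
        for ci in comp:
            members |= cliques[ci]
        merged.append(frozenset(pose_ids[i] for i in members))
    merged.sort(key=lambda c: min(pose_ids.index(p) for p in c))

    clustered = frozenset().union(*merged) if merged else frozenset()
    unclustered = frozenset(pose_ids) - clustered
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    reps = {k: pick_representative(c, rng) for k, c in enumerate(merged)}
    return ClusterSet(
        clusters=tuple(merged), unclustered=unclustered, representatives=reps
    )


def pick_representative(
    cluster: frozenset[str] | set[str], seed: int | np.random.Generator
) -> str:
    """Uniform random choice of a typical pose, reproducible under `seed`."""
    if not cluster:
        raise ValueError("cannot pick a representative of an empty cluster")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    members = sorted(cluster)
    return members[int(rng.integers(len(members)))]


def cluster_poses(
    poses: list[DimerPose],
    reference_pose_id: str | None = None,
    angle_max: float = 45.0,
    corr_min: float = 0.5,
    min_group: int = 4,
    seed: int = 0,
) -> tuple[ClusterSet, pd.DataFrame, list[DimerPose]]:
    """Superpose, score all pairs, and cluster; the full pipeline step.

    Returns the cluster set, the pairwise-measure table and the superposed
    poses (so they can be re-written as PDB).
    """
    if not poses:
        return ClusterSet((), frozenset(), {}), pd.DataFrame(
            columns=["pose_i", "pose_j", "angle_deg", "min_axis_corr", "similar"]
        ), []
    if reference_pose_id is None:
        reference_pose_id = poses[0].pose_id
    aligned = superpose_poses(poses, reference_pose_id)
    sim, table = similarity_matrix(aligned, angle_max, corr_min)
    cs = find_clusters(sim, [p.pose_id for p in aligned], min_group, seed)
    return cs, table, aligned
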