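"""Membrane-topology filtering and QT-like clustering of docking poses.

Rigid-body docking of transmembrane protomers (the docking engine
itself is external; poses are inputs) produces rotation + translation
transforms of a mobile protomer against a fixed, membrane-embedded
target.  Solutions that violate membrane topology are discarded using
two analytics computed per pose:

* **tilt** — the deviation angle of the membrane normal (+z by
  convention) under the pose rotation, in [0, π];
* **z-offset** — the absolute vertical displacement of the protomer's
  geometric centre.

Default thresholds are deliberately permissive: tilt ≤ 0.4 rad and
z-offset ≤ 6.0 Å.  At most the 4000 best-scored solutions are
considered.  Surviving poses are clustered by pairwise Cα-RMSD
(threshold 3.0 Å) with a QT-like greedy algorithm: the pose with the
most within-threshold neighbours becomes a cluster centre, it and its
neighbours are removed, and the process repeats.  RMSD is computed in
the common frame of the fixed target without re-superposition, since
all solutions share the same immobile protomer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "ProtomerStructure",
    "Pose",
    "TopologyParams",
    "TopologyMetrics",
    "PoseCluster",
    "read_ca_coordinates",
    "apply_pose",
    "topology_metrics",
    "filter_poses",
    "pairwise_rmsd",
    "rmsd_matrix",
    "qt_cluster",
    "plant_pose_clusters",
]


@dataclass
class ProtomerStructure:
    """Ordered Cα coordinates (Å) of one protomer chain.

    ``membrane_normal`` is the unit vector of the membrane normal in the
    docking frame; by convention the frame is oriented so this is +z.
    """

    ca_coords: np.ndarray
    chain_id: str = "A"
    membrane_normal: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=np.float64).reshape(-1, 3)
        if len(self.ca_coords) < 3:
            raise ValueError("a protomer needs at least 3 Cα atoms")
        if np.linalg.matrix_rank(self.ca_coords - self.ca_coords.mean(axis=0)) < 2:
            raise ValueError("Cα coordinates must not be collinear")
        if self.membrane_normal is None:
            self.membrane_normal = np.array([0.0, 0.0, 1.0])
        self.membrane_normal = np.asarray(self.membrane_normal, dtype=np.float64)
        norm = np.linalg.norm(self.membrane_normal)
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValueError("membrane_normal must be a unit vector")

    @property
    def centroid(self) -> np.ndarray:
        return self.ca_coords.mean(axis=0)


@dataclass(frozen=True)
class Pose:
    """A rigid-body transform x ↦ R·x + t with an external docking score."""

    rotation: np.ndarray
    translation: np.ndarray
    score: float = 0.0
    id: int = -1

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if np.linalg.norm(R.T @ R - np.eye(3)) >= 1e-6 or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det = +1")


@dataclass(frozen=True)
class TopologyParams:
    """Thresholds of the membrane-topology filter and the pose clustering."""

    tilt_max: float = 0.4  # radians
    zoffset_max: float = 6.0  # Å
    rmsd_threshold: float = 3.0  # Å
    max_solutions: int = 4000

    def __post_init__(self) -> None:
        if min(self.tilt_max, self.zoffset_max, self.rmsd_threshold) <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_solutions <= 0:
            raise ValueError("max_solutions must be positive")


@dataclass(frozen=True)
class TopologyMetrics:
    tilt: float
    z_offset: float
    passes: bool


@dataclass(frozen=True)
class PoseCluster:
    """A QT cluster: members, the most-neighboured centre, population."""

    member_ids: Tuple[int, ...]
    center_id: int
    population: int

    def __post_init__(self) -> None:
        if self.center_id not in self.member_ids:
            raise ValueError("cluster centre must be a member")
        if self.population != len(self.member_ids):
            raise ValueError("population must equal the member count")


def read_ca_coordinates(path, chain: str = "A") -> ProtomerStructure:
    """Read the Cα trace of one chain from a PDB file (residue order).

    Raises ``ValueError`` naming the offending line for malformed ATOM
    records, and if the chain has no Cα atoms.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) >= 54:
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError:
                    raise ValueError(
                        f"{path}: malformed ATOM record at line {lineno}: "
                        f"{line.rstrip()!r}"
                    ) from None
            elif line.startswith(("ATOM", "HETATM")):
                raise ValueError(
                    f"{path}: truncated ATOM record at line {lineno}"
                )

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("protomer", str(path))
    except PDBConstructionException as exc:  # pragma: no cover - defensive
        raise ValueError(f"{path}: PDB parse error: {exc}") from exc

    coords = []
    model = next(structure.get_models())
    for ch in model:
        if ch.id != chain:
            continue
        for residue in ch:
            if "CA" in residue:
                coords.append(residue["CA"].get_coord())
    if not coords:
        raise ValueError(f"{path}: no Cα atoms found for chain {chain!r}")
    return ProtomerStructure(ca_coords=np.array(coords, dtype=np.float64), chain_id=chain)


def apply_pose(structure: ProtomerStructure, pose: Pose) -> np.ndarray:
    """Transformed Cα coordinates: R·x + t for every atom."""
    return structure.ca_coords @ pose.rotation.T + pose.translation


def topology_metrics(
    structure: ProtomerStructure, pose: Pose, params: TopologyParams | None = None
) -> TopologyMetrics:
    """Tilt and z-offset of a pose, with the pass/fail verdict.

    tilt = angle between the membrane normal and its image under the
    pose rotation; z_offset = |vertical displacement of the geometric
    centre|.  A pose passes iff tilt ≤ tilt_max and z_offset ≤
    zoffset_max.
    """
    params = params or TopologyParams()
    n = structure.membrane_normal
    cosang = float(np.clip(np.dot(n, pose.rotation @ n), -1.0, 1.0))
    tilt = float(np.arccos(cosang))
    c = structure.centroid
    z_offset = float(abs((pose.rotation @ c + pose.translation - c)[2]))
    passes = tilt <= params.tilt_max and z_offset <= params.zoffset_max
    return TopologyMetrics(tilt=tilt, z_offset=z_offset, passes=passes)


def filter_poses(
    structure: ProtomerStructure,
    poses: Sequence[Pose],
    params: TopologyParams | None = None,
) -> List[Pose]:
    """Retain the best-scored solutions that satisfy membrane topology.

    The input is first truncated to the ``max_solutions`` best-scored
    poses (higher score = better, stable for ties), then the topology
    filter is applied; the output preserves the score ranking.
    """
    params = params or TopologyParams()
    ranked = sorted(poses, key=lambda p: -p.score)[: params.max_solutions]
    return [p for p in ranked if topology_metrics(structure, p, params).passes]


def pairwise_rmsd(structure: ProtomerStructure, pose_a: Pose, pose_b: Pose) -> float:
    """Cα-RMSD between two placements of the same protomer.

    Computed in the common frame of the fixed docking target — no
    re-superposition — so it is zero iff the two transforms act
    identically on the structure, and a pure relative translation d
    gives exactly ‖d‖.
    """
    diff = apply_pose(structure, pose_a) - apply_pose(structure, pose_b)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def rmsd_matrix(structure: ProtomerStructure, poses: Sequence[Pose]) -> np.ndarray:
    """Symmetric matrix of pairwise Cα-RMSDs (common-frame convention)."""
    placed = np.stack([apply_pose(structure, p) for p in poses]) if poses else np.empty((0, 0, 3))
    m = len(poses)
    out = np.zeros((m, m))
    for i in range(m):
        diff = placed[i + 1 :] - placed[i]
        if len(diff):
            vals = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
            out[i, i + 1 :] = vals
            out[i + 1 :, i] = vals
    return out


def qt_cluster(
    structure: ProtomerStructure,
    poses: Sequence[Pose],
    params: TopologyParams | None = None,
) -> List[PoseCluster]:
    """QT-like greedy clustering of (filtered) poses by Cα-RMSD.

    Repeatedly, among unassigned poses, the one with the most
    within-threshold neighbours (ties: lowest pose id) becomes a cluster
    centre; it and its unassigned neighbours form a cluster and are
    removed.  Clusters come out in extraction order, which is
    non-increasing in population.
    """
    params = params or TopologyParams()
    if not poses:
        return []
    ids = [p.id if p.id >= 0 else k for k, p in enumerate(poses)]
    if len(set(ids)) != len(ids):
        raise ValueError("pose ids must be unique")
    dmat = rmsd_matrix(structure, poses)
    within = dmat <= params.rmsd_threshold
    np.fill_diagonal(within, False)

    unassigned = set(range(len(poses)))
    clusters: List[PoseCluster] = []
    while unassigned:
        # neighbour counts restricted to unassigned poses
        best = min(
            unassigned,
            key=lambda k: (-sum(1 for j in unassigned if within[k, j]), ids[k]),
        )
        members = {best} | {j for j in unassigned if within[best, j]}
        clusters.append(
            PoseCluster(
                member_ids=tuple(sorted(ids[m] for m in members)),
                center_id=ids[best],
                population=len(members),
            )
        )
        unassigned -= members
    return clusters


def plant_pose_clusters(
    n_clusters: int = 3,
    members_per_cluster: int = 5,
    seed: int = 0,
    rmsd_threshold: float = 3.0,
    separation_factor: float = 4.0,
) -> Tuple[List[Pose], List[int]]:
    """Seeded synthetic pose set with planted clusters (pure translations).

    Cluster centres are translations spaced ``separation_factor ×
    rmsd_threshold`` apart; members jitter around their centre by less
    than ``rmsd_threshold / 2``, so for separation > 2× threshold the
    planted partition is exactly recoverable.  For pure translations the
    common-frame Cα-RMSD equals the Euclidean distance between
    translation vectors, making the geometry exact by construction.

    Returns ``(poses, labels)`` with one planted label per pose.
    """
    rng = np.random.default_rng(seed)
    eye = np.eye(3)
    poses: List[Pose] = []
    labels: List[int] = []
    pid = 0
    for c in range(n_clusters):
        center = np.array([c * separation_factor * rmsd_threshold, 0.0, 0.0])
        for _ in range(members_per_cluster):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = rng.uniform(0.0, 0.49 * rmsd_threshold)
            poses.append(
                Pose(
                    rotation=eye,
                    translation=center + radius * direction,
                    score=float(rng.uniform(0.0, 10.0)),
                    id=pid,
                )
            )
            labels.append(c)
            pid += 1
    return poses, labels
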