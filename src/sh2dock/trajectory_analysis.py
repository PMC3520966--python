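"""Post-MD trajectory analytics.

Preprocessing strips solvent and counterions, centers each frame and
superposes it onto the first frame by mass-weighted Kabsch fitting.  On the
fitted ensemble the module computes the pose-stability RMSF (the
frame-averaged mass-weighted RMSD of the ligand to frame 1 — note this is
deliberately NOT the conventional per-atom fluctuation, which is available
separately as :func:`rmsf_per_atom`), k-means conformational clustering
with medoid representatives, geometric hydrogen-bond detection, and
per-residue hydrogen-bond occupancy with the 50% retention rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation
from sklearn.cluster import KMeans

from . import params
from .molecules import Trajectory

__all__ = [
    "FittedTrajectory",
    "ClusterResult",
    "HBond",
    "OccupancyTable",
    "strip_solvent",
    "fit_trajectory",
    "weighted_rmsd",
    "rmsf",
    "rmsf_per_atom",
    "cluster_kmeans",
    "detect_hbonds",
    "occupancy",
]


@dataclass
class FittedTrajectory:
    """Frames after stripping, centering and superposition onto frame 1."""

    traj: Trajectory
    fitted_rmsd: np.ndarray  # mass-weighted RMSD of each frame to frame 1

    @property
    def coords(self) -> np.ndarray:
        return self.traj.coords

    @property
    def n_frames(self) -> int:
        return self.traj.n_frames


@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray
    representatives: np.ndarray  # medoid frame index per cluster
    within_rmsd: np.ndarray  # mean RMSD to medoid per cluster
    degenerate: bool = False


@dataclass
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    receptor_residue: int
    presence: np.ndarray  # per-frame boolean

    @property
    def occupancy(self) -> float:
        return float(self.presence.mean())


@dataclass
class OccupancyTable:
    residues: np.ndarray
    occupancy: np.ndarray
    retained: np.ndarray
    threshold: float = 0.5

    def as_dict(self) -> dict[int, float]:
        return {int(r): float(o) for r, o in zip(self.residues, self.occupancy)}


def weighted_rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Mass-weighted RMSD between two already-superposed coordinate sets."""
    if weights is None:
        weights = np.ones(len(a))
    w = weights / weights.sum()
    d2 = np.einsum("ij,ij->i", a - b, a - b)
    return float(np.sqrt((w * d2).sum()))


def strip_solvent(traj: Trajectory) -> Trajectory:
    """Remove water and counterion atoms (by residue name) from a trajectory."""
    if traj.residue_names is None:
        return traj
    drop = params.WATER_RESNAMES | params.ION_RESNAMES
    keep = np.array([rn.upper() not in drop for rn in traj.residue_names])
    if keep.all():
        return traj
    idx_map = -np.ones(traj.n_atoms, dtype=int)
    idx_map[keep] = np.arange(keep.sum())

    def remap(indices):
        if indices is None:
            return None
        kept = [idx_map[i] for i in indices if keep[i]]
        return np.array(kept, dtype=int)

    return Trajectory(
        coords=traj.coords[:, keep],
        atoms=[a for a, k in zip(traj.atoms, keep) if k],
        frame_spacing=traj.frame_spacing,
        receptor_indices=remap(traj.receptor_indices),
        ligand_indices=remap(traj.ligand_indices),
        residue_numbers=traj.residue_numbers[keep] if traj.residue_numbers is not None else None,
        residue_names=[rn for rn, k in zip(traj.residue_names, keep) if k],
    )


def fit_trajectory(
    traj: Trajectory, weights: np.ndarray | None = None, strip: bool = True
) -> FittedTrajectory:
    """Center every frame and superpose it onto frame 1 (Kabsch, mass-weighted).

    Only proper rotations are used.  Raises on frames whose fitting problem
    is degenerate (< 3 atoms or collinear coordinates).
    """
    if strip:
        traj = strip_solvent(traj)
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    if weights is None:
        weights = traj.masses()
    w = weights / weights.sum()

    coords = traj.coords.copy()
    centers = np.einsum("fij,i->fj", coords, w)
    coords -= centers[:, None, :]

    ref = coords[0]
    if traj.n_atoms < 3:
        raise ValueError("frame 0: fewer than 3 atoms — superposition is degenerate")
    rmsds = np.zeros(traj.n_frames)
    for f in range(traj.n_frames):
        spread = np.linalg.matrix_rank(coords[f] - coords[f].mean(axis=0), tol=1e-9)
        if spread < 2:
            raise ValueError(f"frame {f}: collinear coordinates — superposition is degenerate")
        rot, _ = Rotation.align_vectors(ref, coords[f], weights=w)
        coords[f] = rot.apply(coords[f])
        rmsds[f] = weighted_rmsd(coords[f], ref, weights)

    fitted = Trajectory(
        coords=coords,
        atoms=traj.atoms,
        frame_spacing=traj.frame_spacing,
        receptor_indices=traj.receptor_indices,
        ligand_indices=traj.ligand_indices,
        residue_numbers=traj.residue_numbers,
        residue_names=traj.residue_names,
    )
    return FittedTrajectory(traj=fitted, fitted_rmsd=rmsds)


def _subset_indices(fitted: FittedTrajectory, atom_subset) -> np.ndarray:
    if atom_subset is None:
        atom_subset = fitted.traj.ligand_indices
    if atom_subset is None:
        atom_subset = np.arange(fitted.traj.n_atoms)
    subset = np.asarray(atom_subset, dtype=int)
    if subset.size == 0:
        raise ValueError("empty atom subset")
    return subset


def rmsf(fitted: FittedTrajectory, atom_subset=None, weights: np.ndarray | None = None) -> float:
    """Pose-stability RMSF: mean over frames 2..N of the mass-weighted RMSD
    of the subset (default: ligand) to its conformation in frame 1.
    """
    if fitted.n_frames < 2:
        raise ValueError("need at least 2 frames")
    subset = _subset_indices(fitted, atom_subset)
    if weights is None:
        weights = fitted.traj.masses()[subset]
    ref = fitted.coords[0, subset]
    vals = [
        weighted_rmsd(fitted.coords[f, subset], ref, weights)
        for f in range(1, fitted.n_frames)
    ]
    return float(np.mean(vals))


def rmsf_per_atom(fitted: FittedTrajectory, atom_subset=None) -> np.ndarray:
    """Conventional per-atom RMSF: √⟨|x − ⟨x⟩|²⟩ over frames, per atom."""
    subset = _subset_indices(fitted, atom_subset)
    x = fitted.coords[:, subset]
    mean = x.mean(axis=0)
    return np.sqrt(np.einsum("fij,fij->i", x - mean, x - mean) / x.shape[0])


def _farthest_point_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [int(rng.integers(len(X)))]
    d2 = np.einsum("ij,ij->i", X - X[centers[0]], X - X[centers[0]])
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        centers.append(nxt)
        d2 = np.minimum(d2, np.einsum("ij,ij->i", X - X[nxt], X - X[nxt]))
    return X[centers]


def cluster_kmeans(
    fitted: FittedTrajectory,
    k: int = 5,
    seed: int = 0,
    atom_subset=None,
    weights: np.ndarray | None = None,
) -> ClusterResult:
    """k-means clustering of ligand conformations with RMSD as the metric.

    On the fitted (pre-superposed) ensemble the mass-weighted RMSD between
    frames is a Euclidean distance on √w-scaled flattened coordinates, so
    standard k-means applies.  Initialization is farthest-point seeding from
    a seeded RNG; the representative of each cluster is its medoid (minimum
    summed RMSD within the cluster).
    """
    if k > fitted.n_frames:
        raise ValueError("k exceeds the number of frames")
    subset = _subset_indices(fitted, atom_subset)
    if weights is None:
        weights = fitted.traj.masses()[subset]
    w = weights / weights.sum()
    scaled = fitted.coords[:, subset] * np.sqrt(w)[None, :, None]
    X = scaled.reshape(fitted.n_frames, -1)

    rng = np.random.default_rng(seed)
    init = _farthest_point_init(X, k, rng)
    km = KMeans(n_clusters=k, init=init, n_init=1, random_state=seed)
    labels = km.fit_predict(X)

    reps = np.zeros(k, dtype=int)
    within = np.zeros(k)
    degenerate = len(np.unique(labels)) < k
    for c in range(k):
        members = np.where(labels == c)[0]
        if members.size == 0:
            reps[c] = -1
            continue
        diffs = X[members][:, None, :] - X[members][None, :, :]
        dmat = np.sqrt(np.einsum("ijk,ijk->ij", diffs, diffs))
        medoid_local = int(np.argmin(dmat.sum(axis=1)))
        reps[c] = members[medoid_local]
        within[c] = dmat[medoid_local].mean()
    return ClusterResult(k=k, labels=labels, representatives=reps, within_rmsd=within, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Hydrogen bonds


@dataclass
class HBondCriteria:
    max_distance: float = 3.5  # donor-heavy-atom to acceptor, Å
    min_angle: float = 120.0  # donor–H···acceptor, degrees


def _donor_pairs(traj: Trajectory, indices: np.ndarray, ref_frame: int = 0):
    """(heavy, H) donor pairs: each flagged H paired with its nearest heavy atom."""
    pairs = []
    coords = traj.coords[ref_frame]
    heavy = [i for i in indices if traj.atoms[i].element != "H"]
    if not heavy:
        return pairs
    heavy_arr = np.array(heavy)
    for i in indices:
        if not traj.atoms[i].is_donor_h or traj.atoms[i].element != "H":
            continue
        d2 = np.einsum("ij,ij->i", coords[heavy_arr] - coords[i], coords[heavy_arr] - coords[i])
        j = int(heavy_arr[np.argmin(d2)])
        if d2.min() > 4.0:  # no covalent partner within 2.0 Å (jitter-tolerant)
            raise ValueError(f"flagged donor hydrogen {i} has no adjacent heavy atom")
        pairs.append((j, i))
    return pairs


def detect_hbonds(
    fitted: FittedTrajectory,
    receptor_residues: np.ndarray | None = None,
    criteria: HBondCriteria | None = None,
) -> list[HBond]:
    """Geometric hydrogen bonds between ligand and receptor, per frame.

    A bond is present in a frame iff the donor–acceptor distance is at most
    ``criteria.max_distance`` and the donor–H···acceptor angle is at least
    ``criteria.min_angle``.  Both directions (ligand donor → receptor
    acceptor and vice versa) are scanned.
    """
    criteria = criteria or HBondCriteria()
    traj = fitted.traj
    if traj.receptor_indices is None or traj.ligand_indices is None:
        raise ValueError("trajectory lacks receptor/ligand selections")
    rec_idx = traj.receptor_indices
    lig_idx = traj.ligand_indices
    if receptor_residues is None:
        if traj.residue_numbers is None:
            raise ValueError("receptor residue numbers unavailable")
        receptor_residues = traj.residue_numbers

    candidates = []  # (donor_heavy, H, acceptor, residue)
    for donor_heavy, h in _donor_pairs(traj, lig_idx):
        for acc in rec_idx:
            if traj.atoms[acc].is_acceptor:
                candidates.append((donor_heavy, h, acc, int(receptor_residues[acc])))
    for donor_heavy, h in _donor_pairs(traj, rec_idx):
        for acc in lig_idx:
            if traj.atoms[acc].is_acceptor:
                candidates.append((donor_heavy, h, acc, int(receptor_residues[donor_heavy])))

    bonds = []
    cos_min = np.cos(np.deg2rad(criteria.min_angle))
    for donor_heavy, h, acc, resnum in candidates:
        d_vec = traj.coords[:, acc] - traj.coords[:, donor_heavy]
        dist = np.linalg.norm(d_vec, axis=1)
        v1 = traj.coords[:, donor_heavy] - traj.coords[:, h]
        v2 = traj.coords[:, acc] - traj.coords[:, h]
        cosang = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1) + 1e-12
        )
        # angle >= min_angle  <=>  cos(angle) <= cos(min_angle)
        present = (dist <= criteria.max_distance) & (cosang <= cos_min)
        if present.any():
            bonds.append(
                HBond(donor=donor_heavy, hydrogen=h, acceptor=acc,
                      receptor_residue=resnum, presence=present)
            )
    return bonds


def occupancy(
    hbonds: list[HBond], n_frames: int, threshold: float = 0.5
) -> OccupancyTable:
    """Per-residue hydrogen-bond occupancy with the retention rule.

    A residue's occupancy is the fraction of frames in which it takes part
    in at least one hydrogen bond (union over its bonds); residues below
    the threshold (default 50% of frames) are flagged as dropped.
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    by_residue: dict[int, np.ndarray] = {}
    for hb in hbonds:
        acc = by_residue.setdefault(hb.receptor_residue, np.zeros(n_frames, dtype=bool))
        by_residue[hb.receptor_residue] = acc | hb.presence
    residues = np.array(sorted(by_residue))
    occ = np.array([by_residue[r].mean() for r in residues]) if len(residues) else np.empty(0)
    return OccupancyTable(
        residues=residues, occupancy=occ, retained=occ >= threshold, threshold=threshold
    )
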