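"""Anchor-constrained incremental docking (dock–select–grow–dock).

Large phosphopeptide mimetics (9–22 rotatable bonds) are docked a few
torsions at a time: the root fragment containing the phosphate anchor is
docked first, the best partial poses are kept, the ligand is grown by the
next few rotatable bonds in torsion-tree order, and the process repeats
until all bonds are active.  Selection at every step uses the scoring
function

    S = w · ‖x_P − x₀‖² + E

where x_P is the anchor (phosphorus) atom, x₀ the sub-pocket-1 center and
E the interaction energy of the partial pose — the quadratic term steers
the phosphate into the positively charged sub-pocket while the energy term
ranks conformations.  The inner search is seeded simulated-annealing Monte
Carlo over the rigid-body degrees of freedom plus the newly activated
torsions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .energy import EnergyModel, interaction_energy
from .molecules import Ligand, Pose, apply_pose

__all__ = [
    "DockingConfig",
    "PartialPose",
    "DockingResult",
    "score_S",
    "dock_increment",
    "incremental_dock",
]


@dataclass
class DockingConfig:
    """Knobs of the incremental protocol.

    ``distance_weight`` (w) is in (kcal/mol)/Å²; setting it to 0 recovers
    unconstrained energy-only docking.
    """

    subpocket_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    distance_weight: float = 1.0
    bonds_per_increment: int = 3
    n_keep: int = 16
    n_steps: int = 600
    n_restarts: int = 3
    temp_start: float = 5.0
    temp_end: float = 0.2
    final_polish: bool = True  # low-T refinement of completed poses, all DOF live
    translation_step: float = 0.75
    rotation_step: float = 0.35  # radians
    torsion_step: float = 0.6  # radians
    seed: int = 0

    def __post_init__(self) -> None:
        self.subpocket_center = np.asarray(self.subpocket_center, dtype=float)
        if self.distance_weight < 0:
            raise ValueError("distance_weight must be >= 0")
        if self.bonds_per_increment < 1 or self.n_keep < 1:
            raise ValueError("bonds_per_increment and n_keep must be >= 1")


@dataclass
class PartialPose:
    pose: Pose
    n_active_bonds: int
    score_s: float = np.inf
    energy: float = np.inf
    d2: float = np.inf


@dataclass
class DockingResult:
    poses: list[PartialPose]
    audit_log: list[dict]

    @property
    def best(self) -> PartialPose:
        return self.poses[0]


def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product of quaternions in (x, y, z, w) convention."""
    ax, ay, az, aw = a
    bx, by, bz, bw = b
    return np.array([
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
        aw * bw - ax * bx - ay * by - az * bz,
    ])


def score_S(
    lig_coords: np.ndarray, anchor_index: int, energy: float, config: DockingConfig
) -> tuple[float, float]:
    """The anchor-penalized docking score: S = w·d² + E."""
    delta = lig_coords[anchor_index] - config.subpocket_center
    d2 = float(delta @ delta)
    return config.distance_weight * d2 + energy, d2


def _active_mask(ligand, n_active: int) -> np.ndarray:
    """Atoms of the grown fragment: everything not moved solely by a
    not-yet-activated torsion.  Cached per ligand."""
    cache = getattr(ligand, "_active_mask_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(ligand, "_active_mask_cache", cache)
    if n_active not in cache:
        mask = np.ones(ligand.n_atoms, dtype=bool)
        for tb in ligand.torsion_bonds[n_active:]:
            mask &= ~tb.moving
        cache[n_active] = mask
    return cache[n_active]


def _evaluate(ligand, pose, anchor, receptor, grids, model, config) -> PartialPose:
    coords = apply_pose(ligand, pose)
    n_active = len(pose.torsions)
    mask = None if n_active >= ligand.n_rotatable else _active_mask(ligand, n_active)
    br = interaction_energy(coords, ligand, receptor=receptor, grids=grids,
                            model=model, atom_mask=mask)
    s, d2 = score_S(coords, anchor, br.total, config)
    return PartialPose(pose=pose, n_active_bonds=n_active, score_s=s, energy=br.total, d2=d2)


def _perturb(pose: Pose, rng: np.random.Generator, config: DockingConfig, frozen: int) -> Pose:
    """One Monte Carlo move: either a rigid-body step or a single live torsion."""
    trans = pose.translation
    quat = pose.rotation
    torsions = pose.torsions.copy()
    n_live = len(torsions) - frozen
    if n_live == 0 or rng.random() < 0.5:
        trans = trans + rng.normal(0.0, config.translation_step, 3)
        rv = rng.normal(0.0, config.rotation_step, 3)
        angle = np.sqrt(rv @ rv)
        axis = rv / angle if angle > 1e-12 else np.array([1.0, 0.0, 0.0])
        dq = np.append(np.sin(angle / 2) * axis, np.cos(angle / 2))
        quat = _quat_multiply(dq, quat)
        quat = quat / np.sqrt(quat @ quat)
    else:
        j = frozen + int(rng.integers(n_live))
        torsions[j] += rng.normal(0.0, config.torsion_step)
        torsions[j] = np.mod(torsions[j] + np.pi, 2 * np.pi) - np.pi
    return Pose(trans, quat, torsions)


def _anneal(ligand, start: PartialPose, frozen: int, receptor, grids, model, config, rng):
    """One simulated-annealing chain; returns every accepted state's best."""
    current = start
    best = start
    temps = np.geomspace(config.temp_start, config.temp_end, config.n_steps)
    for temp in temps:
        cand_pose = _perturb(current.pose, rng, config, frozen)
        cand = _evaluate(ligand, cand_pose, ligand.anchor_index(), receptor, grids, model, config)
        delta = cand.score_s - current.score_s
        if delta <= 0 or rng.random() < np.exp(-delta / temp):
            current = cand
            if cand.score_s < best.score_s:
                best = cand
    return best


def dock_increment(
    ligand: Ligand,
    n_active: int,
    seeds: list[PartialPose],
    config: DockingConfig,
    receptor=None,
    grids=None,
    model: EnergyModel | None = None,
    rng: np.random.Generator | None = None,
) -> list[PartialPose]:
    """Search with ``n_active`` torsions live, starting from seed partial poses.

    Previously placed torsions stay frozen; each seed is extended with the
    newly activated torsions (initialized at the reference geometry) and
    refined by annealing.  Returns the ``n_keep`` lowest-S poses; with
    ``config.n_steps == 0`` the seeds are only re-scored.
    """
    if not seeds:
        raise ValueError("empty seed set")
    model = model or EnergyModel()
    rng = rng or np.random.default_rng(config.seed)
    anchor = ligand.anchor_index()
    frozen = len(seeds[0].pose.torsions)
    if n_active - frozen > config.bonds_per_increment:
        raise ValueError("increment activates more bonds than bonds_per_increment")

    results: list[PartialPose] = []
    scan = np.linspace(-np.pi, np.pi, 24, endpoint=False)
    for seed_pose in seeds:
        torsions = np.concatenate(
            [seed_pose.pose.torsions, np.zeros(n_active - len(seed_pose.pose.torsions))]
        )
        pose = Pose(seed_pose.pose.translation, seed_pose.pose.rotation, torsions)
        # greedy coarse scan over each newly activated torsion: place every
        # grown segment in its best rotamer before stochastic refinement
        if config.n_steps > 0:
            for j in range(frozen, n_active):
                # only atoms grown so far count while choosing the rotamer
                mask = (None if j + 1 >= ligand.n_rotatable
                        else _active_mask(ligand, j + 1))
                best_theta, best_s = pose.torsions[j], np.inf
                for theta in scan:
                    pose.torsions[j] = theta
                    coords = apply_pose(ligand, pose)
                    br = interaction_energy(coords, ligand, receptor=receptor,
                                            grids=grids, model=model, atom_mask=mask)
                    s, _ = score_S(coords, anchor, br.total, config)
                    if s < best_s:
                        best_s, best_theta = s, theta
                pose.torsions[j] = best_theta
        state = _evaluate(ligand, pose, anchor, receptor, grids, model, config)
        results.append(state)
        if config.n_steps > 0:
            for _ in range(config.n_restarts):
                results.append(
                    _anneal(ligand, state, frozen, receptor, grids, model, config, rng)
                )
    results.sort(key=lambda p: p.score_s)
    return results[: config.n_keep]


def _local_minimize(ligand, start: PartialPose, receptor, grids, model, config) -> PartialPose:
    """Deterministic Powell refinement of a completed pose over all DOF."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    base_quat = start.pose.rotation
    n_tors = len(start.pose.torsions)
    anchor = ligand.anchor_index()

    def pose_of(p):
        quat = _quat_multiply(
            Rotation.from_rotvec(p[3:6]).as_quat(), base_quat)
        quat = quat / np.sqrt(quat @ quat)
        return Pose(p[:3], quat, p[6:6 + n_tors])

    def objective(p):
        coords = apply_pose(ligand, pose_of(p))
        br = interaction_energy(coords, ligand, receptor=receptor, grids=grids, model=model)
        s, _ = score_S(coords, anchor, br.total, config)
        return s

    p0 = np.concatenate([start.pose.translation, np.zeros(3), start.pose.torsions])
    res = minimize(objective, p0, method="Powell",
                   options={"maxfev": 2500, "xtol": 1e-5, "ftol": 1e-7})
    refined = _evaluate(ligand, pose_of(res.x), anchor, receptor, grids, model, config)
    return refined if refined.score_s < start.score_s else start


def incremental_dock(
    ligand: Ligand,
    receptor=None,
    config: DockingConfig | None = None,
    grids=None,
    model: EnergyModel | None = None,
) -> DockingResult:
    """Full dock–select–grow–dock protocol.

    Torsions activate in torsion-tree breadth-first order,
    ``bonds_per_increment`` at a time; the returned poses all have every
    rotatable bond active and are ranked by S.  Deterministic for a fixed
    config (seed included).
    """
    config = config or DockingConfig()
    model = model or EnergyModel()
    rng = np.random.default_rng(config.seed)
    audit: list[dict] = []

    # stage 0: rigid root fragment, seeded at the sub-pocket in random
    # orientations (the anchor constraint makes the target location known)
    root_idx = sorted(ligand.root_atoms)
    root_center = ligand.ref_coords()[root_idx].mean(axis=0)
    seeds = []
    for _ in range(config.n_keep):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        trans = config.subpocket_center - root_center + rng.normal(0.0, 1.0, 3)
        seeds.append(PartialPose(pose=Pose(trans, q, np.zeros(0)), n_active_bonds=0))
    n_active = 0
    increment = 0
    while True:
        seeds = dock_increment(
            ligand, n_active, seeds, config,
            receptor=receptor, grids=grids, model=model, rng=rng,
        )
        audit.append(
            {
                "increment": increment,
                "n_active_bonds": n_active,
                "kept_scores": [p.score_s for p in seeds],
                "kept_d2": [p.d2 for p in seeds],
            }
        )
        if n_active >= ligand.n_rotatable:
            break
        n_active = min(n_active + config.bonds_per_increment, ligand.n_rotatable)
        increment += 1

    # final refinement: with growth complete, relax all degrees of freedom —
    # a low-temperature annealing pass on every kept pose, then a
    # deterministic local minimization of the leaders to settle each into
    # its exact local optimum
    if config.final_polish and config.n_steps > 0:
        from dataclasses import replace

        polish_cfg = replace(
            config, temp_start=0.5, temp_end=0.02,
            translation_step=0.2, rotation_step=0.08, torsion_step=0.15,
        )
        polished = []
        for p in seeds:
            best = p
            cand = _anneal(ligand, p, 0, receptor, grids, model, polish_cfg, rng)
            if cand.score_s < best.score_s:
                best = cand
            polished.append(best)
        polished.sort(key=lambda p: p.score_s)
        for i, p in enumerate(polished[:5]):
            polished[i] = _local_minimize(ligand, p, receptor, grids, model, config)
        seeds = polished
        audit.append({"increment": "polish",
                      "n_active_bonds": ligand.n_rotatable,
                      "kept_scores": [p.score_s for p in seeds],
                      "kept_d2": [p.d2 for p in seeds]})

    seeds.sort(key=lambda p: p.score_s)
    return DockingResult(poses=seeds, audit_log=audit)
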