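"""Synthetic toy systems and planted-truth datasets.

Every pipeline stage is testable without external structures: a rigid
pocket shell "keyed" to a planted ligand conformation (one strongly
positive phosphate sub-pocket plus secondary sites, residue-numbered like
the SH2 domain so the default sub-pocket configuration applies), flexible
chain ligands with up to 30 rotatable bonds, 1000-frame jittered
trajectories with planted per-atom fluctuation, planted conformational
clusters, scripted hydrogen-bond on/off patterns with exact occupancies,
and affinity tables with a calibrated population correlation to
IC50-derived ΔG.  All generators are bit-reproducible per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .affinity import ExperimentalRecord, dg_from_ic50
from .docking import DockingConfig
from .energy import EnergyModel, interaction_energy
from .molecules import (
    Atom,
    Ligand,
    Pose,
    Receptor,
    Residue,
    Trajectory,
    apply_pose,
    build_torsion_tree,
)

__all__ = [
    "ToySystem",
    "PlantedTrajectory",
    "HBondScriptEntry",
    "make_toy_system",
    "make_planted_trajectory",
    "make_affinity_table",
    "make_snapshot_components",
]

SCRIPTED_RESIDUES = (614, 615)


@dataclass
class ToySystem:
    receptor: Receptor
    ligand: Ligand
    planted_pose: Pose
    planted_coords: np.ndarray
    subpocket_center: np.ndarray
    seed: int
    acceptor_atoms: tuple[int, ...] = ()
    scripted_residues: tuple[int, ...] = SCRIPTED_RESIDUES

    def docking_config(self, **overrides) -> DockingConfig:
        cfg = DockingConfig(subpocket_center=self.subpocket_center.copy())
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


@dataclass
class HBondScriptEntry:
    residue: int
    occupancy: float
    acceptor_atom: int  # ligand atom index (within the ligand)


@dataclass
class PlantedTrajectory:
    traj: Trajectory
    sigma: float
    cluster_labels: np.ndarray
    cluster_offsets: np.ndarray
    script: list[HBondScriptEntry]
    script_presence: dict[int, np.ndarray]
    seed: int


def _random_quat(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def _build_chain(n_atoms: int, bond_length: float = 1.5, angle_deg: float = 109.5) -> np.ndarray:
    """Planar trans zig-zag chain; out-of-plane structure comes from torsions."""
    coords = np.zeros((n_atoms, 3))
    if n_atoms > 1:
        coords[1] = [bond_length, 0.0, 0.0]
    theta = np.deg2rad(180.0 - angle_deg)
    for i in range(2, n_atoms):
        prev_dir = coords[i - 1] - coords[i - 2]
        prev_dir /= np.linalg.norm(prev_dir)
        rot = Rotation.from_rotvec(np.array([0.0, 0.0, 1.0]) * (theta if i % 2 == 0 else -theta))
        coords[i] = coords[i - 1] + bond_length * rot.apply(prev_dir)
    return coords


def _toy_ligand(n_rotatable: int, rng: np.random.Generator) -> tuple[Ligand, list[int]]:
    """Chain ligand: P anchor at one end, alternating small charges, two
    acceptor oxygens, one donor-hydrogen leaf, C-terminal moiety at the far
    end.  Interior chain bonds are rotatable."""
    n_chain = n_rotatable + 3
    coords = _build_chain(n_chain)
    atoms: list[Atom] = []
    for i in range(n_chain):
        element = "C"
        charge = 0.25 if i % 2 else -0.25
        if i == 0:
            element, charge = "P", -1.5
        atoms.append(
            Atom(id=i, name=f"{element}{i}", element=element, charge=charge,
                 mass=30.974 if element == "P" else 12.011,
                 radius=1.8 if element == "P" else (1.45 if i % 2 else 1.85),
                 coords=coords[i], epsilon=0.2 if element == "P" else 0.086,
                 is_phosphorus=(i == 0))
        )
    acceptors: list[int] = []
    for pos in (min(3, n_chain - 1), max(2, min(n_chain - 2, 8))):
        if pos not in acceptors:
            atoms[pos].element = "O"
            atoms[pos].name = f"O{pos}"
            atoms[pos].is_acceptor = True
            atoms[pos].mass = 15.999
            atoms[pos].radius = 1.52
            atoms[pos].charge = -0.35
            acceptors.append(pos)
    bonds = [(i, i + 1, 1 <= i <= n_rotatable) for i in range(n_chain - 1)]
    h_parent = min(5, n_chain - 1)
    h_id = n_chain
    h_dir = rng.normal(size=3)
    h_dir /= np.linalg.norm(h_dir)
    atoms.append(
        Atom(id=h_id, name="H1", element="H", charge=0.25, mass=1.008, radius=1.2,
             coords=coords[h_parent] + 1.0 * h_dir, epsilon=0.016, is_donor_h=True)
    )
    bonds.append((h_parent, h_id, False))
    cterm = frozenset(range(max(0, n_chain - 2), n_chain))
    ligand = build_torsion_tree(atoms, bonds, root_hint=0, cterm_atoms=cterm)
    return ligand, acceptors


_RESERVED_RESIDUES = {591, 609, 611, 612, 613, 614, 615, 623, 638, 640, 644,
                      656, 657, 658, 659, 660}
# loop residues first so the groove walls carry the loop numbering
_SHELL_RESIDUE_POOL = (
    [n for n in range(624, 630)] + [n for n in range(661, 669)]
    + [n for n in range(585, 689) if n not in _RESERVED_RESIDUES
       and not (624 <= n <= 629) and not (661 <= n <= 668)]
)


def _toy_receptor(
    planted: np.ndarray,
    ligand: Ligand,
    acceptors: list[int],
) -> tuple[Receptor, np.ndarray]:
    """Pocket shell keyed to the planted ligand conformation.

    Sub-pocket-1 is a positively charged 5-atom ring around the planted
    anchor; every other heavy ligand atom (except the scripted acceptors)
    gets an opposite-charge shell atom at its LJ-contact distance;
    sub-pocket-2 sits near the planted C-terminal moiety, with sub-pockets
    3 and 4 further out.  Residues 614/615 carry O–H donor pairs aimed at
    the ligand acceptors for hydrogen-bond scripting (their oxygens are not
    flagged as acceptors, keeping the scripted channel free of incidental
    bonds).
    """
    residues: list[Residue] = []
    next_id = [0]

    def add_residue(number, name, specs, flag_acceptors=True):
        atoms = []
        for (aname, element, charge, xyz, eps, radius, mass) in specs:
            a = Atom(id=next_id[0], name=aname, element=element, charge=charge,
                     mass=mass, radius=radius, coords=np.asarray(xyz, float), epsilon=eps)
            if flag_acceptors and element in ("O", "N"):
                a.is_acceptor = True
            if element == "H":
                a.is_donor_h = True
            atoms.append(a)
            next_id[0] += 1
        residues.append(Residue(number=number, name=name, atoms=atoms))

    anchor_pos = planted[ligand.anchor_index()]
    lig_center = planted.mean(axis=0)

    axis = lig_center - anchor_pos
    axis /= np.linalg.norm(axis) + 1e-12
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    perp2 = np.cross(axis, perp)
    sp1_atoms = []
    for i, resnum in enumerate((591, 609, 611, 612, 613)):
        ang = 2 * np.pi * i / 5
        pos = anchor_pos + 3.35 * (np.cos(ang) * perp + np.sin(ang) * perp2) - 0.4 * axis
        sp1_atoms.append(pos)
        add_residue(resnum, "SP1", [(f"N{i}", "N", 0.7, pos, 0.17, 1.55, 100.0)])

    # scripted hydrogen-bond donors go in before the groove walls so the
    # walls can leave their approach corridor open
    from .energy import _golden_spiral

    directions = _golden_spiral(64)
    donor_positions: list[np.ndarray] = []
    donor_specs = []
    for resnum, acc in zip(SCRIPTED_RESIDUES, acceptors):
        acc_pos = planted[acc]
        others = np.delete(planted, acc, axis=0)
        obstacles = np.vstack([others, np.array(sp1_atoms)])
        best_u, best_clear = None, -np.inf
        for u in directions:
            clearance = min(
                np.linalg.norm(obstacles - (acc_pos + 3.2 * u), axis=1).min(),
                np.linalg.norm(obstacles - (acc_pos + 2.2 * u), axis=1).min(),
            )
            if clearance > best_clear:
                best_clear, best_u = clearance, u
        o_pos = acc_pos + 3.2 * best_u
        h_pos = acc_pos + 2.2 * best_u
        donor_positions.extend([o_pos, h_pos])
        donor_specs.append((resnum, o_pos, h_pos))

    # groove walls: a dense tube of neutral pseudo-atoms along the planted
    # chain path.  A conformation threading the tube is buried (many
    # contacts from all sides); anything draped outside touches far fewer
    # wall atoms, so the planted thread is the clear energy winner, and the
    # anchored phosphate fixes the registration along the path.
    heavy = [
        a.id for a in ligand.atoms if a.element != "H" and not a.is_phosphorus
    ]
    pool = iter(_SHELL_RESIDUE_POOL)
    placed_shell: list[np.ndarray] = [p for p in sp1_atoms]
    n_chain = max(heavy) + 1
    for aid in heavy:
        nxt = planted[min(aid + 1, n_chain - 1)]
        prv = planted[max(aid - 1, 0)]
        tangent = nxt - prv
        tangent /= np.linalg.norm(tangent) + 1e-12
        b1 = np.cross(tangent, [0.0, 0.0, 1.0])
        if np.linalg.norm(b1) < 1e-6:
            b1 = np.cross(tangent, [0.0, 1.0, 0.0])
        b1 /= np.linalg.norm(b1)
        b2 = np.cross(tangent, b1)
        # +0.35 Å slack: near-planted threads must stay extendable
        contact = ligand.atoms[aid].radius + 1.7 + 0.35
        ring_specs = []
        phase = 0.5 * (aid % 2)  # stagger alternate rings
        for jj in range(6):
            ang = 2 * np.pi * (jj + phase) / 6
            direction = np.cos(ang) * b1 + np.sin(ang) * b2
            pos = planted[aid] + contact * direction
            d_lig = np.linalg.norm(planted - pos, axis=1)
            d_lig[aid] = np.inf
            if d_lig.min() < 3.2:
                continue
            if placed_shell and min(np.linalg.norm(p - pos) for p in placed_shell) < 2.2:
                continue
            if donor_positions and min(
                np.linalg.norm(p - pos) for p in donor_positions
            ) < 2.2:
                continue
            placed_shell.append(pos)
            # one mildly charged partner per ring; the rest are neutral walls
            charge = -1.2 * ligand.atoms[aid].charge if not ring_specs else 0.0
            ring_specs.append((f"W{len(ring_specs)}", "C", charge, pos, 0.5, 1.7, 100.0))
        if ring_specs:
            add_residue(next(pool), "SHL", ring_specs)

    # end cap: close the tube beyond the C-terminal atom so the tail cannot
    # slide out of the groove
    last = n_chain - 1
    tangent = planted[last] - planted[last - 1] if n_chain > 1 else np.array([1.0, 0, 0])
    tangent = tangent / (np.linalg.norm(tangent) + 1e-12)
    b1 = np.cross(tangent, [0.0, 0.0, 1.0])
    if np.linalg.norm(b1) < 1e-6:
        b1 = np.cross(tangent, [0.0, 1.0, 0.0])
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(tangent, b1)
    cap_center = planted[last] + (ligand.atoms[last].radius + 1.7 + 0.5) * tangent
    cap_specs = [("WC", "C", 0.0, cap_center, 0.5, 1.7, 100.0)]
    for jj in range(4):
        ang = 2 * np.pi * jj / 4
        pos = cap_center + 2.4 * (np.cos(ang) * b1 + np.sin(ang) * b2)
        d_lig = np.linalg.norm(planted - pos, axis=1)
        if d_lig.min() < 3.0:
            continue
        cap_specs.append((f"WC{jj}", "C", 0.0, pos, 0.5, 1.7, 100.0))
    add_residue(next(pool), "CAP", cap_specs)

    ct_idx = sorted(ligand.cterm_atoms)
    ct_center = planted[ct_idx].mean(axis=0)
    out_dir = ct_center - lig_center
    out_dir /= np.linalg.norm(out_dir) + 1e-12

    def clear_of_ligand(pos, push_dir):
        # push a pocket atom outward until sterically clear of the ligand
        for _ in range(12):
            if np.linalg.norm(planted - pos, axis=1).min() >= 3.2:
                break
            pos = pos + push_dir
        return pos

    for resnum, offset in zip((638, 640, 644), ((4.0, 0.0), (4.0, 1.2), (4.0, -1.2))):
        pos = clear_of_ligand(ct_center + offset[0] * out_dir + offset[1] * perp, out_dir)
        add_residue(resnum, "SP2", [("C2", "C", 0.0, pos, 0.3, 1.7, 100.0)])
    for resnum, shift in zip((656, 657, 658), (0.0, 1.2, -1.2)):
        pos = clear_of_ligand(ct_center + 9.0 * out_dir + shift * perp2, out_dir)
        add_residue(resnum, "SP3", [("C3", "C", 0.0, pos, 0.3, 1.7, 100.0)])
    sp4_dir = out_dir + perp
    sp4_dir /= np.linalg.norm(sp4_dir)
    for resnum, shift in zip((623, 659, 660), (0.0, 1.5, -1.5)):
        pos = clear_of_ligand(ct_center + 6.0 * out_dir + 6.0 * perp + shift * perp2, sp4_dir)
        add_residue(resnum, "SP4", [("C4", "C", 0.0, pos, 0.3, 1.7, 100.0)])

    for resnum, o_pos, h_pos in donor_specs:
        add_residue(resnum, "DON",
                    [("OD", "O", -0.3, o_pos, 0.21, 1.52, 15.999),
                     ("HD", "H", 0.3, h_pos, 0.016, 1.2, 1.008)],
                    flag_acceptors=False)

    receptor = Receptor(residues=residues)
    return receptor, np.array(sp1_atoms).mean(axis=0)


def _pose_from_vector(p: np.ndarray, n_tors: int, base_quat: np.ndarray) -> Pose:
    quat = (Rotation.from_rotvec(p[3:6]) * Rotation.from_quat(base_quat)).as_quat()
    quat /= np.linalg.norm(quat)
    return Pose(p[:3], quat, p[6 : 6 + n_tors])


def make_toy_system(n_rotatable: int, seed: int = 0, max_retries: int = 8) -> ToySystem:
    """Generate a keyed pocket + flexible chain ligand with a planted pose.

    A candidate pose (random torsions, rotation and translation of the
    reference chain) keys the pocket; the pose is then locally refined on
    the surrogate energy so the planted pose is a strict local optimum,
    which is verified at generation (20 random small perturbations must all
    raise the energy, and the planted energy must undercut 100 random
    poses).  Retries with a derived sub-seed on self-clash or failed
    verification.
    """
    if not (0 <= n_rotatable <= 30):
        raise ValueError("n_rotatable must be in [0, 30]")
    model = EnergyModel()
    for attempt in range(max_retries):
        rng = np.random.default_rng((seed * 100003 + attempt * 7919 + 17) % (2**31))
        ligand, acceptors = _toy_ligand(n_rotatable, rng)
        torsions = rng.uniform(-0.7, 0.7, ligand.n_rotatable)
        quat = _random_quat(rng)
        translation = rng.uniform(8.0, 14.0, 3)
        pose0 = Pose(translation, quat, torsions)
        planted0 = apply_pose(ligand, pose0)
        sep = ligand.bond_graph_distances()
        iu, ju = np.triu_indices(ligand.n_atoms, k=1)
        far = sep[iu, ju] > 3
        d = np.linalg.norm(planted0[iu[far]] - planted0[ju[far]], axis=1)
        if d.size and d.min() < 2.4:
            continue
        # key the pocket to the pose, refine the pose in that pocket, and
        # iterate to self-consistency: walls built around a pre-refinement
        # conformation would leave the refined pose off the tube centerline,
        # making a recentered thread — not the planted pose — the optimum
        planted_pose = pose0
        planted = planted0
        p_current = np.concatenate([translation, np.zeros(3), torsions])
        receptor = sp1_center = None
        clashed = False
        for _ in range(3):
            receptor, sp1_center = _toy_receptor(planted, ligand, acceptors)
            rec_xyz = receptor.coords()
            gap = np.linalg.norm(rec_xyz[:, None, :] - planted[None, :, :], axis=2).min()
            if gap < 2.1:  # pocket construction produced a steric clash
                clashed = True
                break

            def energy_of(p):
                pose = _pose_from_vector(p, ligand.n_rotatable, quat)
                return interaction_energy(
                    apply_pose(ligand, pose), ligand, receptor=receptor, model=model
                ).total

            res = minimize(energy_of, p_current, method="Powell",
                           options={"maxfev": 4000, "xtol": 1e-6, "ftol": 1e-8})
            p_current = res.x
            new_pose = _pose_from_vector(p_current, ligand.n_rotatable, quat)
            new_planted = apply_pose(ligand, new_pose)
            drift = float(np.abs(new_planted - planted).max())
            planted_pose, planted = new_pose, new_planted
            if drift < 0.05:
                break
        if clashed:
            continue
        if np.linalg.norm(planted[ligand.anchor_index()] - sp1_center) > 1.0:
            continue
        e_planted = interaction_energy(planted, ligand, receptor=receptor, model=model).total

        ok = True
        for _ in range(20):
            pert = Pose(
                planted_pose.translation + rng.normal(0, 0.08, 3),
                _perturb_quat(planted_pose.rotation, rng, 0.03),
                planted_pose.torsions + rng.normal(0, 0.03, ligand.n_rotatable),
            )
            e_pert = interaction_energy(
                apply_pose(ligand, pert), ligand, receptor=receptor, model=model
            ).total
            if e_pert <= e_planted:
                ok = False
                break
        if ok:
            for _ in range(100):
                rand = Pose(rng.uniform(0.0, 20.0, 3), _random_quat(rng),
                            rng.uniform(-np.pi, np.pi, ligand.n_rotatable))
                e_rand = interaction_energy(
                    apply_pose(ligand, rand), ligand, receptor=receptor, model=model
                ).total
                if e_rand <= e_planted:
                    ok = False
                    break
        if ok:
            return ToySystem(
                receptor=receptor, ligand=ligand, planted_pose=planted_pose,
                planted_coords=planted, subpocket_center=sp1_center, seed=seed,
                acceptor_atoms=tuple(acceptors),
            )
    raise RuntimeError("could not generate a verified toy system; geometry infeasible")


def _perturb_quat(quat: np.ndarray, rng: np.random.Generator, scale: float) -> np.ndarray:
    dq = Rotation.from_rotvec(rng.normal(0, scale, 3))
    out = (dq * Rotation.from_quat(quat)).as_quat()
    return out / np.linalg.norm(out)


def make_planted_trajectory(
    system: ToySystem,
    n_frames: int = 1000,
    sigma: float = 0.15,
    cluster_fractions: tuple[float, ...] = (1.0,),
    cluster_spread: float = 3.0,
    hbond_script: list[HBondScriptEntry] | None = None,
    receptor_sigma: float = 0.03,
    frame_spacing: float = 10.0,
    seed: int = 0,
) -> PlantedTrajectory:
    """Jittered trajectory with planted clusters and scripted hydrogen bonds.

    Cluster references are the planted ligand conformation translated by
    well-separated offsets (magnitude ``cluster_spread`` Å); per-cluster
    frame counts are realized exactly from ``cluster_fractions`` (largest
    remainder).  Per-frame Gaussian jitter has scale ``sigma`` on ligand
    atoms and ``receptor_sigma`` on the pocket shell.  Scripted donor and
    acceptor atoms are placed exactly (no jitter) so every scripted
    occupancy is realized by construction: present frames use a
    3.2 Å / 180° geometry, absent frames a 6 Å separation.
    """
    if not np.isclose(sum(cluster_fractions), 1.0):
        raise ValueError("cluster fractions must sum to 1")
    rng = np.random.default_rng(seed)
    rec_atoms = system.receptor.atoms
    lig_atoms = system.ligand.atoms
    n_rec, n_lig = len(rec_atoms), len(lig_atoms)

    k = len(cluster_fractions)
    counts = np.floor(np.array(cluster_fractions) * n_frames).astype(int)
    remainder = n_frames - counts.sum()
    order = np.argsort(-(np.array(cluster_fractions) * n_frames - counts))
    counts[order[:remainder]] += 1
    labels = np.repeat(np.arange(k), counts)

    offsets = np.zeros((k, 3))
    dirs = np.eye(3)
    for c in range(1, k):
        offsets[c] = cluster_spread * ((-1) ** c) * dirs[(c - 1) % 3] * ((c + 1) // 2)

    rec_ref = np.array([a.coords for a in rec_atoms])
    lig_ref = system.planted_coords

    coords = np.empty((n_frames, n_rec + n_lig, 3))
    coords[:, :n_rec] = rec_ref[None] + rng.normal(0, receptor_sigma, (n_frames, n_rec, 3))
    coords[:, n_rec:] = (
        lig_ref[None] + offsets[labels][:, None, :]
        + rng.normal(0, sigma, (n_frames, n_lig, 3))
    )

    script = list(hbond_script or [])
    presence_map: dict[int, np.ndarray] = {}
    donor_res = {res.number: res for res in system.receptor.residues if res.name == "DON"}
    rec_index_of = {a.id: i for i, a in enumerate(rec_atoms)}
    lig_center = lig_ref.mean(axis=0)
    for entry in script:
        if entry.residue not in donor_res:
            raise ValueError(f"residue {entry.residue} has no scripted donor pair")
        if not (0.0 <= entry.occupancy <= 1.0):
            raise ValueError("occupancy must be in [0, 1]")
        res = donor_res[entry.residue]
        o_i = rec_index_of[res.atoms[0].id]
        h_i = rec_index_of[res.atoms[1].id]
        acc_global = n_rec + entry.acceptor_atom
        n_present = int(np.floor(entry.occupancy * n_frames + 0.5))  # half-up
        present = np.zeros(n_frames, dtype=bool)
        present[rng.permutation(n_frames)[:n_present]] = True
        presence_map[entry.residue] = present
        acc_pos = lig_ref[entry.acceptor_atom][None] + offsets[labels]
        coords[:, acc_global] = acc_pos
        # reuse the receptor's static donor direction for this residue
        u = res.atoms[0].coords - lig_ref[entry.acceptor_atom]
        u = u / np.linalg.norm(u)
        dist = np.where(present, 3.2, 6.0)[:, None]
        coords[:, o_i] = acc_pos + dist * u
        coords[:, h_i] = acc_pos + (dist - 1.0) * u

    atoms_all: list[Atom] = []
    resnums: list[int] = []
    resnames: list[str] = []
    i = 0
    for res in system.receptor.residues:
        for a in res.atoms:
            atoms_all.append(Atom(id=i, name=a.name, element=a.element, charge=a.charge,
                                  mass=a.mass, radius=a.radius, coords=a.coords.copy(),
                                  epsilon=a.epsilon, is_donor_h=a.is_donor_h,
                                  is_acceptor=a.is_acceptor))
            resnums.append(res.number)
            resnames.append(res.name)
            i += 1
    for a in lig_atoms:
        atoms_all.append(Atom(id=i, name=a.name, element=a.element, charge=a.charge,
                              mass=a.mass, radius=a.radius, coords=a.coords.copy(),
                              epsilon=a.epsilon, is_donor_h=a.is_donor_h,
                              is_acceptor=a.is_acceptor, is_phosphorus=a.is_phosphorus))
        resnums.append(1)
        resnames.append("LIG")
        i += 1

    traj = Trajectory(
        coords=coords,
        atoms=atoms_all,
        frame_spacing=frame_spacing,
        receptor_indices=np.arange(n_rec),
        ligand_indices=np.arange(n_rec, n_rec + n_lig),
        residue_numbers=np.array(resnums),
        residue_names=resnames,
    )
    return PlantedTrajectory(
        traj=traj, sigma=sigma, cluster_labels=labels, cluster_offsets=offsets,
        script=script, script_presence=presence_map, seed=seed,
    )


def make_affinity_table(
    n_compounds: int = 12,
    target_r: float = 0.63,
    seed: int = 0,
    est_mean: float = -30.0,
    est_scale: float = 8.0,
) -> tuple[list[ExperimentalRecord], np.ndarray, float]:
    """Experimental table + planted ΔG estimates with population correlation
    ``target_r``.

    IC50 values are log-spaced over the assay's 39–100,000 nM span (the
    weakest compound is censored, mirroring a reported '>' bound); the
    estimates are ``target_r``·z + √(1−r²)·noise on the standardized
    experimental ΔG, rescaled to an affinity-like range.  Returns
    (records, estimates, realized sample R).
    """
    if n_compounds < 3:
        raise ValueError("need at least 3 compounds")
    if not (-1.0 <= target_r <= 1.0):
        raise ValueError("|target_r| must be <= 1")
    rng = np.random.default_rng(seed)
    ic50 = np.geomspace(39.0, 100_000.0, n_compounds)
    records = [
        ExperimentalRecord(compound=f"cmpd{i + 1:02d}", ic50_nM=float(v),
                           censored=(i == n_compounds - 1))
        for i, v in enumerate(ic50)
    ]
    dg_exp = np.array([dg_from_ic50(r.ic50_nM) for r in records])
    z = (dg_exp - dg_exp.mean()) / dg_exp.std()
    noise = rng.standard_normal(n_compounds)
    latent = target_r * z + np.sqrt(max(0.0, 1.0 - target_r**2)) * noise
    dg_est = est_mean + est_scale * latent
    realized = float(np.corrcoef(dg_est, dg_exp)[0, 1])
    return records, dg_est, realized


def make_snapshot_components(
    n_frames: int = 1000,
    mean: tuple[float, float, float] = (-35.0, 18.0, -2.5),
    sigma: tuple[float, float, float] = (3.0, 2.0, 0.3),
    seed: int = 0,
):
    """Stationary Gaussian per-frame Δ-components for affinity-scheme tests."""
    from .affinity import SnapshotEnergies

    rng = np.random.default_rng(seed)
    return SnapshotEnergies(
        d_e_mm=rng.normal(mean[0], sigma[0], n_frames),
        d_g_polar=rng.normal(mean[1], sigma[1], n_frames),
        d_g_nonpolar=rng.normal(mean[2], sigma[2], n_frames),
        source="native-GB",
    )
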