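"""Structure representation and I/O for receptors, flexible ligands and trajectories.

Internal conventions: lengths in Å, charges in elementary-charge units,
masses in amu; atom indices are 0-based, PDB residue numbers keep author
(1-based) numbering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from Bio.PDB import PDBParser

from . import params

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Receptor",
    "Ligand",
    "Pose",
    "Trajectory",
    "read_receptor_pdb",
    "build_torsion_tree",
    "apply_pose",
    "read_trajectory",
    "write_trajectory",
    "write_pose_pdb",
    "read_ligand_file",
    "write_ligand_file",
]


@dataclass
class Atom:
    """A point atom with nonbonded parameters and hydrogen-bond roles."""

    id: int
    name: str
    element: str
    charge: float
    mass: float
    radius: float
    coords: np.ndarray
    epsilon: float = 0.1
    is_donor_h: bool = False
    is_acceptor: bool = False
    is_phosphorus: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.mass <= 0 or self.radius <= 0:
            raise ValueError(f"atom {self.id}: mass and radius must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.id}: non-finite coordinates")


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[Atom]
    chain: str = "A"


@dataclass
class Receptor:
    """An ordered set of residues treated as rigid during docking."""

    residues: list[Residue]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("receptor must contain at least one residue")
        numbers = [r.number for r in self.residues]
        if len(set(numbers)) != len(numbers):
            raise ValueError("duplicate residue numbers within chain")

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def atom_arrays(self) -> dict[str, np.ndarray]:
        """Vectorized parameter views used by the energy module."""
        atoms = self.atoms
        return {
            "coords": np.array([a.coords for a in atoms]),
            "charge": np.array([a.charge for a in atoms]),
            "radius": np.array([a.radius for a in atoms]),
            "epsilon": np.array([a.epsilon for a in atoms]),
            "mass": np.array([a.mass for a in atoms]),
        }

    def residue_of_atom(self) -> np.ndarray:
        """Residue number for every atom, aligned with :meth:`atoms`."""
        return np.array([r.number for r in self.residues for _ in r.atoms])


@dataclass
class TorsionBond:
    """One rotatable bond of the torsion tree.

    ``axis`` is the (parent_atom, child_atom) pair defining the rotation
    axis; ``moving`` is the boolean mask of atoms displaced by the torsion.
    """

    axis: tuple[int, int]
    moving: np.ndarray
    depth: int


@dataclass
class Ligand:
    """A flexible ligand: atoms, bonds and a rooted torsion tree."""

    atoms: list[Atom]
    bonds: list[tuple[int, int, bool]]
    root_atoms: frozenset[int] = frozenset()
    torsion_bonds: list[TorsionBond] = field(default_factory=list)
    cterm_atoms: frozenset[int] = frozenset()

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_rotatable(self) -> int:
        return len(self.torsion_bonds)

    def ref_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def atom_arrays(self) -> dict[str, np.ndarray]:
        # cached: atoms are treated as immutable once the tree is built
        cached = getattr(self, "_arrays_cache", None)
        if cached is None:
            cached = {
                "coords": self.ref_coords(),
                "charge": np.array([a.charge for a in self.atoms]),
                "radius": np.array([a.radius for a in self.atoms]),
                "epsilon": np.array([a.epsilon for a in self.atoms]),
                "mass": np.array([a.mass for a in self.atoms]),
            }
            object.__setattr__(self, "_arrays_cache", cached)
        return cached

    def anchor_index(self) -> int:
        """Index of the single anchor (phosphorus) atom."""
        cached = getattr(self, "_anchor_cache", None)
        if cached is None:
            anchors = [a.id for a in self.atoms if a.is_phosphorus]
            if len(anchors) != 1:
                raise ValueError(
                    f"expected exactly one anchor atom, found {len(anchors)}"
                )
            cached = anchors[0]
            object.__setattr__(self, "_anchor_cache", cached)
        return cached

    def bond_graph_distances(self) -> np.ndarray:
        """All-pairs bond-count separation (for 1-4 exclusion masks)."""
        cached = getattr(self, "_sep_cache", None)
        if cached is None:
            g = nx.Graph()
            g.add_nodes_from(range(self.n_atoms))
            g.add_edges_from([(a, b) for a, b, _ in self.bonds])
            n = self.n_atoms
            cached = np.full((n, n), 10_000, dtype=int)
            for src, lengths in nx.all_pairs_shortest_path_length(g, cutoff=4):
                for dst, d in lengths.items():
                    cached[src, dst] = d
            object.__setattr__(self, "_sep_cache", cached)
        return cached


@dataclass
class Pose:
    """Rigid-body placement plus torsion angles — the docking search state.

    Torsions are applied root-outward to the reference internal geometry,
    then the rotation (about the root-fragment reference centroid), then
    the translation.
    """

    translation: np.ndarray
    rotation: np.ndarray  # unit quaternion, scalar-last (x, y, z, w)
    torsions: np.ndarray

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.torsions = np.asarray(self.torsions, dtype=float)
        norm = float(self.rotation @ self.rotation)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError("rotation quaternion must have unit norm")

    @classmethod
    def identity(cls, n_torsions: int = 0) -> "Pose":
        return cls(np.zeros(3), np.array([0.0, 0.0, 0.0, 1.0]), np.zeros(n_torsions))


@dataclass
class Trajectory:
    """Frame-indexed coordinates with shared atom metadata.

    ``receptor_indices`` / ``ligand_indices`` select the two species inside
    the complex; ``frame_spacing`` is in ps.
    """

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    atoms: list[Atom]
    frame_spacing: float = 10.0
    receptor_indices: np.ndarray | None = None
    ligand_indices: np.ndarray | None = None
    residue_numbers: np.ndarray | None = None
    residue_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom metadata does not match coordinate count")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])


# ---------------------------------------------------------------------------
# Receptor I/O


def _make_atom(idx, name, resname, x, y, z, element=None) -> tuple[Atom, bool]:
    el = element or params.guess_element(name)
    radius, eps, mass, charge, known = params.lookup(resname, name, el)
    atom = Atom(
        id=idx,
        name=name,
        element=el,
        charge=charge,
        mass=mass,
        radius=radius,
        coords=np.array([x, y, z], dtype=float),
        epsilon=eps,
    )
    # conservative geometric-role flags; refined by assign_hbond_roles
    if el == "H":
        atom.is_donor_h = True
    if el in ("O", "N"):
        atom.is_acceptor = True
    if el == "P":
        atom.is_phosphorus = True
    return atom, known


def read_receptor_pdb(
    path: str | Path, residue_range: tuple[int, int] | None = None
) -> Receptor:
    """Read a receptor from a PDB file, keeping residues in an author-numbered
    inclusive range and dropping waters, ions and nucleic-acid residues.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("receptor", str(path))
    except Exception as exc:  # pragma: no cover - Bio.PDB raises varied types
        raise ValueError(f"unparseable PDB file {path}: {exc}") from exc

    residues: list[Residue] = []
    idx = 0
    chain_id = "A"
    for model in structure:
        for chain in model:
            chain_id = chain.id
            for res in chain:
                resname = res.get_resname().strip().upper()
                if resname in params.WATER_RESNAMES:
                    continue
                if resname in params.NUCLEIC_RESNAMES or resname in params.ION_RESNAMES:
                    continue
                number = res.get_id()[1]
                if residue_range is not None and not (
                    residue_range[0] <= number <= residue_range[1]
                ):
                    continue
                atoms = []
                for a in res:
                    atom, known = _make_atom(
                        idx,
                        a.get_name(),
                        resname,
                        *a.get_coord(),
                        element=(a.element or None),
                    )
                    if not known:
                        logger.warning(
                            "unknown atom %s/%s: element-fallback parameters used",
                            resname,
                            a.get_name(),
                        )
                    atoms.append(atom)
                    idx += 1
                residues.append(Residue(number=number, name=resname, atoms=atoms, chain=chain.id))
        break  # first model only
    if not residues:
        raise ValueError("empty selection after residue filtering")
    return Receptor(residues=residues, chain_id=chain_id)


# ---------------------------------------------------------------------------
# Torsion tree


def build_torsion_tree(
    atoms: list[Atom],
    bonds: list[tuple[int, int, bool]],
    root_hint: int | None = None,
    cterm_atoms: frozenset[int] | None = None,
) -> Ligand:
    """Build a ligand with a rooted torsion tree.

    Rigid units are the connected components left after cutting rotatable
    bonds; ring bonds (non-bridges) are forced non-rotatable, as are bonds
    whose distal side holds no atom beyond the bond (nothing would move).
    The root unit contains ``root_hint`` (default: the phosphorus atom, or
    atom 0).  Rotatable bonds are ordered by breadth-first unit depth from
    the root, ties broken by the lower atom id on the bond.
    """
    n = len(atoms)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from([(a, b) for a, b, _ in bonds])
    if n and not nx.is_connected(g):
        raise ValueError("ligand bond graph is disconnected")

    bridges = set(frozenset(e) for e in nx.bridges(g)) if n > 1 else set()
    rotatable = []
    for a, b, flag in bonds:
        if flag and frozenset((a, b)) in bridges:
            rotatable.append((a, b))

    # rigid units: components after cutting rotatable bonds
    g_rigid = g.copy()
    g_rigid.remove_edges_from(rotatable)
    units = [frozenset(c) for c in nx.connected_components(g_rigid)]
    unit_of = {a: i for i, u in enumerate(units) for a in u}

    if root_hint is None:
        phos = [a.id for a in atoms if a.is_phosphorus]
        root_hint = phos[0] if phos else 0
    if root_hint not in unit_of:
        raise ValueError(f"root_hint atom {root_hint} absent from ligand")
    root_unit = unit_of[root_hint]

    # unit tree via BFS from the root unit
    unit_graph = nx.Graph()
    unit_graph.add_nodes_from(range(len(units)))
    bond_of_units = {}
    for a, b in rotatable:
        ua, ub = unit_of[a], unit_of[b]
        unit_graph.add_edge(ua, ub)
        bond_of_units[frozenset((ua, ub))] = (a, b)

    depth = {root_unit: 0}
    order: list[tuple[int, int, int, int]] = []  # (depth, min id, max id, unit)
    parent = {}
    for u, v in nx.bfs_edges(unit_graph, root_unit):
        depth[v] = depth[u] + 1
        parent[v] = u
        a, b = bond_of_units[frozenset((u, v))]
        order.append((depth[v], min(a, b), max(a, b), v))
    order.sort()

    torsion_bonds = []
    for d, _, _, v in order:
        u = parent[v]
        a, b = bond_of_units[frozenset((u, v))]
        if unit_of[a] != u:
            a, b = b, a
        # moving set: all atoms in the subtree rooted at unit v
        sub_units = {v} | nx.descendants(nx.bfs_tree(unit_graph, root_unit), v)
        moving = np.zeros(n, dtype=bool)
        for su in sub_units:
            for atom_id in units[su]:
                moving[atom_id] = True
        if moving.sum() <= 1:
            continue  # terminal single atom: rotation is a no-op
        torsion_bonds.append(TorsionBond(axis=(a, b), moving=moving, depth=d))

    # re-flag bonds so n_rotatable matches the tree
    kept_axes = {frozenset(tb.axis) for tb in torsion_bonds}
    final_bonds = [(a, b, frozenset((a, b)) in kept_axes) for a, b, _ in bonds]

    return Ligand(
        atoms=atoms,
        bonds=final_bonds,
        root_atoms=units[root_unit],
        torsion_bonds=torsion_bonds,
        cterm_atoms=cterm_atoms or frozenset(),
    )


def _rotate_about_axis(coords, origin, axis, angle) -> np.ndarray:
    # Rodrigues rotation with explicit cross product; this sits in the
    # docking search's innermost loop
    k = axis / np.sqrt(axis @ axis)
    v = coords - origin
    c, s = np.cos(angle), np.sin(angle)
    kxv = np.empty_like(v)
    kxv[:, 0] = k[1] * v[:, 2] - k[2] * v[:, 1]
    kxv[:, 1] = k[2] * v[:, 0] - k[0] * v[:, 2]
    kxv[:, 2] = k[0] * v[:, 1] - k[1] * v[:, 0]
    return origin + v * c + kxv * s + np.outer(v @ k, k) * (1.0 - c)


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix from a unit quaternion (x, y, z, w convention)."""
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def apply_pose(ligand: Ligand, pose: Pose) -> np.ndarray:
    """Coordinates of the ligand under a pose (torsions, rotation, translation).

    Torsions beyond the active prefix stay at the reference internal
    geometry.  The rigid-body rotation is taken about the reference centroid
    of the root fragment, which torsions never displace.
    """
    if len(pose.torsions) > ligand.n_rotatable:
        raise ValueError("pose has more torsions than the ligand has rotatable bonds")
    coords = ligand.atom_arrays()["coords"].copy()
    for angle, tb in zip(pose.torsions, ligand.torsion_bonds):
        if angle == 0.0:
            continue
        a, b = tb.axis
        axis = coords[b] - coords[a]
        coords[tb.moving] = _rotate_about_axis(coords[tb.moving], coords[a], axis, angle)
    root_idx = sorted(ligand.root_atoms)
    center = ligand.atom_arrays()["coords"][root_idx].mean(axis=0)
    coords = center + (coords - center) @ _quat_to_matrix(pose.rotation).T
    return coords + pose.translation


# ---------------------------------------------------------------------------
# Ligand file format (structured text)

_FLAG_CODES = {"P": "is_phosphorus", "DH": "is_donor_h", "ACC": "is_acceptor"}


def write_ligand_file(ligand: Ligand, path: str | Path) -> None:
    lines = ["# sh2dock ligand v1", f"atoms {ligand.n_atoms}"]
    for a in ligand.atoms:
        flags = [code for code, attr in _FLAG_CODES.items() if getattr(a, attr)]
        if a.id in ligand.cterm_atoms:
            flags.append("CT")
        lines.append(
            f"{a.id} {a.name} {a.element} {a.charge:.6f} {a.mass:.4f} "
            f"{a.radius:.4f} {a.epsilon:.6f} "
            f"{a.coords[0]:.6f} {a.coords[1]:.6f} {a.coords[2]:.6f} "
            f"{','.join(flags) if flags else '-'}"
        )
    lines.append(f"bonds {len(ligand.bonds)}")
    for a, b, rot in ligand.bonds:
        lines.append(f"{a} {b} {1 if rot else 0}")
    root_hint = min(ligand.root_atoms) if ligand.root_atoms else 0
    lines.append(f"root {root_hint}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ligand_file(path: str | Path) -> Ligand:
    lines = [
        ln.strip()
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    it = iter(lines)
    head = next(it).split()
    if head[0] != "atoms":
        raise ValueError("malformed ligand file: expected 'atoms N'")
    n_atoms = int(head[1])
    atoms, cterm = [], set()
    for _ in range(n_atoms):
        parts = next(it).split()
        idx = int(parts[0])
        atom = Atom(
            id=idx,
            name=parts[1],
            element=parts[2],
            charge=float(parts[3]),
            mass=float(parts[4]),
            radius=float(parts[5]),
            epsilon=float(parts[6]),
            coords=np.array([float(parts[7]), float(parts[8]), float(parts[9])]),
        )
        if parts[10] != "-":
            for flag in parts[10].split(","):
                if flag == "CT":
                    cterm.add(idx)
                else:
                    setattr(atom, _FLAG_CODES[flag], True)
        atoms.append(atom)
    head = next(it).split()
    n_bonds = int(head[1])
    bonds = []
    for _ in range(n_bonds):
        a, b, rot = next(it).split()
        bonds.append((int(a), int(b), rot == "1"))
    root_hint = None
    for ln in it:
        if ln.startswith("root"):
            root_hint = int(ln.split()[1])
    return build_torsion_tree(atoms, bonds, root_hint=root_hint, cterm_atoms=frozenset(cterm))


# ---------------------------------------------------------------------------
# Trajectory and pose I/O


def _pdb_atom_line(serial, name, resname, chain, resnum, xyz, element, hetatm=False):
    record = "HETATM" if hetatm else "ATOM  "
    name_fmt = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"{record}{serial:>5d} {name_fmt}{'':1s}{resname:>3s} {chain:1s}"
        f"{resnum:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def write_pose_pdb(receptor, ligand, lig_coords, path: str | Path) -> None:
    """Write a receptor + placed ligand complex as a single-model PDB."""
    lines = []
    serial = 1
    if receptor is not None:
        for res in receptor.residues:
            for a in res.atoms:
                lines.append(
                    _pdb_atom_line(serial, a.name, res.name, res.chain, res.number, a.coords, a.element)
                )
                serial += 1
    if ligand is not None:
        for a, xyz in zip(ligand.atoms, lig_coords):
            lines.append(_pdb_atom_line(serial, a.name, "LIG", "L", 1, xyz, a.element, hetatm=True))
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(traj: Trajectory, path: str | Path, fmt: str = "pdb") -> None:
    """Write a trajectory as multi-model PDB or plain-text frame blocks."""
    path = Path(path)
    if fmt == "pdb":
        lines = []
        resnums = traj.residue_numbers
        resnames = traj.residue_names
        for f in range(traj.n_frames):
            lines.append(f"MODEL     {f + 1:>4d}")
            for i, a in enumerate(traj.atoms):
                resnum = int(resnums[i]) if resnums is not None else 1
                resname = resnames[i] if resnames is not None else "MOL"
                lines.append(
                    _pdb_atom_line(i + 1, a.name, resname, "A", resnum, traj.coords[f, i], a.element)
                )
            lines.append("ENDMDL")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "txt":
        lines = [
            "# sh2dock traj v1",
            f"natoms {traj.n_atoms} frames {traj.n_frames} spacing_ps {traj.frame_spacing}",
        ]
        for f in range(traj.n_frames):
            lines.append(f"frame {f}")
            for i in range(traj.n_atoms):
                x, y, z = traj.coords[f, i]
                lines.append(f"{x:.3f} {y:.3f} {z:.3f}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def read_trajectory(
    path: str | Path, fmt: str = "pdb", frame_spacing: float = 10.0
) -> Trajectory:
    """Read a trajectory (multi-model PDB or plain-text frames)."""
    path = Path(path)
    if fmt == "txt":
        return _read_traj_txt(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("traj", str(path))
    frames = []
    atoms_meta: list[Atom] = []
    resnums: list[int] = []
    resnames: list[str] = []
    for m_idx, model in enumerate(structure):
        coords = []
        meta_this: list[tuple] = []
        for chain in model:
            for res in chain:
                for a in res:
                    coords.append(a.get_coord())
                    meta_this.append((a.get_name(), res.get_resname().strip(), res.get_id()[1]))
        if not atoms_meta:
            for i, (name, resname, resnum) in enumerate(meta_this):
                atom, _ = _make_atom(i, name, resname, 0.0, 0.0, 0.0)
                atoms_meta.append(atom)
                resnums.append(resnum)
                resnames.append(resname)
        if len(coords) != len(atoms_meta):
            raise ValueError(
                f"frame {m_idx}: atom count {len(coords)} != expected {len(atoms_meta)}"
            )
        frames.append(np.array(coords, dtype=float))
    if not frames:
        raise ValueError(f"no frames found in {path}")
    lig_mask = np.array([rn == "LIG" for rn in resnames])
    return Trajectory(
        coords=np.stack(frames),
        atoms=atoms_meta,
        frame_spacing=frame_spacing,
        receptor_indices=np.where(~lig_mask)[0] if lig_mask.any() else None,
        ligand_indices=np.where(lig_mask)[0] if lig_mask.any() else None,
        residue_numbers=np.array(resnums),
        residue_names=resnames,
    )


def _read_traj_txt(path: Path) -> Trajectory:
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    lines = [ln for ln in lines if not ln.startswith("#")]
    head = lines[0].split()
    n_atoms, n_frames = int(head[1]), int(head[3])
    spacing = float(head[5])
    coords = np.empty((n_frames, n_atoms, 3))
    pos = 1
    for f in range(n_frames):
        if pos >= len(lines) or not lines[pos].startswith("frame"):
            raise ValueError(f"truncated file: missing frame {f}")
        pos += 1
        for i in range(n_atoms):
            if pos >= len(lines) or lines[pos].startswith("frame"):
                raise ValueError(f"frame {f}: atom count mismatch at atom {i}")
            coords[f, i] = [float(v) for v in lines[pos].split()]
            pos += 1
    atoms = [
        Atom(id=i, name=f"C{i}", element="C", charge=0.0, mass=12.011, radius=1.7,
             coords=np.zeros(3))
        for i in range(n_atoms)
    ]
    return Trajectory(coords=coords, atoms=atoms, frame_spacing=spacing)
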