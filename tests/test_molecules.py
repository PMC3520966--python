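import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sh2dock.molecules import (
    Atom,
    Pose,
    Trajectory,
    apply_pose,
    build_torsion_tree,
    read_ligand_file,
    read_receptor_pdb,
    read_trajectory,
    write_ligand_file,
    write_trajectory,
)

TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.685   7.129  -4.889  1.00  0.00           C
ATOM      4  N   GLY A   2      13.509   6.900  -3.866  1.00  0.00           N
ATOM      5  CA  GLY A   2      14.548   7.856  -3.530  1.00  0.00           C
ATOM      6  N   SER A   3      15.500   7.200  -2.500  1.00  0.00           N
ATOM      7  O   HOH A   4      20.000  20.000  20.000  1.00  0.00           O
ATOM      8  QQ  UNK A   5      25.000  25.000  25.000  1.00  0.00
END
"""


def chain_atoms(n, element="C"):
    return [
        Atom(id=i, name=f"{element}{i}", element=element, charge=0.0, mass=12.0,
             radius=1.7, coords=np.array([1.5 * i, 0.4 * (i % 2), 0.0]))
        for i in range(n)
    ]


class TestReadReceptor:
    def test_residue_range_filter(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        rec = read_receptor_pdb(p, residue_range=(1, 2))
        assert [r.number for r in rec.residues] == [1, 2]

    def test_waters_dropped(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        rec = read_receptor_pdb(p)
        assert all(r.name != "HOH" for r in rec.residues)

    def test_unknown_atom_gets_fallback_params(self, tmp_path, caplog):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        with caplog.at_level("WARNING"):
            rec = read_receptor_pdb(p)
        unk = [a for r in rec.residues for a in r.atoms if a.name == "QQ"]
        assert len(unk) == 1 and unk[0].radius > 0 and unk[0].mass > 0
        assert any("fallback" in m for m in caplog.messages)

    def test_empty_selection_raises(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        with pytest.raises(ValueError):
            read_receptor_pdb(p, residue_range=(100, 200))


class TestTorsionTree:
    def test_two_unit_single_torsion(self):
        # two rigid CH-like units joined by one rotatable bond
        atoms = chain_atoms(4)
        bonds = [(0, 1, False), (1, 2, True), (2, 3, False)]
        lig = build_torsion_tree(atoms, bonds, root_hint=0)
        assert lig.n_rotatable == 1
        assert lig.torsion_bonds[0].axis == (1, 2)
        assert 0 in lig.root_atoms and 1 in lig.root_atoms

    def test_ring_is_rigid(self):
        atoms = chain_atoms(3)
        bonds = [(0, 1, True), (1, 2, True), (2, 0, True)]
        lig = build_torsion_tree(atoms, bonds, root_hint=0)
        assert lig.n_rotatable == 0
        assert lig.root_atoms == frozenset({0, 1, 2})

    def test_branched_bfs_order(self):
        # star: center unit 0-1; arms at 1 and three bonds out, hand-drawn:
        #   0-1 (rigid), 1-2 rot (depth1), 2-3 rot (depth2), 1-4 rot (depth1)
        atoms = chain_atoms(8)
        bonds = [(0, 1, False), (1, 2, True), (2, 3, True), (3, 5, False),
                 (1, 4, True), (1, 6, True), (6, 7, False)]
        lig = build_torsion_tree(atoms, bonds, root_hint=0)
        # hand enumeration: (1,2) and (1,6) sit at depth 1 ((1,2) first by
        # atom-id tie-break), (2,3) at depth 2; (1,4) moves only the single
        # leaf atom 4 and is demoted
        assert [tb.axis for tb in lig.torsion_bonds] == [(1, 2), (1, 6), (2, 3)]
        assert set(np.where(lig.torsion_bonds[2].moving)[0]) <= set(
            np.where(lig.torsion_bonds[0].moving)[0]
        )

    def test_terminal_leaf_bond_demoted(self):
        # 3-atom chain: the first bond carries a real torsion (atom 2 moves),
        # the last would rotate only the single leaf atom and is demoted
        atoms = chain_atoms(3)
        bonds = [(0, 1, True), (1, 2, True)]
        lig = build_torsion_tree(atoms, bonds, root_hint=0)
        assert [tb.axis for tb in lig.torsion_bonds] == [(0, 1)]

    def test_disconnected_raises(self):
        atoms = chain_atoms(4)
        bonds = [(0, 1, False), (2, 3, False)]
        with pytest.raises(ValueError):
            build_torsion_tree(atoms, bonds)


@pytest.fixture()
def simple_ligand():
    atoms = chain_atoms(4)
    bonds = [(0, 1, False), (1, 2, True), (2, 3, False)]
    return build_torsion_tree(atoms, bonds, root_hint=0)


class TestApplyPose:
    def test_identity(self, simple_ligand):
        coords = apply_pose(simple_ligand, Pose.identity(1))
        assert np.allclose(coords, simple_ligand.ref_coords())

    def test_pure_translation(self, simple_ligand):
        pose = Pose(np.array([1.0, 0, 0]), np.array([0.0, 0, 0, 1.0]), np.zeros(1))
        coords = apply_pose(simple_ligand, pose)
        assert np.allclose(coords, simple_ligand.ref_coords() + [1.0, 0, 0])

    def test_180_degree_torsion_mirrors_moving_set(self, simple_ligand):
        pose = Pose(np.zeros(3), np.array([0.0, 0, 0, 1.0]), np.array([np.pi]))
        coords = apply_pose(simple_ligand, pose)
        ref = simple_ligand.ref_coords()
        a, b = simple_ligand.torsion_bonds[0].axis
        axis = ref[b] - ref[a]
        axis /= np.linalg.norm(axis)
        # hand geometry: atom 3 reflects through the bond axis line
        v = ref[3] - ref[a]
        expected = ref[a] + 2 * (v @ axis) * axis - v
        assert np.allclose(coords[3], expected, atol=1e-9)
        assert np.allclose(coords[:3], ref[:3])  # root and axis atoms fixed

    def test_root_fragment_rigid_under_any_pose(self, simple_ligand, rng):
        ref = simple_ligand.ref_coords()
        root = sorted(simple_ligand.root_atoms)
        for _ in range(10):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            pose = Pose(rng.normal(0, 5, 3), q, rng.uniform(-np.pi, np.pi, 1))
            coords = apply_pose(simple_ligand, pose)
            d_ref = np.linalg.norm(ref[root][:, None] - ref[root][None], axis=2)
            d_new = np.linalg.norm(coords[root][:, None] - coords[root][None], axis=2)
            assert np.allclose(d_ref, d_new, atol=1e-9)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(theta=st.floats(-3.1, 3.1))
    def test_torsion_inverts(self, theta):
        from sh2dock.molecules import _rotate_about_axis

        atoms = chain_atoms(4)
        bonds = [(0, 1, False), (1, 2, True), (2, 3, False)]
        simple_ligand = build_torsion_tree(atoms, bonds, root_hint=0)

        q = np.array([0.0, 0, 0, 1.0])
        fwd = apply_pose(simple_ligand, Pose(np.zeros(3), q, np.array([theta])))
        tb = simple_ligand.torsion_bonds[0]
        a, b = tb.axis
        undone = fwd.copy()
        undone[tb.moving] = _rotate_about_axis(
            fwd[tb.moving], fwd[a], fwd[b] - fwd[a], -theta
        )
        assert np.allclose(undone, simple_ligand.ref_coords(), atol=1e-9)


class TestTrajectoryIO:
    def _traj(self, n_frames=2, n_atoms=3):
        rng = np.random.default_rng(5)
        atoms = chain_atoms(n_atoms)
        return Trajectory(
            coords=rng.normal(0, 4, (n_frames, n_atoms, 3)),
            atoms=atoms,
            frame_spacing=10.0,
            residue_numbers=np.ones(n_atoms, dtype=int),
            residue_names=["MOL"] * n_atoms,
        )

    @pytest.mark.parametrize("fmt", ["pdb", "txt"])
    def test_round_trip_coordinates(self, tmp_path, fmt):
        traj = self._traj()
        path = tmp_path / f"t.{fmt}"
        write_trajectory(traj, path, fmt=fmt)
        back = read_trajectory(path, fmt=fmt)
        assert back.n_frames == traj.n_frames
        assert np.allclose(back.coords, traj.coords, atol=1e-3)

    def test_missing_atom_reports_frame(self, tmp_path):
        traj = self._traj()
        path = tmp_path / "t.txt"
        write_trajectory(traj, path, fmt="txt")
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]))  # drop last atom of frame 1
        with pytest.raises(ValueError, match="frame 1"):
            read_trajectory(path, fmt="txt")

    def test_thousand_frame_trajectory_metadata(self, planted):
        traj = planted.traj
        assert traj.n_frames == 1000
        assert traj.frame_spacing == 10.0

    def test_frame_count_mismatch_rejected(self):
        atoms = chain_atoms(3)
        with pytest.raises(ValueError):
            Trajectory(coords=np.zeros((2, 4, 3)), atoms=atoms)


class TestLigandFile:
    def test_round_trip(self, tmp_path, toy10):
        path = tmp_path / "lig.lig"
        write_ligand_file(toy10.ligand, path)
        back = read_ligand_file(path)
        assert back.n_rotatable == toy10.ligand.n_rotatable
        assert back.anchor_index() == toy10.ligand.anchor_index()
        assert back.cterm_atoms == toy10.ligand.cterm_atoms
        assert np.allclose(back.ref_coords(), toy10.ligand.ref_coords(), atol=1e-6)
        assert [a.is_acceptor for a in back.atoms] == [
            a.is_acceptor for a in toy10.ligand.atoms
        ]
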