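import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.metrics import adjusted_rand_score

from sh2dock.molecules import Atom, Trajectory
from sh2dock.trajectory_analysis import (
    HBond,
    HBondCriteria,
    cluster_kmeans,
    detect_hbonds,
    fit_trajectory,
    occupancy,
    rmsf,
    rmsf_per_atom,
    strip_solvent,
    weighted_rmsd,
)


def make_traj(frames, masses=None, **kw):
    frames = np.asarray(frames, dtype=float)
    n = frames.shape[1]
    atoms = [
        Atom(id=i, name=f"C{i}", element="C", charge=0.0,
             mass=(masses[i] if masses is not None else 12.0),
             radius=1.7, coords=frames[0, i])
        for i in range(n)
    ]
    return Trajectory(coords=frames, atoms=atoms, **kw)


BASE = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.0, 2, 0], [0.5, 0.5, 1.5]])


class TestFit:
    def test_rigid_copies_fit_to_zero(self, rng):
        frames = [BASE]
        for _ in range(4):
            rot = Rotation.from_rotvec(rng.normal(0, 1, 3))
            frames.append(rot.apply(BASE) + rng.normal(0, 5, 3))
        fitted = fit_trajectory(make_traj(frames))
        assert np.all(fitted.fitted_rmsd <= 1e-6)

    def test_pure_translation_fits_exactly(self):
        fitted = fit_trajectory(make_traj([BASE, BASE + [5.0, 0, 0]]))
        assert fitted.fitted_rmsd[1] == pytest.approx(0.0, abs=1e-9)

    def test_displaced_atom_matches_rotation_grid_oracle(self):
        moved = BASE.copy()
        moved[3] += [0.6, -0.4, 0.3]
        traj = make_traj([BASE, moved])
        fitted = fit_trajectory(traj)
        # oracle: coarse rotation grid + Nelder-Mead polish, independent of Kabsch
        w = traj.masses() / traj.masses().sum()
        a = BASE - (w[:, None] * BASE).sum(0)
        b = moved - (w[:, None] * moved).sum(0)

        def msd(rv):
            d = a - Rotation.from_rotvec(rv).apply(b)
            return float((w * np.einsum("ij,ij->i", d, d)).sum())

        best = None
        for x in np.linspace(-np.pi, np.pi, 12, endpoint=False):
            for y in np.linspace(-np.pi, np.pi, 12, endpoint=False):
                for z in np.linspace(-np.pi, np.pi, 12, endpoint=False):
                    v = np.array([x, y, z])
                    if best is None or msd(v) < msd(best):
                        best = v
        from scipy.optimize import minimize

        res = minimize(msd, best, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        assert fitted.fitted_rmsd[1] == pytest.approx(np.sqrt(res.fun), abs=1e-4)

    def test_degenerate_frame_reported(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        with pytest.raises(ValueError, match="frame 0"):
            fit_trajectory(make_traj([line, line]))

    def test_solvent_stripped_before_fitting(self):
        frames = np.zeros((2, 3, 3))
        frames[:, 0] = BASE[:2].mean(0)
        traj = make_traj([BASE[:3], BASE[:3] + 1.0])
        traj.residue_names = ["MOL", "MOL", "HOH"]
        traj.residue_numbers = np.array([1, 1, 2])
        stripped = strip_solvent(traj)
        assert stripped.n_atoms == 2


class TestRmsf:
    def test_identical_frames_zero(self):
        fitted = fit_trajectory(make_traj([BASE] * 5))
        assert rmsf(fitted, atom_subset=np.arange(4)) == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_two_frames(self):
        # subset of one atom displaced 2 Å: a single-term mean, no fitting
        moved = BASE.copy()
        moved[3] += [0.0, 0.0, 2.0]
        traj = make_traj([BASE, moved])
        fitted = fit_trajectory(traj, strip=False)
        # disable superposition influence by fitting on the static subset
        fitted.traj.coords[:] = [BASE, moved]
        assert rmsf(fitted, atom_subset=[3]) == pytest.approx(2.0, abs=1e-9)

    def test_planted_jitter_matches_simulation_oracle(self, toy10, jitter_only):
        pt, fitted = jitter_only
        observed = rmsf(fitted)
        lig_idx = pt.traj.ligand_indices
        m = np.array([pt.traj.atoms[i].mass for i in lig_idx])
        w = m / m.sum()
        ref1 = pt.traj.coords[0, lig_idx]  # the realized first frame
        oracle_rng = np.random.default_rng(4242)
        vals = []
        for _ in range(3000):
            frame = toy10.planted_coords + oracle_rng.normal(0, pt.sigma, ref1.shape)
            d = frame - ref1
            vals.append(np.sqrt((w * np.einsum("ij,ij->i", d, d)).sum()))
        assert observed == pytest.approx(np.mean(vals), rel=0.03)

    def test_conventional_per_atom_variant(self, jitter_only):
        _, fitted = jitter_only
        per_atom = rmsf_per_atom(fitted)
        # jitter sigma 0.15 per coordinate -> per-atom RMSF ~ sqrt(3)*sigma
        assert per_atom.mean() == pytest.approx(np.sqrt(3) * 0.15, rel=0.05)

    def test_global_rigid_transform_invariance(self, rng):
        frames = [BASE + rng.normal(0, 0.1, BASE.shape) for _ in range(6)]
        rot = Rotation.from_rotvec([0.5, -0.1, 0.8])
        moved = [rot.apply(f) + [3, 4, 5] for f in frames]
        r1 = rmsf(fit_trajectory(make_traj(frames)), atom_subset=np.arange(4))
        r2 = rmsf(fit_trajectory(make_traj(moved)), atom_subset=np.arange(4))
        assert r1 == pytest.approx(r2, abs=1e-9)


class TestClustering:
    def test_planted_partition_recovered(self, planted, fitted):
        res = cluster_kmeans(fitted, k=5, seed=0)
        assert adjusted_rand_score(planted.cluster_labels, res.labels) == 1.0
        for c in range(5):
            assert res.labels[res.representatives[c]] == c

    def test_k1_global_medoid(self):
        rng = np.random.default_rng(3)
        frames = [BASE + rng.normal(0, 0.05, BASE.shape) for _ in range(7)]
        fitted = fit_trajectory(make_traj(frames))
        res = cluster_kmeans(fitted, k=1, seed=0, atom_subset=np.arange(4))
        assert res.k == 1 and set(res.labels) == {0}
        X = fitted.coords.reshape(7, -1)
        dmat = np.linalg.norm(X[:, None] - X[None], axis=2)
        assert res.representatives[0] == np.argmin(dmat.sum(axis=1))

    def test_identical_frames_degenerate(self):
        fitted = fit_trajectory(make_traj([BASE] * 6))
        res = cluster_kmeans(fitted, k=5, seed=0, atom_subset=np.arange(4))
        assert res.degenerate

    def test_k_exceeding_frames_rejected(self):
        fitted = fit_trajectory(make_traj([BASE] * 3))
        with pytest.raises(ValueError):
            cluster_kmeans(fitted, k=5, atom_subset=np.arange(4))


def hb_traj(donor_xyz, h_xyz, acc_xyz):
    """2-atom receptor donor (O-H) + 1-atom ligand acceptor, single frame."""
    atoms = [
        Atom(id=0, name="OD", element="O", charge=-0.3, mass=16.0, radius=1.52,
             coords=np.array(donor_xyz), is_acceptor=False),
        Atom(id=1, name="HD", element="H", charge=0.3, mass=1.0, radius=1.2,
             coords=np.array(h_xyz), is_donor_h=True),
        Atom(id=2, name="OA", element="O", charge=-0.3, mass=16.0, radius=1.52,
             coords=np.array(acc_xyz), is_acceptor=True),
        # spectator ligand atoms so superposition is non-degenerate
        Atom(id=3, name="C1", element="C", charge=0.0, mass=12.0, radius=1.7,
             coords=np.array([8.0, 4.0, 0.0])),
        Atom(id=4, name="C2", element="C", charge=0.0, mass=12.0, radius=1.7,
             coords=np.array([8.0, 0.0, 4.0])),
    ]
    coords = np.stack([np.array([a.coords for a in atoms])] * 2)
    traj = Trajectory(
        coords=coords, atoms=atoms,
        receptor_indices=np.array([0, 1]), ligand_indices=np.array([2, 3, 4]),
        residue_numbers=np.array([611, 611, 1, 1, 1]),
        residue_names=["SER", "SER", "LIG", "LIG", "LIG"],
    )
    return fit_trajectory(traj, strip=False)


class TestHbonds:
    def test_ideal_geometry_detected(self):
        fitted = hb_traj([0, 0, 0], [1.0, 0, 0], [2.9, 0, 0])
        bonds = detect_hbonds(fitted)
        assert len(bonds) == 1
        assert bonds[0].receptor_residue == 611
        assert bonds[0].presence.all()

    def test_distance_cutoff(self):
        fitted = hb_traj([0, 0, 0], [1.0, 0, 0], [4.0, 0, 0])
        assert detect_hbonds(fitted) == []

    def test_angle_cutoff(self):
        # donor-H along x, acceptor placed to give a 90 degree angle at H
        fitted = hb_traj([0, 0, 0], [1.0, 0, 0], [1.0, 2.7, 0])
        assert detect_hbonds(fitted) == []

    def test_criteria_configurable(self):
        fitted = hb_traj([0, 0, 0], [1.0, 0, 0], [3.8, 0, 0])
        assert detect_hbonds(fitted, criteria=HBondCriteria(4.0, 120.0))


class TestOccupancy:
    def bond(self, residue, mask):
        return HBond(donor=0, hydrogen=1, acceptor=2, receptor_residue=residue,
                     presence=np.asarray(mask, dtype=bool))

    def test_fraction_and_retention(self):
        mask = np.zeros(1000, dtype=bool)
        mask[:600] = True
        table = occupancy([self.bond(611, mask)], 1000)
        assert table.occupancy[0] == pytest.approx(0.6)
        assert table.retained[0]

    def test_450_of_1000_dropped(self):
        mask = np.zeros(1000, dtype=bool)
        mask[:450] = True
        table = occupancy([self.bond(612, mask)], 1000)
        assert table.occupancy[0] == pytest.approx(0.45)
        assert not table.retained[0]

    def test_union_of_disjoint_bonds(self):
        first, second = np.zeros(1000, bool), np.zeros(1000, bool)
        first[:500] = True
        second[500:] = True
        table = occupancy([self.bond(613, first), self.bond(613, second)], 1000)
        assert table.occupancy[0] == pytest.approx(1.0)

    def test_union_bound_property(self, rng):
        bonds = [self.bond(640, rng.random(200) < p) for p in (0.2, 0.5, 0.7)]
        table = occupancy(bonds, 200)
        assert table.occupancy[0] >= max(b.occupancy for b in bonds) - 1e-12


def test_weighted_rmsd_symmetry(rng):
    a, b = rng.normal(0, 2, (4, 3)), rng.normal(0, 2, (4, 3))
    w = rng.uniform(1, 3, 4)
    assert weighted_rmsd(a, b, w) == pytest.approx(weighted_rmsd(b, a, w))
    assert weighted_rmsd(a, a, w) == 0.0
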