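import numpy as np
import pandas as pd
import pytest
import sympy

from sh2dock.affinity import (
    ExperimentalRecord,
    R_GAS,
    T_STANDARD,
    correlation_vs_length,
    dg_from_ic50,
    dg_from_ki,
    estimate_affinity,
    experimental_table,
    ki_from_ic50,
    load_external_energies,
    normal_mode_entropy,
    snapshot_energies,
    _HBAR_OVER_KB,
    _KCAL_PER_A2_AMU_TO_S2,
)
from sh2dock.synthetic_data import (
    make_affinity_table,
    make_planted_trajectory,
    make_snapshot_components,
)
from sh2dock.trajectory_analysis import fit_trajectory


class TestChengPrusoff:
    def test_printed_example_exact(self):
        # IC50 190 nM, probe 10 nM, probe Kd 150 nM
        assert ki_from_ic50(190.0) == pytest.approx(178.125, abs=1e-12)

    def test_no_competition_limit(self):
        assert ki_from_ic50(250.0, probe_conc_nM=0.0) == 250.0

    def test_probe_at_kd_halves(self):
        assert ki_from_ic50(100.0, probe_conc_nM=150.0) == pytest.approx(50.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ki_from_ic50(-1.0)


class TestDeltaG:
    def test_one_molar_is_zero(self):
        assert dg_from_ki(1e9) == pytest.approx(0.0, abs=1e-12)

    def test_arbitrary_precision_oracle(self):
        # RT·ln(178.125e-9 mol/L) evaluated with sympy at 50 digits
        expected = float(
            sympy.N(sympy.Rational("0.001986") * 298
                    * sympy.log(sympy.Rational("178.125") * sympy.Integer(10) ** -9), 50)
        )
        assert dg_from_ki(178.125) == pytest.approx(expected, abs=1e-9)
        assert dg_from_ic50(190.0) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-9.20, abs=0.005)

    def test_tenfold_shift_is_rt_ln10(self):
        shift = dg_from_ki(100.0) - dg_from_ki(1000.0)
        assert shift == pytest.approx(-R_GAS * T_STANDARD * np.log(10.0), abs=1e-12)

    def test_monotone_in_ic50(self):
        dgs = [dg_from_ic50(v) for v in (39.0, 190.0, 1000.0, 100000.0)]
        assert dgs == sorted(dgs)

    def test_log10_option(self):
        assert dg_from_ki(178.125, log10=True) == pytest.approx(
            dg_from_ki(178.125) / np.log(10.0)
        )


class TestSchemes:
    def test_constant_components(self):
        snaps = make_snapshot_components(100, mean=(-15.0, -3.0, -2.0),
                                         sigma=(0.0, 0.0, 0.0), seed=0)
        est = estimate_affinity(snaps, scheme="A")
        assert est.dg_bind == pytest.approx(-20.0, abs=1e-9)
        assert est.minus_t_ds == 0.0

    def test_entropy_additivity(self):
        snaps = make_snapshot_components(200, seed=1)
        a = estimate_affinity(snaps, scheme="A")
        c = estimate_affinity(snaps, scheme="C", minus_t_ds=15.0)
        assert c.dg_bind == pytest.approx(a.dg_bind + 15.0, abs=1e-12)

    def test_scheme_identities(self):
        snaps = make_snapshot_components(300, seed=2)
        pb = make_snapshot_components(300, mean=(-30.0, 12.0, -2.0), seed=3)
        ts = 11.5
        a = estimate_affinity(snaps, "A").dg_bind
        b = estimate_affinity(snaps, "B", pb_snapshots=pb).dg_bind
        c = estimate_affinity(snaps, "C", minus_t_ds=ts).dg_bind
        d = estimate_affinity(snaps, "D", minus_t_ds=ts, pb_snapshots=pb).dg_bind
        assert c - a == pytest.approx(ts, abs=1e-12)
        assert d - b == pytest.approx(ts, abs=1e-12)
        assert (c - a) == pytest.approx(d - b, abs=1e-12)

    def test_prefix_mean_matches_hand_computation(self):
        snaps = make_snapshot_components(1000, seed=4)
        est = estimate_affinity(snaps, "A", prefix_fraction=0.2)
        assert est.n_frames_used == 200
        assert est.dg_bind == pytest.approx(float(snaps.nonentropic()[:200].mean()))

    def test_frame_order_invariance_within_prefix(self):
        snaps = make_snapshot_components(500, seed=5)
        est = estimate_affinity(snaps, "A")
        rng = np.random.default_rng(0)
        perm = rng.permutation(500)
        snaps.d_e_mm = snaps.d_e_mm[perm]
        snaps.d_g_polar = snaps.d_g_polar[perm]
        snaps.d_g_nonpolar = snaps.d_g_nonpolar[perm]
        assert estimate_affinity(snaps, "A").dg_bind == pytest.approx(est.dg_bind)

    def test_pb_scheme_requires_channel(self):
        snaps = make_snapshot_components(50, seed=6)
        with pytest.raises(ValueError):
            estimate_affinity(snaps, "B")

    def test_prefix_convergence_on_stationary_input(self):
        snaps = make_snapshot_components(2000, mean=(-35.0, 18.0, -2.5), seed=7)
        truth = -35.0 + 18.0 - 2.5
        errs = [abs(estimate_affinity(snaps, "A", prefix_fraction=f).dg_bind - truth)
                for f in (0.2, 1.0)]
        assert errs[1] < 0.5 and errs[0] < 1.0


class TestEntropy:
    def test_harmonic_oscillator_closed_form(self):
        k, m = 25.0, 14.0
        val = normal_mode_entropy(lambda x: 0.5 * k * np.sum(x**2),
                                  np.zeros((1, 3)), np.array([m]), rigid_modes=0)
        omega = np.sqrt(k * _KCAL_PER_A2_AMU_TO_S2 / m)
        x = _HBAR_OVER_KB * omega / 298.0
        s = R_GAS * (x / np.expm1(x) - np.log1p(-np.exp(-x)))
        assert val == pytest.approx(-298.0 * 3 * s, rel=0.01)

    def test_stiff_limit_vanishes(self):
        val = normal_mode_entropy(lambda x: 0.5 * 1e6 * np.sum(x**2),
                                  np.zeros((1, 3)), np.array([1.0]), rigid_modes=0)
        assert abs(val) < 1e-6

    def test_diatomic_single_mode(self):
        k, d0 = 300.0, 1.5

        def bond(x):
            r = np.linalg.norm(x[0] - x[1])
            return 0.5 * k * (r - d0) ** 2

        coords = np.array([[0.0, 0, 0], [d0, 0, 0]])
        v_lin = normal_mode_entropy(bond, coords, np.array([12.0, 12.0]), linear=True)
        # a single vibration: equals the analytic 1-mode entropy with reduced mass
        mu = 6.0
        omega = np.sqrt(2 * k / 12.0 * _KCAL_PER_A2_AMU_TO_S2)
        x = _HBAR_OVER_KB * omega / 298.0
        s = R_GAS * (x / np.expm1(x) - np.log1p(-np.exp(-x)))
        assert v_lin == pytest.approx(-298.0 * s, rel=0.01)
        assert mu == pytest.approx(12.0 / 2)


class TestSnapshotEnergies:
    def test_separated_ligand_nearly_zero_deltas(self, toy10):
        pt = make_planted_trajectory(toy10, n_frames=3, sigma=0.0, seed=0)
        traj = pt.traj
        traj.coords[:, traj.ligand_indices] += 150.0
        fitted = fit_trajectory(traj)
        snaps = snapshot_energies(fitted)
        assert np.all(np.abs(snaps.d_e_mm) < 1e-6)
        assert np.all(np.abs(snaps.d_g_nonpolar) < 0.05)

    def test_stride_frame_count(self, fitted):
        snaps = snapshot_energies(fitted, stride=100)
        assert snaps.n_frames == 10

    def test_single_frame_matches_pairwise_oracle(self, toy10):
        from sh2dock.energy import EnergyModel, COULOMB

        pt = make_planted_trajectory(toy10, n_frames=1, sigma=0.0, seed=0)
        fitted = fit_trajectory(pt.traj)
        snaps = snapshot_energies(fitted)
        traj = fitted.traj
        model = EnergyModel()
        # oracle: explicit double loop over receptor-ligand pairs
        e = 0.0
        for i in traj.receptor_indices:
            for j in traj.ligand_indices:
                ai, aj = traj.atoms[i], traj.atoms[j]
                d2 = float(np.sum((traj.coords[0, i] - traj.coords[0, j]) ** 2))
                if d2 > model.cutoff**2:
                    continue
                sig_i = 2 * ai.radius / 2 ** (1 / 6)
                sig_j = 2 * aj.radius / 2 ** (1 / 6)
                a12 = 4 * np.sqrt(ai.epsilon * aj.epsilon) * (sig_i * sig_j) ** 6
                a6 = 4 * np.sqrt(ai.epsilon * aj.epsilon) * (sig_i * sig_j) ** 3
                r2 = max(d2, 1.0)
                e += min(a12 / r2**6, model.repulsion_cap) - a6 / r2**3
                e += COULOMB * ai.charge * aj.charge / (4.0 * max(d2, 1.0))
        assert snaps.d_e_mm[0] == pytest.approx(e, abs=1e-6)

    def test_external_csv_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "frame": [0, 1, 2],
            "d_e_mm": [-30.0, -31.0, -29.5],
            "d_g_polar": [12.0, 12.5, 11.8],
            "d_g_nonpolar": [-2.0, -2.1, -1.9],
        })
        path = tmp_path / "pb.csv"
        df.to_csv(path, index=False)
        snaps = load_external_energies(path)
        assert snaps.source == "external-file"
        assert snaps.nonentropic()[0] == pytest.approx(-20.0)


class TestCorrelation:
    def records(self, dg_est):
        recs = [ExperimentalRecord(f"c{i}", float(v))
                for i, v in enumerate(np.geomspace(50, 50000, len(dg_est)))]
        return recs

    def estimates_frame(self, recs, values, prefix=1.0):
        return pd.DataFrame({
            "compound": [r.compound for r in recs],
            "prefix_fraction": prefix,
            "dg_bind": values,
        })

    def test_affine_relation_gives_unit_correlation(self):
        recs = self.records(np.zeros(6))
        dg_exp = experimental_table(recs)["dg_exp"].to_numpy()
        out = correlation_vs_length(self.estimates_frame(recs, 2 * dg_exp + 1), recs)
        assert out["pearson_r"].iloc[0] == pytest.approx(1.0)
        out = correlation_vs_length(self.estimates_frame(recs, -dg_exp), recs)
        assert out["pearson_r"].iloc[0] == pytest.approx(-1.0)

    def test_planted_table_matches_definition_oracle(self):
        records, dg_est, realized = make_affinity_table(12, target_r=0.63, seed=5)
        out = correlation_vs_length(
            self.estimates_frame(records, dg_est), records)
        r_pkg = out["pearson_r"].iloc[0]
        dg_exp = np.array([dg_from_ic50(r.ic50_nM) for r in records])
        x, y = dg_est - dg_est.mean(), dg_exp - dg_exp.mean()
        r_def = float((x @ y) / np.sqrt((x @ x) * (y @ y)))
        assert r_pkg == pytest.approx(r_def, abs=1e-12)
        assert r_pkg == pytest.approx(realized, abs=1e-12)

    def test_censored_flagging_and_exclusion(self):
        records, dg_est, _ = make_affinity_table(10, target_r=0.8, seed=2)
        frame = self.estimates_frame(records, dg_est)
        full = correlation_vs_length(frame, records)
        assert full["n_censored"].iloc[0] == 1
        reduced = correlation_vs_length(frame, records, include_censored=False)
        assert reduced["n"].iloc[0] == 9

    def test_zero_variance_rejected(self):
        recs = self.records(np.zeros(5))
        with pytest.raises(ValueError):
            correlation_vs_length(self.estimates_frame(recs, np.ones(5)), recs)

    def test_too_few_compounds_rejected(self):
        recs = self.records(np.zeros(2))
        with pytest.raises(ValueError):
            correlation_vs_length(self.estimates_frame(recs, [1.0, 2.0]), recs)
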