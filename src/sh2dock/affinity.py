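"""Snapshot-averaged binding-affinity estimation and experimental conversion.

The binding free energy is estimated end-point style over trajectory
snapshots:

    ΔG_bind = ⟨ΔE_MM + ΔG_polar + ΔG_nonpolar⟩ − T·ΔS

with the Δ taken complex − receptor − ligand on the same frames
(single-trajectory decomposition).  Four schemes are supported:
A (GB polar term, entropy ignored), B (externally supplied PB polar term,
entropy ignored), C (= A + entropy) and D (= B + entropy).  The entropy
penalty comes from harmonic normal-mode analysis of locally minimized
snapshots.  Experimental IC50 values convert to ΔG via the Cheng–Prusoff
inhibition constant and ΔG_exp = RT·ln(Ki in mol/L) at T = 298 K with
R = 0.001986 kcal/(K·mol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .energy import EnergyModel, gb_polar_energy, pairwise_energy, sasa

R_GAS = 0.001986  # kcal / (K mol)
T_STANDARD = 298.0  # K
# ħ/k_B in seconds·K, and the conversion (kcal/mol/Å²)/(amu) -> s⁻² for ω²
_HBAR_OVER_KB = 7.638232e-12
_KCAL_PER_A2_AMU_TO_S2 = 4184.0 / 6.02214076e23 * 1e20 / 1.66053906660e-27

__all__ = [
    "SnapshotEnergies",
    "AffinityEstimate",
    "ExperimentalRecord",
    "snapshot_energies",
    "load_external_energies",
    "harmonic_entropy",
    "normal_mode_entropy",
    "estimate_affinity",
    "ki_from_ic50",
    "dg_from_ki",
    "dg_from_ic50",
    "correlation_vs_length",
]


@dataclass
class SnapshotEnergies:
    """Per-frame Δ-components (complex − receptor − ligand), kcal/mol."""

    d_e_mm: np.ndarray
    d_g_polar: np.ndarray
    d_g_nonpolar: np.ndarray
    source: str = "native-GB"

    def __post_init__(self) -> None:
        for arr in (self.d_e_mm, self.d_g_polar, self.d_g_nonpolar):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite snapshot energy component")

    @property
    def n_frames(self) -> int:
        return len(self.d_e_mm)

    def nonentropic(self) -> np.ndarray:
        return self.d_e_mm + self.d_g_polar + self.d_g_nonpolar


@dataclass
class AffinityEstimate:
    scheme: str
    dg_bind: float
    minus_t_ds: float
    n_frames_used: int
    temperature: float = T_STANDARD


@dataclass
class ExperimentalRecord:
    compound: str
    ic50_nM: float
    censored: bool = False
    ki_nM: float | None = None
    dg_exp: float | None = None

    def __post_init__(self) -> None:
        if self.ic50_nM <= 0:
            raise ValueError("IC50 must be positive")


def snapshot_energies(
    fitted,
    model: EnergyModel | None = None,
    stride: int = 1,
    screen: float = 0.8,
) -> SnapshotEnergies:
    """Per-frame Δ-components from a fitted complex trajectory (native GB path).

    The complex, receptor and ligand terms come from the same frames, so the
    intramolecular MM terms cancel exactly and ΔE_MM reduces to the
    receptor–ligand interaction energy; ΔG_polar and ΔG_nonpolar are genuine
    three-evaluation differences.
    """
    model = model or EnergyModel()
    traj = fitted.traj
    rec_idx, lig_idx = traj.receptor_indices, traj.ligand_indices
    if rec_idx is None or lig_idx is None:
        raise ValueError("trajectory lacks receptor/ligand selections")
    if np.intersect1d(rec_idx, lig_idx).size:
        raise ValueError("receptor and ligand selections overlap")

    charges = np.array([a.charge for a in traj.atoms])
    radii = np.array([a.radius for a in traj.atoms])
    eps = np.array([a.epsilon for a in traj.atoms])
    screens = np.full(traj.n_atoms, screen)
    frames = range(0, traj.n_frames, stride)

    d_mm, d_pol, d_np = [], [], []
    all_idx = np.concatenate([rec_idx, lig_idx])
    for f in frames:
        xyz = traj.coords[f]
        e_inter_vdw, e_inter_elec = pairwise_energy(
            xyz[lig_idx], charges[lig_idx], radii[lig_idx], eps[lig_idx],
            xyz[rec_idx], charges[rec_idx], radii[rec_idx], eps[rec_idx], model,
        )
        g_pol_cpx = gb_polar_energy(xyz[all_idx], charges[all_idx], radii[all_idx], model, screen=screens[all_idx])
        g_pol_rec = gb_polar_energy(xyz[rec_idx], charges[rec_idx], radii[rec_idx], model, screen=screens[rec_idx])
        g_pol_lig = gb_polar_energy(xyz[lig_idx], charges[lig_idx], radii[lig_idx], model, screen=screens[lig_idx])
        sasa_cpx = sasa(xyz[all_idx], radii[all_idx], model.probe_radius, model.sasa_points).sum()
        sasa_rec = sasa(xyz[rec_idx], radii[rec_idx], model.probe_radius, model.sasa_points).sum()
        sasa_lig = sasa(xyz[lig_idx], radii[lig_idx], model.probe_radius, model.sasa_points).sum()
        d_mm.append(e_inter_vdw + e_inter_elec)
        d_pol.append(g_pol_cpx - g_pol_rec - g_pol_lig)
        # the offset b is an absolute-scale reference and cancels in the
        # binding decomposition: ΔG_nonpolar = γ·ΔSASA
        d_np.append(model.surface_tension * (sasa_cpx - sasa_rec - sasa_lig))
    return SnapshotEnergies(
        d_e_mm=np.array(d_mm), d_g_polar=np.array(d_pol), d_g_nonpolar=np.array(d_np),
        source="native-GB",
    )


def load_external_energies(path) -> SnapshotEnergies:
    """Load per-snapshot Δ-components from CSV (frame, d_e_mm, d_g_polar,
    d_g_nonpolar) — the input channel for externally computed PB energies."""
    df = pd.read_csv(path).sort_values("frame")
    return SnapshotEnergies(
        d_e_mm=df["d_e_mm"].to_numpy(float),
        d_g_polar=df["d_g_polar"].to_numpy(float),
        d_g_nonpolar=df["d_g_nonpolar"].to_numpy(float),
        source="external-file",
    )


# ---------------------------------------------------------------------------
# Normal-mode entropy


def harmonic_entropy(omega: np.ndarray, temperature: float = T_STANDARD) -> float:
    """Vibrational entropy (kcal/mol/K) of harmonic modes with angular
    frequencies ``omega`` (s⁻¹), from the quantum harmonic-oscillator
    partition function."""
    x = _HBAR_OVER_KB * np.asarray(omega) / temperature  # ħω/kT
    s = R_GAS * (x / np.expm1(x) - np.log1p(-np.exp(-x)))
    return float(s.sum())


def _minimize(energy_fn, coords, n_steps=200, step=1e-3):
    """Plain gradient descent with numeric gradients (local pre-relaxation)."""
    x = coords.copy().ravel()
    h = 1e-5
    for _ in range(n_steps):
        grad = np.zeros_like(x)
        for i in range(len(x)):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            grad[i] = (energy_fn(xp.reshape(coords.shape)) - energy_fn(xm.reshape(coords.shape))) / (2 * h)
        x -= step * grad
    return x.reshape(coords.shape)


def normal_mode_entropy(
    energy_fn,
    coords: np.ndarray,
    masses: np.ndarray,
    temperature: float = T_STANDARD,
    minimize_steps: int = 0,
    h: float = 1e-4,
    linear: bool = False,
    rigid_modes: int | None = None,
) -> float:
    """−T·S_vib (kcal/mol) from finite-difference normal-mode analysis.

    The mass-weighted Hessian of ``energy_fn`` (kcal/mol as a function of an
    (n, 3) coordinate array) is built by central differences; the 6 smallest
    |eigenvalue| modes (5 if ``linear``) are discarded as rigid-body modes,
    and the remaining frequencies enter the harmonic-oscillator entropy at
    ``temperature``.  Warns if more than the expected number of modes are
    near-zero (ill-minimized input).
    """
    coords = np.asarray(coords, dtype=float)
    if minimize_steps > 0:
        coords = _minimize(energy_fn, coords, n_steps=minimize_steps)
    n = coords.shape[0]
    dof = 3 * n
    x0 = coords.ravel()

    hess = np.zeros((dof, dof))
    for i in range(dof):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        gp = _num_grad(energy_fn, xp, coords.shape, h)
        gm = _num_grad(energy_fn, xm, coords.shape, h)
        hess[i] = (gp - gm) / (2 * h)
    hess = 0.5 * (hess + hess.T)

    m = np.repeat(np.asarray(masses, dtype=float), 3)
    mw = hess / np.sqrt(np.outer(m, m))
    evals = np.linalg.eigvalsh(mw)

    if rigid_modes is None:
        rigid_modes = 5 if linear else 6
        rigid_modes = min(rigid_modes, dof)
    order = np.argsort(np.abs(evals))
    keep = np.sort(order[rigid_modes:])
    kept = evals[keep]
    near_zero = int((np.abs(evals) < 1e-6).sum())
    if near_zero > rigid_modes:
        import logging

        logging.getLogger(__name__).warning(
            "%d near-zero modes (> %d expected): structure may not be minimized",
            near_zero, rigid_modes,
        )
    kept = kept[kept > 1e-10]  # imaginary modes excluded from the entropy
    omega = np.sqrt(kept * _KCAL_PER_A2_AMU_TO_S2)
    s_vib = harmonic_entropy(omega, temperature)
    return -temperature * s_vib


def _num_grad(energy_fn, x, shape, h):
    g = np.zeros_like(x)
    for i in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (energy_fn(xp.reshape(shape)) - energy_fn(xm.reshape(shape))) / (2 * h)
    return g


def binding_entropy_term(
    energy_fns: dict, coords: dict, masses: dict, temperature: float = T_STANDARD, **kw
) -> float:
    """−TΔS = −T(S_complex − S_receptor − S_ligand) on one snapshot."""
    t = {}
    for key in ("complex", "receptor", "ligand"):
        t[key] = normal_mode_entropy(
            energy_fns[key], coords[key], masses[key], temperature, **kw
        )
    return t["complex"] - t["receptor"] - t["ligand"]


# ---------------------------------------------------------------------------
# Scheme combination


def estimate_affinity(
    snapshots: SnapshotEnergies,
    scheme: str = "A",
    minus_t_ds: float | np.ndarray = 0.0,
    prefix_fraction: float = 1.0,
    pb_snapshots: SnapshotEnergies | None = None,
) -> AffinityEstimate:
    """Scheme A/B/C/D affinity estimate over a leading prefix of frames.

    A: GB non-entropic; B: external-PB non-entropic; C = A + (−TΔS);
    D = B + (−TΔS).  ``prefix_fraction`` restricts all averages to the first
    fraction of frames, emulating estimates from truncated simulations.
    """
    scheme = scheme.upper()
    if scheme not in "ABCD" or len(scheme) != 1:
        raise ValueError("scheme must be one of A, B, C, D")
    if not (0.0 < prefix_fraction <= 1.0):
        raise ValueError("prefix_fraction must be in (0, 1]")
    if scheme in ("B", "D"):
        if pb_snapshots is None:
            raise ValueError(f"scheme {scheme} requires externally supplied PB energies")
        source = pb_snapshots
    else:
        source = snapshots
    n_use = max(1, int(round(prefix_fraction * source.n_frames)))
    nonentropic = float(source.nonentropic()[:n_use].mean())
    if scheme in ("C", "D"):
        ts_arr = np.atleast_1d(np.asarray(minus_t_ds, dtype=float))
        if ts_arr.size > 1:
            n_ts = max(1, int(round(prefix_fraction * ts_arr.size)))
            ts = float(ts_arr[:n_ts].mean())
        else:
            ts = float(ts_arr[0])
    else:
        ts = 0.0
    return AffinityEstimate(
        scheme=scheme, dg_bind=nonentropic + ts, minus_t_ds=ts, n_frames_used=n_use
    )


# ---------------------------------------------------------------------------
# Experimental conversion (Cheng–Prusoff + ΔG)


def ki_from_ic50(ic50_nM: float, probe_conc_nM: float = 10.0, probe_kd_nM: float = 150.0) -> float:
    """Cheng–Prusoff inhibition constant for a competition assay (nM)."""
    if ic50_nM <= 0 or probe_conc_nM < 0 or probe_kd_nM <= 0:
        raise ValueError("concentrations must be positive")
    return ic50_nM / (1.0 + probe_conc_nM / probe_kd_nM)


def dg_from_ki(
    ki_nM: float, temperature: float = T_STANDARD, r_gas: float = R_GAS, log10: bool = False
) -> float:
    """ΔG_exp = RT·ln(Ki in mol/L), kcal/mol (optionally RT·log10, exposed
    for sensitivity analyses)."""
    if ki_nM <= 0:
        raise ValueError("Ki must be positive")
    ki_molar = ki_nM * 1e-9
    return r_gas * temperature * (np.log10(ki_molar) if log10 else np.log(ki_molar))


def dg_from_ic50(ic50_nM: float, **kw) -> float:
    return dg_from_ki(ki_from_ic50(ic50_nM), **kw)


def experimental_table(records: list[ExperimentalRecord]) -> pd.DataFrame:
    """Fill in Ki and ΔG_exp for a list of experimental records."""
    rows = []
    for rec in records:
        ki = ki_from_ic50(rec.ic50_nM)
        dg = dg_from_ki(ki)
        rec.ki_nM, rec.dg_exp = ki, dg
        rows.append(
            {"compound": rec.compound, "ic50_nM": rec.ic50_nM, "censored": rec.censored,
             "ki_nM": ki, "dg_exp": dg}
        )
    return pd.DataFrame(rows)


def correlation_vs_length(
    estimates: pd.DataFrame,
    records: list[ExperimentalRecord],
    include_censored: bool = True,
) -> pd.DataFrame:
    """Pearson R between estimated and experimental ΔG at each prefix fraction.

    ``estimates`` columns: compound, prefix_fraction, dg_bind.  Censored
    IC50s (reported only as a bound) enter at the bound value and are
    flagged; set ``include_censored=False`` to drop them.
    """
    exp = experimental_table(records).set_index("compound")
    if not include_censored:
        exp = exp[~exp["censored"]]
    rows = []
    for prefix, grp in estimates.groupby("prefix_fraction"):
        merged = grp.set_index("compound").join(exp, how="inner")
        if len(merged) < 3:
            raise ValueError(f"prefix {prefix}: need >= 3 compounds for a correlation")
        if np.isclose(merged["dg_bind"].std(), 0) or np.isclose(merged["dg_exp"].std(), 0):
            raise ValueError(f"prefix {prefix}: zero variance in one variable")
        r, _ = pearsonr(merged["dg_bind"], merged["dg_exp"])
        rows.append(
            {"prefix_fraction": prefix, "pearson_r": float(r), "n": len(merged),
             "n_censored": int(merged["censored"].sum())}
        )
    return pd.DataFrame(rows).sort_values("prefix_fraction").reset_index(drop=True)
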