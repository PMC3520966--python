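"""Interaction-energy surrogate and solvation terms.

The docking/affinity energetics use a self-contained surrogate model:

* Lennard-Jones with geometric (OPLS-style) mixing — chosen because it makes
  the receptor field exactly separable into per-probe-species grid maps,
* Coulomb electrostatics with a distance-dependent dielectric ε(r) = 4r,
* polar solvation by a Hawkins–Cramer–Truhlar (HCT) pairwise-descreening
  generalized Born model with the Still cross term,
* nonpolar solvation as γ·SASA + b with Shrake–Rupley sphere sampling.

Energies are kcal/mol, lengths Å, charges elementary charges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np


logger = logging.getLogger(__name__)

COULOMB = 332.06  # kcal·Å/(mol·e²)
# distance floor (Å²) for the Coulomb term: with the capped LJ repulsion a
# bare 1/r² attraction would otherwise create a non-physical sink at r → 0
COULOMB_R2_FLOOR = 1.0
# distance floor (Å²) for the LJ terms: with the repulsion capped, the r⁻⁶
# attraction would otherwise dominate as r → 0
LJ_R2_FLOOR = 1.0

__all__ = [
    "EnergyModel",
    "EnergyBreakdown",
    "GridMaps",
    "precompute_grids",
    "interaction_energy",
    "pairwise_energy",
    "gb_polar_energy",
    "sasa",
    "intramolecular_energy",
]


@dataclass
class EnergyModel:
    """Parameters of the surrogate energy function."""

    dielectric_slope: float = 4.0  # ε(r) = slope · r
    cutoff: float = 12.0
    repulsion_cap: float = 1.0e5
    solvent_dielectric: float = 78.5
    solute_dielectric: float = 1.0
    surface_tension: float = 0.00542  # γ, kcal/mol/Å²
    surface_offset: float = 0.92  # b, kcal/mol
    probe_radius: float = 1.4
    sasa_points: int = 240

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.surface_tension < 0:
            raise ValueError("surface tension must be non-negative")
        if self.solvent_dielectric < 1 or self.solute_dielectric < 1:
            raise ValueError("dielectrics must be >= 1")


@dataclass
class EnergyBreakdown:
    e_vdw: float = 0.0
    e_elec: float = 0.0
    e_internal: float = 0.0
    g_gb: float = 0.0
    g_sasa_nonpolar: float = 0.0

    @property
    def total(self) -> float:
        return self.e_vdw + self.e_elec + self.e_internal + self.g_gb + self.g_sasa_nonpolar


def _lj_coeffs(radius: np.ndarray, epsilon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom separable LJ factors under geometric mixing.

    With ε_ij = √(ε_i ε_j) and σ_ij³ = σ_i^{3/2} σ_j^{3/2} the pair energy
    4ε_ij (σ_ij¹²/r¹² − σ_ij⁶/r⁶) factors into a12_i·a12_j/r¹² − a6_i·a6_j/r⁶
    with a12 = 2√ε σ⁶ and a6 = 2√ε σ³.
    """
    sigma = radius * 2.0 / 2 ** (1 / 6)  # vdW radius = r_min/2 → σ
    a12 = 2.0 * np.sqrt(epsilon) * sigma**6
    a6 = 2.0 * np.sqrt(epsilon) * sigma**3
    return a12, a6


def pairwise_energy(
    coords_a, charge_a, radius_a, eps_a, coords_b, charge_b, radius_b, eps_b,
    model: EnergyModel,
) -> tuple[float, float]:
    """Direct (e_vdw, e_elec) between two atom sets, kcal/mol."""
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.maximum(r2, LJ_R2_FLOOR, out=r2)
    mask = r2 <= model.cutoff**2
    a12a, a6a = _lj_coeffs(np.asarray(radius_a), np.asarray(eps_a))
    a12b, a6b = _lj_coeffs(np.asarray(radius_b), np.asarray(eps_b))
    inv_r6 = np.where(mask, r2**-3, 0.0)
    e_rep = np.outer(a12a, a12b) * inv_r6**2
    e_att = np.outer(a6a, a6b) * inv_r6
    e_vdw = float(np.minimum(e_rep, model.repulsion_cap).sum() - e_att.sum())
    r2c = np.maximum(r2, COULOMB_R2_FLOOR)
    inv_eps_r2 = np.where(mask, 1.0 / (model.dielectric_slope * r2c), 0.0)
    e_elec = float(COULOMB * (np.outer(charge_a, charge_b) * inv_eps_r2).sum())
    return e_vdw, e_elec


@dataclass
class GridMaps:
    """Receptor field maps: LJ repulsion/attraction kernels and electrostatics.

    ``rep``/``att`` store Σ_j a12_j/r¹² and Σ_j a6_j/r⁶; ``elec`` stores the
    potential Σ_j COULOMB·q_j/(slope·r²).  Trilinear interpolation is defined
    strictly inside the box.
    """

    origin: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    rep: np.ndarray = field(repr=False, default=None)
    att: np.ndarray = field(repr=False, default=None)
    elec: np.ndarray = field(repr=False, default=None)

    def contains(self, pts: np.ndarray, margin: float = 0.0) -> bool:
        rel = (pts - self.origin) / self.spacing
        hi = np.array(self.shape) - 1
        return bool(np.all(rel >= margin / self.spacing) and np.all(rel <= hi - margin / self.spacing))

    def save_text(self, path) -> None:
        """Export the three maps as a plain-text tensor file."""
        from pathlib import Path

        header = (
            f"# sh2dock grid v1\norigin {self.origin[0]} {self.origin[1]} "
            f"{self.origin[2]}\nspacing {self.spacing}\nshape "
            f"{self.shape[0]} {self.shape[1]} {self.shape[2]}\n"
        )
        body = "\n".join(
            " ".join(f"{v:.8g}" for v in grid.ravel())
            for grid in (self.rep, self.att, self.elec)
        )
        Path(path).write_text(header + body + "\n")

    @classmethod
    def load_text(cls, path) -> "GridMaps":
        from pathlib import Path

        lines = Path(path).read_text().splitlines()
        origin = np.array([float(v) for v in lines[1].split()[1:]])
        spacing = float(lines[2].split()[1])
        shape = tuple(int(v) for v in lines[3].split()[1:])
        grids = [
            np.array([float(v) for v in ln.split()]).reshape(shape)
            for ln in lines[4:7]
        ]
        return cls(origin=origin, spacing=spacing, shape=shape,
                   rep=grids[0], att=grids[1], elec=grids[2])

    def interpolate(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        rel = (pts - self.origin) / self.spacing
        i0 = np.floor(rel).astype(int)
        hi = np.array(self.shape) - 1
        if np.any(i0 < 0) or np.any(i0 >= hi):
            raise ValueError("point outside grid box")
        frac = rel - i0
        out = []
        for grid in (self.rep, self.att, self.elec):
            acc = np.zeros(len(pts))
            for dx in (0, 1):
                for dy in (0, 1):
                    for dz in (0, 1):
                        w = (
                            (frac[:, 0] if dx else 1 - frac[:, 0])
                            * (frac[:, 1] if dy else 1 - frac[:, 1])
                            * (frac[:, 2] if dz else 1 - frac[:, 2])
                        )
                        acc += w * grid[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
            out.append(acc)
        return out[0], out[1], out[2]


def precompute_grids(
    receptor, model: EnergyModel, box_center, box_size, spacing: float = 0.375
) -> GridMaps:
    """Tabulate receptor LJ kernels and the ε(r)=4r Coulomb potential on a grid."""
    box_center = np.asarray(box_center, dtype=float)
    box_size = np.asarray(box_size, dtype=float) * np.ones(3)
    shape = tuple(int(np.floor(s / spacing)) + 1 for s in box_size)
    origin = box_center - (np.array(shape) - 1) * spacing / 2.0

    arrays = receptor.atom_arrays()
    rcoords = arrays["coords"]
    a12, a6 = _lj_coeffs(arrays["radius"], arrays["epsilon"])
    q = arrays["charge"]

    axes = [origin[d] + spacing * np.arange(shape[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    rep = np.zeros(len(pts))
    att = np.zeros(len(pts))
    elec = np.zeros(len(pts))
    chunk = 20000
    for s in range(0, len(pts), chunk):
        block = pts[s : s + chunk]
        diff = block[:, None, :] - rcoords[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", diff, diff)
        np.maximum(r2, LJ_R2_FLOOR, out=r2)
        mask = r2 <= model.cutoff**2
        inv_r6 = np.where(mask, r2**-3, 0.0)
        rep[s : s + chunk] = np.minimum((a12 * inv_r6**2).sum(axis=1), model.repulsion_cap)
        att[s : s + chunk] = (a6 * inv_r6).sum(axis=1)
        r2c = np.maximum(r2, COULOMB_R2_FLOOR)
        elec[s : s + chunk] = COULOMB * np.where(mask, q / (model.dielectric_slope * r2c), 0.0).sum(axis=1)
    if not np.any(rep) and not np.any(elec):
        logger.warning("grid box appears to be far from all receptor atoms (all-zero maps)")
    return GridMaps(
        origin=origin,
        spacing=spacing,
        shape=shape,
        rep=rep.reshape(shape),
        att=att.reshape(shape),
        elec=elec.reshape(shape),
    )


def _intra_pairs(ligand):
    """Cached nonbonded pair lists (separation > 3 bonds) with pair coefficients."""
    cached = getattr(ligand, "_intra_cache", None)
    if cached is None:
        sep = ligand.bond_graph_distances()
        arrays = ligand.atom_arrays()
        a12, a6 = _lj_coeffs(arrays["radius"], arrays["epsilon"])
        q = arrays["charge"]
        iu, ju = np.triu_indices(ligand.n_atoms, k=1)
        keep = sep[iu, ju] > 3
        iu, ju = iu[keep], ju[keep]
        cached = (iu, ju, a12[iu] * a12[ju], a6[iu] * a6[ju], q[iu] * q[ju])
        object.__setattr__(ligand, "_intra_cache", cached)
    return cached


def intramolecular_energy(
    ligand, coords: np.ndarray, model: EnergyModel, atom_mask: np.ndarray | None = None
) -> float:
    """Ligand internal LJ + Coulomb over atom pairs separated by > 3 bonds.

    ``atom_mask`` restricts the sum to pairs inside a subset (used for
    partially grown ligands during incremental docking).
    """
    iu, ju, a12p, a6p, qq = _intra_pairs(ligand)
    if atom_mask is not None and len(iu):
        keep = atom_mask[iu] & atom_mask[ju]
        iu, ju, a12p, a6p, qq = iu[keep], ju[keep], a12p[keep], a6p[keep], qq[keep]
    if len(iu) == 0:
        return 0.0
    diff = coords[iu] - coords[ju]
    r2 = np.einsum("ij,ij->i", diff, diff)
    np.maximum(r2, LJ_R2_FLOOR, out=r2)
    inv_r6 = r2**-3
    e_vdw = np.minimum(a12p * inv_r6**2, model.repulsion_cap) - a6p * inv_r6
    e_elec = COULOMB * qq / (model.dielectric_slope * np.maximum(r2, COULOMB_R2_FLOOR))
    return float(e_vdw.sum() + e_elec.sum())


def interaction_energy(
    lig_coords: np.ndarray,
    ligand,
    receptor=None,
    grids: GridMaps | None = None,
    model: EnergyModel | None = None,
    include_internal: bool = True,
    atom_mask: np.ndarray | None = None,
) -> EnergyBreakdown:
    """Ligand–receptor interaction energy via grid interpolation or direct sums.

    ``atom_mask`` restricts all terms to a subset of ligand atoms — the
    incremental docking protocol scores only the grown fragment of a
    partial pose.  Falls back to the direct path (with a warning) when any
    ligand atom lies outside the grid box.
    """
    model = model or EnergyModel()
    arrays = ligand.atom_arrays()
    charge, radius, eps = arrays["charge"], arrays["radius"], arrays["epsilon"]
    coords_sel = lig_coords
    if atom_mask is not None:
        coords_sel = lig_coords[atom_mask]
        charge, radius, eps = charge[atom_mask], radius[atom_mask], eps[atom_mask]
    br = EnergyBreakdown()
    use_grids = grids is not None
    if use_grids:
        try:
            rep, att, elec = grids.interpolate(coords_sel)
        except ValueError:
            if receptor is None:
                raise
            logger.warning("ligand atom outside grid box: falling back to direct path")
            use_grids = False
    if use_grids:
        a12, a6 = _lj_coeffs(radius, eps)
        br.e_vdw = float((a12 * rep - a6 * att).sum())
        br.e_elec = float((charge * elec).sum())
    else:
        if receptor is None:
            raise ValueError("need either grids or an explicit receptor")
        rec = receptor.atom_arrays()
        br.e_vdw, br.e_elec = pairwise_energy(
            coords_sel, charge, radius, eps,
            rec["coords"], rec["charge"], rec["radius"], rec["epsilon"], model,
        )
    if include_internal:
        br.e_internal = intramolecular_energy(ligand, lig_coords, model, atom_mask)
    return br


# ---------------------------------------------------------------------------
# Generalized Born (HCT pairwise descreening, Still cross term)


def _born_radii(coords, radii, screen) -> np.ndarray:
    n = len(coords)
    inv_alpha = 1.0 / radii
    if n > 1:
        diff = coords[:, None, :] - coords[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        s = screen * radii  # scaled descreening radii of the perturbing atoms
        rho_i = radii[:, None]
        sj = s[None, :]
        U = r + sj
        L = np.maximum(rho_i, np.abs(r - sj))
        active = (U > rho_i) & ~np.eye(n, dtype=bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            integral = 0.5 * (
                1.0 / L
                - 1.0 / U
                + 0.25 * (r - sj**2 / r) * (1.0 / U**2 - 1.0 / L**2)
                + 0.5 / r * np.log(L / U)
            )
        integral = np.where(active, integral, 0.0)
        inv_alpha = inv_alpha - integral.sum(axis=1)
    return 1.0 / np.maximum(inv_alpha, 1e-8)


def gb_polar_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    radii: np.ndarray,
    model: EnergyModel | None = None,
    screen: np.ndarray | None = None,
) -> float:
    """Polar solvation energy (kcal/mol) of an atom set.

    HCT Born radii from vdW radii (no offset) with per-element descreening
    scales; the pair term uses the Still function
    f = √(r² + αᵢαⱼ·exp(−r²/(4αᵢαⱼ))).  Reduces to the Born ion formula for
    a single charge.
    """
    model = model or EnergyModel()
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    charges = np.asarray(charges, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    if screen is None:
        screen = np.full(len(radii), 0.8)
    alpha = _born_radii(coords, radii, np.asarray(screen, dtype=float))
    diff = coords[:, None, :] - coords[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    aa = alpha[:, None] * alpha[None, :]
    f = np.sqrt(r2 + aa * np.exp(-r2 / (4.0 * aa)))
    qq = np.outer(charges, charges)
    prefac = -0.5 * COULOMB * (1.0 / model.solute_dielectric - 1.0 / model.solvent_dielectric)
    return float(prefac * (qq / f).sum())


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake–Rupley, golden-spiral points)


def _golden_spiral(n: int) -> np.ndarray:
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 240,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley sampling.

    Deterministic for fixed ``n_points``: test points come from a golden
    spiral on each expanded sphere.
    """
    if n_points < 60:
        raise ValueError("n_points must be >= 60")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe
    n = len(coords)
    sphere = _golden_spiral(n_points)
    areas = np.empty(n)
    if n > 1:
        diff = coords[:, None, :] - coords[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        if n > 1:
            cut = (radii[i] + radii) ** 2
            neighbors = np.where((d2[i] < cut) & (np.arange(n) != i))[0]
            for j in neighbors:
                dj = pts - coords[j]
                exposed &= np.einsum("ij,ij->i", dj, dj) > radii[j] ** 2
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * exposed.mean()
    return areas


def nonpolar_energy(total_sasa: float, model: EnergyModel | None = None) -> float:
    """G_nonpolar = γ·SASA + b."""
    model = model or EnergyModel()
    return model.surface_tension * total_sasa + model.surface_offset
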