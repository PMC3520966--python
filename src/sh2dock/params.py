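"""Bundled nonbonded parameter tables.

A deliberately small, self-contained surrogate for force-field atom typing:
van der Waals radius (Å), well depth (kcal/mol), mass (amu), partial charge
(e) and a GB descreening scale factor, keyed by element with a sparse
residue+atom overlay for protein backbone atoms.  Users can override any
entry through :func:`load_overrides`.
"""

from __future__ import annotations

import json
from pathlib import Path

# element -> (vdw radius Å, LJ well depth kcal/mol, mass amu, default charge e)
ELEMENT_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "H": (1.20, 0.016, 1.008, 0.10),
    "C": (1.70, 0.086, 12.011, 0.00),
    "N": (1.55, 0.170, 14.007, -0.30),
    "O": (1.52, 0.210, 15.999, -0.40),
    "S": (1.80, 0.250, 32.06, -0.10),
    "P": (1.80, 0.200, 30.974, 1.10),
    "NA": (2.27, 0.003, 22.990, 1.00),
    "CL": (1.75, 0.265, 35.45, -1.00),
    "X": (1.70, 0.100, 12.011, 0.00),  # unknown-element fallback
}

# HCT pairwise-descreening scale factors by element (dimensionless)
GB_SCREEN: dict[str, float] = {
    "H": 0.85,
    "C": 0.72,
    "N": 0.79,
    "O": 0.85,
    "S": 0.96,
    "P": 0.86,
    "X": 0.80,
}

# (residue name, atom name) -> partial charge overlay for common protein atoms.
# Coarse, charge-group style values; the full force-field derivation is out of
# scope for this artifact.
RESIDUE_CHARGES: dict[tuple[str, str], float] = {
    ("ANY", "N"): -0.42,
    ("ANY", "H"): 0.27,
    ("ANY", "CA"): 0.03,
    ("ANY", "C"): 0.60,
    ("ANY", "O"): -0.57,
    ("LYS", "NZ"): -0.30,
    ("LYS", "HZ1"): 0.34,
    ("LYS", "HZ2"): 0.34,
    ("LYS", "HZ3"): 0.34,
    ("ARG", "NH1"): -0.63,
    ("ARG", "NH2"): -0.63,
    ("ARG", "CZ"): 0.64,
    ("ARG", "HH11"): 0.45,
    ("ARG", "HH12"): 0.45,
    ("ARG", "HH21"): 0.45,
    ("ARG", "HH22"): 0.45,
    ("SER", "OG"): -0.65,
    ("SER", "HG"): 0.43,
    ("GLU", "OE1"): -0.82,
    ("GLU", "OE2"): -0.82,
    ("GLU", "CD"): 0.81,
    ("ASP", "OD1"): -0.82,
    ("ASP", "OD2"): -0.82,
    ("TYR", "OH"): -0.56,
    ("TYR", "HH"): 0.40,
    ("GLN", "OE1"): -0.61,
    ("GLN", "NE2"): -0.94,
    ("GLN", "HE21"): 0.43,
    ("GLN", "HE22"): 0.43,
}

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "DOD"}
ION_RESNAMES = {"NA", "NA+", "CL", "CL-", "K", "K+", "MG", "ZN", "CA"}
NUCLEIC_RESNAMES = {
    "DA", "DT", "DG", "DC", "DU", "A", "T", "G", "C", "U",
    "ADE", "THY", "GUA", "CYT", "URA",
}


def guess_element(atom_name: str) -> str:
    """Guess the element from a PDB-style atom name."""
    name = atom_name.strip()
    if not name:
        return "X"
    if name[:2].upper() in ("NA", "CL", "MG", "ZN") and len(name) <= 3:
        return name[:2].upper()
    for ch in name:
        if ch.isalpha():
            el = ch.upper()
            return el if el in ELEMENT_PARAMS else "X"
    return "X"


def lookup(residue_name: str, atom_name: str, element: str | None = None):
    """Return ``(radius, epsilon, mass, charge, known)`` for an atom.

    ``known`` is False when only the element-based fallback applied.
    """
    el = element or guess_element(atom_name)
    if el not in ELEMENT_PARAMS:
        el = "X"
    radius, eps, mass, q = ELEMENT_PARAMS[el]
    key_specific = (residue_name.upper(), atom_name.strip().upper())
    key_any = ("ANY", atom_name.strip().upper())
    known = True
    if key_specific in RESIDUE_CHARGES:
        q = RESIDUE_CHARGES[key_specific]
    elif key_any in RESIDUE_CHARGES:
        q = RESIDUE_CHARGES[key_any]
    else:
        known = el != "X"
    return radius, eps, mass, q, known


def gb_screen(element: str) -> float:
    return GB_SCREEN.get(element.upper(), GB_SCREEN["X"])


def load_overrides(path: str | Path) -> None:
    """Merge a JSON override file into the bundled tables.

    Schema: ``{"elements": {"C": [r, eps, mass, q]},
    "residue_charges": {"LYS:NZ": -0.3}}``.
    """
    data = json.loads(Path(path).read_text())
    for el, vals in data.get("elements", {}).items():
        ELEMENT_PARAMS[el.upper()] = tuple(float(v) for v in vals)  # type: ignore[assignment]
    for key, q in data.get("residue_charges", {}).items():
        res, atom = key.split(":")
        RESIDUE_CHARGES[(res.upper(), atom.upper())] = float(q)
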