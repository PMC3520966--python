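"""Sub-pocket contact mapping and binding-mode classification.

The SH2 ligand groove is described by four sub-pockets: the positively
charged phosphate-binding sub-pocket-1 (Lys591, Arg609, Ser611, Glu612,
Ser613), sub-pocket-2 (Glu638, Tyr640, Gln644), sub-pocket-3 (Gly656,
Tyr657, Lys658) and sub-pocket-4 (flanked by Trp623, Ile659, Met660), plus
the two loops 623–629 and 656–668 that form the groove of the wedged mode.
A bound conformation is labelled by where its C-terminal moiety sits while
the phosphate anchor occupies sub-pocket-1: *bent* (sub-pocket-2),
*extended* (sub-pocket-3) or *wedged* (buried between both loops with
neither sub-pocket-2 nor -3 dominant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SubPocketDef",
    "BindingModeLabel",
    "default_subpockets",
    "contact_map",
    "classify_mode",
    "classify_clusters",
]

LOOP_1 = tuple(range(623, 630))  # residues 623-629
LOOP_2 = tuple(range(656, 669))  # residues 656-668


@dataclass
class SubPocketDef:
    name: str
    residues: tuple[int, ...]
    cutoff: float = 4.5

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def default_subpockets(cutoff: float = 4.5) -> list[SubPocketDef]:
    return [
        SubPocketDef("sub-pocket-1", (591, 609, 611, 612, 613), cutoff),
        SubPocketDef("sub-pocket-2", (638, 640, 644), cutoff),
        SubPocketDef("sub-pocket-3", (656, 657, 658), cutoff),
        SubPocketDef("sub-pocket-4", (623, 659, 660), cutoff),
        SubPocketDef("loop-623-629", LOOP_1, cutoff),
        SubPocketDef("loop-656-668", LOOP_2, cutoff),
    ]


@dataclass
class BindingModeLabel:
    label: str  # bent | extended | wedged | anchored-only | unclassified
    contacts: dict = field(default_factory=dict)
    candidates: tuple[str, ...] = ()


def _moiety_contacts(
    moiety_coords: np.ndarray,
    rec_coords: np.ndarray,
    rec_residues: np.ndarray,
    pocket: SubPocketDef,
) -> int:
    """Number of moiety/receptor heavy-atom pairs within the pocket cutoff."""
    sel = np.isin(rec_residues, pocket.residues)
    if not sel.any() or len(moiety_coords) == 0:
        return 0
    diff = moiety_coords[:, None, :] - rec_coords[sel][None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    return int((d2 <= pocket.cutoff**2).sum())


def contact_map(
    moieties: dict[str, np.ndarray],
    rec_coords: np.ndarray,
    rec_residues: np.ndarray,
    subpockets: list[SubPocketDef] | None = None,
) -> dict[str, dict[str, int]]:
    """Contact counts per (moiety, sub-pocket).

    ``moieties`` maps a moiety name (e.g. ``anchor``, ``cterm``) to its
    heavy-atom coordinates; a moiety contacts a sub-pocket iff at least one
    atom pair is within the pocket's cutoff.
    """
    if not moieties:
        raise ValueError("no moieties designated")
    subpockets = subpockets or default_subpockets()
    return {
        mname: {p.name: _moiety_contacts(xyz, rec_coords, rec_residues, p) for p in subpockets}
        for mname, xyz in moieties.items()
    }


def classify_mode(contacts: dict[str, dict[str, int]]) -> BindingModeLabel:
    """Bent / extended / wedged classification from a contact map.

    Requires the anchor in sub-pocket-1 for any mode label.  The C-terminal
    moiety decides the mode: sub-pocket-2 contact → bent, sub-pocket-3 →
    extended, contact with BOTH groove loops while neither sub-pocket-2 nor
    -3 dominates → wedged.  When several candidates apply, precedence is
    wedged > extended > bent by contact count; exact ties are reported as
    unclassified with both candidates listed.
    """
    if "anchor" not in contacts or "cterm" not in contacts:
        raise ValueError("moieties 'anchor' and 'cterm' must both be designated")
    anchor = contacts["anchor"]
    cterm = contacts["cterm"]
    if anchor.get("sub-pocket-1", 0) == 0:
        return BindingModeLabel(label="unclassified", contacts=contacts)

    n2 = cterm.get("sub-pocket-2", 0)
    n3 = cterm.get("sub-pocket-3", 0)
    loop1 = cterm.get("loop-623-629", 0)
    loop2 = cterm.get("loop-656-668", 0)
    wedged_n = min(loop1, loop2) if (loop1 > 0 and loop2 > 0) else 0

    candidates: list[tuple[int, str]] = []
    if n2 > 0:
        candidates.append((n2, "bent"))
    if n3 > 0:
        candidates.append((n3, "extended"))
    # wedged needs both loops engaged and neither named sub-pocket dominant
    if wedged_n > 0 and n2 <= wedged_n and n3 <= wedged_n:
        candidates.append((wedged_n, "wedged"))

    if not candidates:
        return BindingModeLabel(label="anchored-only", contacts=contacts)

    precedence = {"wedged": 2, "extended": 1, "bent": 0}
    best_count = max(c for c, _ in candidates)
    top = [name for c, name in candidates if c == best_count]
    if len(top) == 1:
        return BindingModeLabel(label=top[0], contacts=contacts, candidates=tuple(top))
    top.sort(key=lambda n: -precedence[n])
    # distinct-precedence ties resolve by precedence; true ambiguity is reported
    if precedence[top[0]] > precedence[top[1]]:
        return BindingModeLabel(label=top[0], contacts=contacts, candidates=tuple(top))
    return BindingModeLabel(label="unclassified", contacts=contacts, candidates=tuple(top))


def classify_clusters(
    fitted,
    cluster_result,
    anchor_indices: np.ndarray,
    cterm_indices: np.ndarray,
    subpockets: list[SubPocketDef] | None = None,
) -> dict[int, BindingModeLabel]:
    """Mode label of each cluster's representative frame (pure function of
    the representatives)."""
    traj = fitted.traj
    rec_idx = traj.receptor_indices
    labels = {}
    heavy_rec = np.array([i for i in rec_idx if traj.atoms[i].element != "H"])
    rec_res = traj.residue_numbers[heavy_rec]
    for c, rep in enumerate(cluster_result.representatives):
        if rep < 0:
            continue
        xyz = traj.coords[rep]
        moieties = {
            "anchor": xyz[np.asarray(anchor_indices, dtype=int)],
            "cterm": xyz[np.asarray(cterm_indices, dtype=int)],
        }
        cmap = contact_map(moieties, xyz[heavy_rec], rec_res, subpockets)
        labels[c] = classify_mode(cmap)
    return labels
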