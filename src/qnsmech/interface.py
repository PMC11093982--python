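"""Dimer-interface and ligand-contact descriptors.

Solvent-accessible surface areas use the same deterministic Shrake–
Rupley sampler as the contact module but with the conventional 1.4 Å
water probe.  Buried interface area per protomer is
(SASA(A) + SASA(B) − SASA(AB)) / 2.  Pair finders (salt bridges,
hydrogen bonds, nonbonded and polar contacts) use distance criteria on
typed atoms across the chain partition; a D–H···A angle test activates
automatically when hydrogens are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .contacts import sample_surface
from .structures import Atom, Residue, Structure

__all__ = [
    "InterfaceReport",
    "sasa",
    "buried_interface_area",
    "find_salt_bridges",
    "find_hbonds",
    "nonbonded_contacts",
    "polar_contacts",
    "interface_report",
]

ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
POLAR_ELEMENTS = {"N", "O", "S"}


def _flat_atoms(s: Structure) -> tuple[list[Residue], list[Atom], np.ndarray]:
    residues, atoms, coords = [], [], []
    for res in s.residues():
        for a in res.atoms:
            residues.append(res)
            atoms.append(a)
            coords.append(a.coords)
    return residues, atoms, np.stack(coords) if coords else np.zeros((0, 3))


def sasa(s: Structure, probe: float = 1.4, n_points: int = 960) -> tuple[np.ndarray, float]:
    """Shrake–Rupley solvent-accessible surface area.

    Returns (per-atom areas in structure atom order, total), Å².
    """
    atoms = list(s.atoms())
    if not atoms:
        return np.zeros(0), 0.0
    surf = sample_surface(atoms, probe=probe, n=n_points)
    return surf.atom_areas, float(surf.atom_areas.sum())


def _merge(a: Structure, b: Structure) -> Structure:
    out = Structure(entry_id=f"{a.entry_id}+{b.entry_id}")
    for src, tag in ((a, ""), (b, "*")):
        for chain_id, residues in src.chains.items():
            cid = chain_id
            while cid in out.chains:
                cid = cid + tag if tag else cid + "*"
            out.chains[cid] = residues
    return out


def buried_interface_area(
    a: Structure, b: Structure, probe: float = 1.4, n_points: int = 960
) -> float:
    """Interface area buried per protomer: (SASA(a) + SASA(b) − SASA(ab))/2."""
    _, area_a = sasa(a, probe, n_points)
    _, area_b = sasa(b, probe, n_points)
    _, area_ab = sasa(_merge(a, b), probe, n_points)
    return max((area_a + area_b - area_ab) / 2.0, 0.0)


def _cross_pairs(
    a: Structure, b: Structure, cutoff: float
) -> list[tuple[Residue, Atom, Residue, Atom, float]]:
    res_a, at_a, xa = _flat_atoms(a)
    res_b, at_b, xb = _flat_atoms(b)
    if xa.size == 0 or xb.size == 0:
        return []
    tree = cKDTree(xb)
    out = []
    for i, pos in enumerate(xa):
        for j in tree.query_ball_point(pos, cutoff):
            d = float(np.linalg.norm(pos - xb[j]))
            out.append((res_a[i], at_a[i], res_b[j], at_b[j], d))
    return out


def find_salt_bridges(
    a: Structure, b: Structure, cutoff: float = 4.0
) -> list[tuple[str, str, float]]:
    """Residue pairs with a carboxylate-oxygen to basic-nitrogen distance at
    or below *cutoff* across the a/b partition (His counted as potential
    cation).  One entry per residue pair carrying the minimum distance."""
    best: dict[tuple[str, str], float] = {}
    for ra, aa, rb, ab, d in _cross_pairs(a, b, cutoff):
        fwd = aa.name in ACIDIC_ATOMS.get(ra.res_name.upper(), ()) and ab.name in BASIC_ATOMS.get(
            rb.res_name.upper(), ()
        )
        rev = ab.name in ACIDIC_ATOMS.get(rb.res_name.upper(), ()) and aa.name in BASIC_ATOMS.get(
            ra.res_name.upper(), ()
        )
        if fwd or rev:
            key = (ra.key, rb.key)
            if d < best.get(key, np.inf):
                best[key] = d
    return sorted((ka, kb, d) for (ka, kb), d in best.items())


def _hydrogens_near(res: Residue, donor: Atom, r: float = 1.3) -> list[Atom]:
    return [
        h
        for h in res.atoms
        if h.is_hydrogen and np.linalg.norm(h.coords - donor.coords) <= r
    ]


def find_hbonds(
    a: Structure, b: Structure, d_max: float = 3.35
) -> list[tuple[str, str, float]]:
    """N/O donor–acceptor heavy-atom pairs across the partition within
    *d_max* Å.  When the donor carries hydrogens, a D–H···A angle of at
    least 90° is additionally required."""
    out = []
    for ra, aa, rb, ab, d in _cross_pairs(a, b, d_max):
        if aa.element.upper() not in ("N", "O") or ab.element.upper() not in ("N", "O"):
            continue
        hs = _hydrogens_near(ra, aa) + _hydrogens_near(rb, ab)
        if hs:
            ok = False
            for h, donor, acceptor in [(h, aa, ab) for h in _hydrogens_near(ra, aa)] + [
                (h, ab, aa) for h in _hydrogens_near(rb, ab)
            ]:
                v1 = donor.coords - h.coords
                v2 = acceptor.coords - h.coords
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 90.0:
                    ok = True
                    break
            if not ok:
                continue
        out.append((f"{ra.key}:{aa.name}", f"{rb.key}:{ab.name}", d))
    return sorted(out)


def nonbonded_contacts(
    a: Structure, b: Structure, d_max: float = 3.9
) -> tuple[int, list[tuple[str, str, float]]]:
    """Non-hydrogen atom pairs across the partition within *d_max* Å,
    excluding pairs already counted as hydrogen bonds."""
    hb = {(x, y) for x, y, _ in find_hbonds(a, b)}
    pairs = []
    for ra, aa, rb, ab, d in _cross_pairs(a, b, d_max):
        if aa.is_hydrogen or ab.is_hydrogen:
            continue
        key = (f"{ra.key}:{aa.name}", f"{rb.key}:{ab.name}")
        if key in hb:
            continue
        pairs.append((*key, d))
    pairs.sort()
    return len(pairs), pairs


def polar_contacts(
    ligand: Residue, protein: Structure, d_max: float = 3.5
) -> list[tuple[str, str, float]]:
    """Ligand N/O/S to protein N/O/S atom pairs within *d_max* Å."""
    out = []
    prot_atoms = [
        (res, a)
        for res in protein.residues()
        for a in res.atoms
        if a.element.upper() in POLAR_ELEMENTS
    ]
    if not prot_atoms:
        return []
    coords = np.stack([a.coords for _, a in prot_atoms])
    tree = cKDTree(coords)
    for la in ligand.atoms:
        if la.element.upper() not in POLAR_ELEMENTS:
            continue
        for j in tree.query_ball_point(la.coords, d_max):
            res, pa = prot_atoms[j]
            d = float(np.linalg.norm(la.coords - pa.coords))
            out.append((f"{ligand.key}:{la.name}", f"{res.key}:{pa.name}", d))
    return sorted(out)


@dataclass
class InterfaceReport:
    buried_area_per_protomer: float
    salt_bridges: list[tuple[str, str, float]] = field(default_factory=list)
    hbonds: list[tuple[str, str, float]] = field(default_factory=list)
    nonbonded_count: int = 0
    nonbonded_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "buried_area_per_protomer_A2": self.buried_area_per_protomer,
            "n_salt_bridges": len(self.salt_bridges),
            "n_hbonds": len(self.hbonds),
            "n_nonbonded": self.nonbonded_count,
            "salt_bridges": self.salt_bridges,
            "hbonds": self.hbonds,
        }


def interface_report(
    a: Structure,
    b: Structure,
    salt_bridge_cutoff: float = 4.0,
    hbond_cutoff: float = 3.35,
    nonbonded_cutoff: float = 3.9,
    probe: float = 1.4,
    n_points: int = 960,
) -> InterfaceReport:
    """All interface descriptors for the protomer pair (a, b)."""
    count, pairs = nonbonded_contacts(a, b, nonbonded_cutoff)
    return InterfaceReport(
        buried_area_per_protomer=buried_interface_area(a, b, probe, n_points),
        salt_bridges=find_salt_bridges(a, b, salt_bridge_cutoff),
        hbonds=find_hbonds(a, b, hbond_cutoff),
        nonbonded_count=count,
        nonbonded_pairs=pairs,
    )
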