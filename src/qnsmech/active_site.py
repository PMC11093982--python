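"""Truncated active-site ("cluster") model construction.

A cluster model is carved out of a full structure as every residue with
at least one heavy atom within an inclusion radius (default 12.0 Å) of
the catalytic residue, taken whole.  Chain breaks created by the
truncation are neutralized with capping hydrogens (N-side becomes a
neutral amine, C-side an aldehyde) placed along the severed-bond
direction at ideal bond lengths.  Mobility is then partitioned: all
backbone atoms are rigid, as are side chains of non-reactive residues;
the ligand, cap atoms and reactive side chains are mobile.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from ._chem import CAP_H_BOND
from .structures import Atom, Residue, Structure

__all__ = [
    "ActiveSiteModel",
    "extract_active_site",
    "neutralize_termini",
    "truncate_ligand",
    "assign_mobility",
]

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}

# Atom-key format: "<chain>/<seq><icode>:<atom name>"


def atom_key(res: Residue, atom: Atom) -> str:
    return f"{res.key}:{atom.name}"


@dataclass
class CapRecord:
    residue_key: str
    cap_type: str  # "neutral-amine" | "aldehyde"
    atom_name: str


@dataclass
class ActiveSiteModel:
    source_entry: str
    catalytic_residue: str
    inclusion_radius: float
    residues: list[Residue]
    ligand: Residue | None = None
    caps: list[CapRecord] = field(default_factory=list)
    mobile_atoms: set[str] = field(default_factory=set)
    rigid_atoms: set[str] = field(default_factory=set)
    source: Structure | None = None

    def all_residues(self) -> list[Residue]:
        out = list(self.residues)
        if self.ligand is not None:
            out.append(self.ligand)
        return out

    def residue(self, key: str) -> Residue:
        for res in self.all_residues():
            if res.key == key:
                return res
        raise KeyError(f"no residue {key!r} in active-site model")

    def atoms(self) -> list[tuple[str, Atom]]:
        return [
            (atom_key(res, a), a)
            for res in self.all_residues()
            for a in res.atoms
        ]

    def atom(self, key: str) -> Atom:
        for k, a in self.atoms():
            if k == key:
                return a
        raise KeyError(f"no atom {key!r} in active-site model")

    def copy(self) -> "ActiveSiteModel":
        return copy.deepcopy(self)


def extract_active_site(
    s: Structure,
    catalytic: str,
    radius: float = 12.0,
    *,
    from_atom: str | None = None,
) -> ActiveSiteModel:
    """Carve the cluster: whole residues with >=1 heavy atom within *radius*
    of any heavy atom of the catalytic residue (or of the single atom
    *from_atom* when given).  The catalytic residue is always included and
    any non-polymer residue flagged as ligand is carried separately."""
    if radius <= 0:
        raise ValueError("inclusion radius must be positive")
    cat = s.residue(catalytic)  # KeyError names the key if missing
    if from_atom is not None:
        center = cat.atom(from_atom).coords[None, :]
    else:
        center = cat.coords(heavy_only=True)
        if center.size == 0:
            center = cat.coords()

    kept: list[Residue] = []
    ligand: Residue | None = None
    for res in s.residues():
        coords = res.coords(heavy_only=True)
        if coords.size == 0:
            coords = res.coords()
        if coords.size == 0:
            continue
        diff = coords[:, None, :] - center[None, :, :]
        dmin = float(np.sqrt((diff**2).sum(axis=-1)).min())
        included = dmin <= radius or res.key == cat.key
        if not included:
            continue
        if res.is_ligand and not res.is_water:
            ligand = copy.deepcopy(res)
        elif not res.is_water:
            kept.append(copy.deepcopy(res))

    return ActiveSiteModel(
        source_entry=s.entry_id,
        catalytic_residue=cat.key,
        inclusion_radius=radius,
        residues=kept,
        ligand=ligand,
        source=s,
    )


def _cap_direction(from_pos: np.ndarray, towards: np.ndarray) -> np.ndarray:
    v = towards - from_pos
    n = np.linalg.norm(v)
    if n < 1e-9:
        v = np.array([1.0, 0.0, 0.0])
        n = 1.0
    return v / n


def _place_cap(res: Residue, anchor: Atom, towards: np.ndarray, name: str) -> Atom:
    length = CAP_H_BOND.get(anchor.element.upper(), 1.09)
    pos = anchor.coords + _cap_direction(anchor.coords, towards) * length
    # collision guard: displace along the bisector away from the offender
    for other in res.atoms:
        if np.linalg.norm(other.coords - pos) < 0.8:
            away = _cap_direction(other.coords, pos) + _cap_direction(anchor.coords, towards)
            away /= np.linalg.norm(away)
            pos = anchor.coords + away * length
            break
    serial = max((a.serial for a in res.atoms), default=0) + 1
    return Atom(serial=serial, name=name, element="H", coords=pos)


def neutralize_termini(m: ActiveSiteModel) -> ActiveSiteModel:
    """Cap every backbone discontinuity the truncation created.

    A kept polymer residue whose source-chain predecessor was excised gets
    a neutral-amine cap (H on N, 1.01 Å along the severed N–C bond); one
    whose successor was excised gets an aldehyde cap (H on C, 1.09 Å along
    the severed C–N bond).  Original atom coordinates are never modified.
    """
    if m.source is None:
        raise ValueError("model lacks a source structure; build it with extract_active_site")
    out = m.copy()
    kept_keys = {r.key for r in out.residues}

    for res in out.residues:
        if not res.is_polymer:
            continue
        source_chain = m.source.chains.get(res.chain_id, [])
        poly = [r for r in source_chain if r.is_polymer]
        idx = next((i for i, r in enumerate(poly) if r.key == res.key), None)
        if idx is None:
            continue
        # N-side break: predecessor exists in source but was excised
        if idx > 0 and poly[idx - 1].key not in kept_keys and res.has_atom("N"):
            prev = poly[idx - 1]
            if prev.has_atom("C"):
                cap = _place_cap(res, res.atom("N"), prev.atom("C").coords, "HN2")
                res.atoms.append(cap)
                out.caps.append(CapRecord(res.key, "neutral-amine", cap.name))
        # C-side break: successor exists in source but was excised
        if idx < len(poly) - 1 and poly[idx + 1].key not in kept_keys and res.has_atom("C"):
            nxt = poly[idx + 1]
            if nxt.has_atom("N"):
                cap = _place_cap(res, res.atom("C"), nxt.atom("N").coords, "HC1")
                res.atoms.append(cap)
                out.caps.append(CapRecord(res.key, "aldehyde", cap.name))
    return out


def truncate_ligand(
    lig: Residue,
    keep: list[str],
    *,
    bond_tol: float = 1.85,
) -> Residue:
    """Retain only the anchor atoms named in *keep* (e.g. the thioethyl
    group plus acyl head of a CoA thioester); valences severed by the
    truncation are capped with hydrogens at ideal geometry.

    Bonds are inferred from heavy-atom distances below *bond_tol* Å.
    """
    missing = [n for n in keep if not lig.has_atom(n)]
    if missing:
        raise ValueError(f"keep-spec atoms absent from ligand {lig.key}: {missing}")
    keep_set = set(keep)
    kept = [copy.deepcopy(a) for a in lig.atoms if a.name in keep_set]
    removed = [a for a in lig.atoms if a.name not in keep_set and not a.is_hydrogen]

    out = Residue(
        chain_id=lig.chain_id,
        seq_id=lig.seq_id,
        icode=lig.icode,
        res_name=lig.res_name,
        atoms=kept,
        is_polymer=False,
        is_water=False,
        is_ligand=True,
    )
    # cap each severed heavy-heavy bond
    cap_i = 1
    for a in out.atoms:
        if a.is_hydrogen:
            continue
        for r in removed:
            if np.linalg.norm(a.coords - r.coords) < bond_tol:
                length = CAP_H_BOND.get(a.element.upper(), 1.09)
                pos = a.coords + _cap_direction(a.coords, r.coords) * length
                serial = max(x.serial for x in out.atoms) + 1
                out.atoms.append(
                    Atom(serial=serial, name=f"HX{cap_i}", element="H", coords=pos)
                )
                cap_i += 1
    return out


def assign_mobility(m: ActiveSiteModel, reactive_residues: set[str]) -> ActiveSiteModel:
    """Partition atoms into rigid and mobile sets.

    Rigid: all backbone atoms plus side chains of non-reactive residues.
    Mobile: ligand atoms, cap atoms and side chains of reactive residues.
    """
    model_keys = {r.key for r in m.residues}
    unknown = reactive_residues - model_keys
    if unknown:
        raise KeyError(f"reactive residues not in model: {sorted(unknown)}")
    out = m.copy()
    out.mobile_atoms = set()
    out.rigid_atoms = set()
    cap_names = {(c.residue_key, c.atom_name) for c in out.caps}
    for res in out.residues:
        for a in res.atoms:
            key = atom_key(res, a)
            if (res.key, a.name) in cap_names:
                out.mobile_atoms.add(key)
            elif a.name in BACKBONE_NAMES:
                out.rigid_atoms.add(key)
            elif res.key in reactive_residues:
                out.mobile_atoms.add(key)
            else:
                out.rigid_atoms.add(key)
    if out.ligand is not None:
        for a in out.ligand.atoms:
            out.mobile_atoms.add(atom_key(out.ligand, a))
    return out
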