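"""Probe-based residue–substrate contact mapping and in-silico mutagenesis.

The protocol mirrors contact-surface analysis of enzyme reaction
snapshots: sample each substrate atom's probe-expanded sphere (Shrake–
Rupley style, deterministic golden-spiral points, probe 1.5 Å), discard
points buried inside neighbouring substrate atoms, and assign every
remaining surface point lying within 3.0 Å of a receptor atom to the
residue owning the nearest such atom.  Per-residue contact areas are
classified as *minor* below 0.5 Å² and *major* at or above it.  Simple
side-chain mutations (terminal heavy-atom deletions and single ideal-
geometry methyl additions) let the same machinery screen how a mutation
changes contact along the reaction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._chem import vdw_radius
from .structures import Atom, Residue, Structure

__all__ = [
    "SurfaceSample",
    "ContactRecord",
    "MutationSpec",
    "sample_surface",
    "residue_contact_areas",
    "classify_contact",
    "contact_trace",
    "apply_mutation",
    "screen_mutation",
    "golden_spiral_points",
]

ContactClass = Literal["none", "minor", "major"]

MINOR_MAJOR_THRESHOLD = 0.5  # Å²


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


@dataclass
class SurfaceSample:
    """Exposed surface points of a set of atoms at radius vdW + probe."""

    points: np.ndarray  # (m, 3) exposed points, Å
    weights: np.ndarray  # (m,) Å² per point
    owners: np.ndarray  # (m,) index of the owning atom
    probe: float
    n_points_per_atom: int
    atom_areas: np.ndarray  # (n_atoms,) exposed area per atom, Å²

    @property
    def total_area(self) -> float:
        return float(self.weights.sum())


def sample_surface(
    atoms: Sequence[Atom], probe: float = 1.5, n: int = 960
) -> SurfaceSample:
    """Shrake–Rupley surface of *atoms* with the given probe radius.

    Every atom contributes *n* golden-spiral points on its expanded sphere;
    points inside any neighbouring atom's expanded sphere are discarded.
    Each surviving point carries weight 4π(r+probe)²/n.
    """
    if len(atoms) == 0:
        raise ValueError("need at least one atom")
    if n < 92:
        raise ValueError("need at least 92 points per atom")
    centers = np.stack([a.coords for a in atoms])
    radii = np.array([vdw_radius(a.element) + probe for a in atoms])
    unit = golden_spiral_points(n)

    tree = cKDTree(centers)
    max_r = radii.max()
    all_points, all_weights, all_owners = [], [], []
    atom_areas = np.zeros(len(atoms))
    for i, (c, r) in enumerate(zip(centers, radii)):
        pts = c + r * unit
        neighbours = [j for j in tree.query_ball_point(c, r + max_r) if j != i]
        exposed = np.ones(n, dtype=bool)
        for j in neighbours:
            d2 = ((pts - centers[j]) ** 2).sum(axis=1)
            # a point on or inside a neighbour's expanded sphere is buried
            exposed &= d2 > radii[j] ** 2 + 1e-9
        kept = pts[exposed]
        w = 4.0 * np.pi * r * r / n
        atom_areas[i] = w * kept.shape[0]
        if kept.size:
            all_points.append(kept)
            all_weights.append(np.full(kept.shape[0], w))
            all_owners.append(np.full(kept.shape[0], i, dtype=int))

    points = np.vstack(all_points) if all_points else np.zeros((0, 3))
    weights = np.concatenate(all_weights) if all_weights else np.zeros(0)
    owners = np.concatenate(all_owners) if all_owners else np.zeros(0, dtype=int)
    return SurfaceSample(points, weights, owners, probe, n, atom_areas)


@dataclass
class ContactRecord:
    residue: str
    state_label: str
    area: float
    contact_class: ContactClass

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("contact area cannot be negative")


def classify_contact(area: float) -> ContactClass:
    """Classify a contact area: none at 0, minor below 0.5 Å², major at or
    above 0.5 Å²."""
    if area < 0:
        raise ValueError("contact area cannot be negative")
    if area == 0:
        return "none"
    return "minor" if area < MINOR_MAJOR_THRESHOLD else "major"


def residue_contact_areas(
    surface: SurfaceSample,
    receptor: Structure,
    cutoff: float = 3.0,
    state_label: str = "",
) -> list[ContactRecord]:
    """Assign each exposed substrate surface point with a receptor atom
    within *cutoff* Å to the residue owning the nearest such atom; emit one
    record per contacting residue with its summed point weight as area."""
    residues = list(receptor.residues())
    atom_res: list[int] = []
    atom_pos: list[np.ndarray] = []
    for ri, res in enumerate(residues):
        for a in res.atoms:
            atom_res.append(ri)
            atom_pos.append(a.coords)
    if not atom_pos or surface.points.shape[0] == 0:
        return []
    tree = cKDTree(np.stack(atom_pos))
    dist, idx = tree.query(surface.points, distance_upper_bound=cutoff)
    in_range = np.isfinite(dist)
    areas: dict[int, float] = {}
    for p in np.nonzero(in_range)[0]:
        ri = atom_res[idx[p]]
        areas[ri] = areas.get(ri, 0.0) + float(surface.weights[p])
    records = [
        ContactRecord(
            residue=residues[ri].key,
            state_label=state_label,
            area=a,
            contact_class=classify_contact(a),
        )
        for ri, a in areas.items()
    ]
    records.sort(key=lambda r: _res_sort_key(r.residue))
    return records


def _res_sort_key(key: str) -> tuple:
    chain, _, rest = key.partition("/")
    num = "".join(ch for ch in rest if ch.isdigit() or ch == "-")
    icode = rest[len(num):]
    return (chain, int(num) if num else 0, icode)


def contact_trace(
    states: Sequence[tuple[str, Structure]],
    substrate_id: str,
    cutoff: float = 3.0,
    probe: float = 1.5,
    n_points: int = 960,
) -> pd.DataFrame:
    """Residue × state table of contact areas across reaction snapshots.

    Each state is a (label, Structure) pair containing the substrate
    residue *substrate_id*; residues with no contact in any state are
    dropped.  Returns a DataFrame indexed by residue key with one
    ``area:<state>`` and one ``class:<state>`` column per state.
    """
    if not states:
        raise ValueError("need at least one state")
    per_state: dict[str, dict[str, float]] = {}
    for label, st in states:
        try:
            substrate = st.residue(substrate_id)
        except KeyError:
            raise KeyError(f"state {label!r} lacks substrate {substrate_id!r}")
        receptor = _without_residue(st, substrate_id)
        surf = sample_surface(substrate.atoms, probe=probe, n=n_points)
        recs = residue_contact_areas(surf, receptor, cutoff=cutoff, state_label=label)
        per_state[label] = {r.residue: r.area for r in recs}

    residues = sorted(
        {r for areas in per_state.values() for r in areas}, key=_res_sort_key
    )
    data: dict[str, list] = {}
    for label, _ in states:
        areas = [per_state[label].get(r, 0.0) for r in residues]
        data[f"area:{label}"] = areas
        data[f"class:{label}"] = [classify_contact(a) for a in areas]
    return pd.DataFrame(data, index=pd.Index(residues, name="residue"))


def _without_residue(s: Structure, key: str) -> Structure:
    out = Structure(entry_id=s.entry_id, cell=s.cell, space_group=s.space_group)
    for chain_id, residues in s.chains.items():
        kept = [r for r in residues if r.key != key]
        if kept:
            out.chains[chain_id] = kept
    return out


# ---------------------------------------------------------------------------
# In-silico mutagenesis


@dataclass
class MutationSpec:
    """A side-chain edit expressible as terminal heavy-atom deletions plus at
    most one ideal-geometry methyl addition."""

    residue: str
    from_aa: str
    to_aa: str
    delete_atoms: tuple[str, ...] = ()
    add_methyl_on: str | None = None
    rename_atoms: dict[str, tuple[str, str]] = field(default_factory=dict)

    @classmethod
    def standard(cls, residue: str, from_aa: str, to_aa: str) -> "MutationSpec":
        """Look up a supported substitution (sterically shrinking edits and
        single-methyl growths)."""
        table = _SUPPORTED_MUTATIONS.get((from_aa.upper(), to_aa.upper()))
        if table is None:
            raise ValueError(
                f"unsupported mutation {from_aa}->{to_aa}: only terminal "
                "deletions and single-methyl additions are expressible"
            )
        return cls(residue=residue, from_aa=from_aa.upper(), to_aa=to_aa.upper(), **table)


# Supported edits; deletions are terminal heavy atoms of the source side chain.
_SUPPORTED_MUTATIONS: dict[tuple[str, str], dict] = {
    ("LEU", "ALA"): {"delete_atoms": ("CG", "CD1", "CD2")},
    ("LEU", "VAL"): {"delete_atoms": ("CD1",)},
    ("LEU", "ILE"): {"delete_atoms": ("CD2",), "add_methyl_on": "CB"},
    ("SER", "GLY"): {"delete_atoms": ("OG", "CB")},
    ("SER", "THR"): {"add_methyl_on": "CB"},
    ("ASN", "SER"): {
        "delete_atoms": ("OD1", "ND2"),
        "rename_atoms": {"CG": ("OG", "O")},
    },
    ("THR", "SER"): {"delete_atoms": ("CG2",)},
    ("VAL", "ALA"): {"delete_atoms": ("CG1", "CG2")},
}


def _methyl_position(res: Residue, parent_name: str, bond_length: float = 1.52) -> np.ndarray:
    """Ideal position for a methyl carbon on *parent*: along the negative sum
    of unit vectors to the parent's bonded heavy neighbours (tetrahedral,
    staggered by construction)."""
    parent = res.atom(parent_name)
    neighbours = [
        a
        for a in res.atoms
        if a.name != parent_name
        and not a.is_hydrogen
        and np.linalg.norm(a.coords - parent.coords) < 1.8
    ]
    if not neighbours:
        direction = np.array([1.0, 0.0, 0.0])
    else:
        vecs = [
            (a.coords - parent.coords) / np.linalg.norm(a.coords - parent.coords)
            for a in neighbours
        ]
        direction = -np.sum(vecs, axis=0)
        norm = np.linalg.norm(direction)
        if norm < 1e-6:
            # neighbours cancel; pick any perpendicular
            direction = np.cross(vecs[0], np.array([0.0, 0.0, 1.0]))
            if np.linalg.norm(direction) < 1e-6:
                direction = np.cross(vecs[0], np.array([0.0, 1.0, 0.0]))
            norm = np.linalg.norm(direction)
        direction /= norm
    return parent.coords + bond_length * direction


def apply_mutation(s: Structure, m: MutationSpec) -> Structure:
    """Apply a side-chain mutation to a copy of *s*: delete the named
    terminal heavy atoms, optionally add one methyl carbon at ideal
    tetrahedral geometry (C–C 1.52 Å), and rename the residue."""
    out = s.copy()
    res = out.residue(m.residue)
    if res.res_name.upper() != m.from_aa.upper():
        raise ValueError(
            f"residue {m.residue} is {res.res_name}, mutation expects {m.from_aa}"
        )
    missing = [n for n in m.delete_atoms if not res.has_atom(n)]
    if missing:
        raise ValueError(f"residue {m.residue} lacks atoms {missing}")
    res.atoms = [a for a in res.atoms if a.name not in set(m.delete_atoms)]
    for old, (new, element) in m.rename_atoms.items():
        if res.has_atom(old):
            a = res.atom(old)
            a.name = new
            a.element = element
    if m.add_methyl_on is not None:
        pos = _methyl_position(res, m.add_methyl_on)
        serial = max((a.serial for a in res.atoms), default=0) + 1
        new_name = "CG2" if m.add_methyl_on == "CB" else "CX1"
        res.atoms.append(Atom(serial=serial, name=new_name, element="C", coords=pos))
    res.res_name = m.to_aa.upper()
    return out


def screen_mutation(
    states: Sequence[tuple[str, Structure]],
    m: MutationSpec,
    substrate_id: str,
    cutoff: float = 3.0,
    probe: float = 1.5,
    n_points: int = 960,
) -> pd.DataFrame:
    """Per-state change in the mutated residue's substrate contact.

    Returns a DataFrame with one row per state: wild-type area, mutant
    area, Δarea and both contact classes, plus a ``sign_change`` flag where
    Δ flips sign relative to the neighbouring state (transition-state-
    versus-product clash logic).
    """
    rows = []
    for label, st in states:
        mutant = apply_mutation(st, m)
        wt_trace = contact_trace([(label, st)], substrate_id, cutoff, probe, n_points)
        mut_trace = contact_trace(
            [(label, mutant)], substrate_id, cutoff, probe, n_points
        )
        a_wt = float(wt_trace[f"area:{label}"].get(m.residue, 0.0)) if not wt_trace.empty else 0.0
        a_mut = (
            float(mut_trace[f"area:{label}"].get(m.residue, 0.0))
            if not mut_trace.empty
            else 0.0
        )
        rows.append(
            {
                "state": label,
                "area_wt": a_wt,
                "area_mut": a_mut,
                "delta": a_mut - a_wt,
                "class_wt": classify_contact(a_wt),
                "class_mut": classify_contact(a_mut),
            }
        )
    df = pd.DataFrame(rows)
    deltas = df["delta"].to_numpy()
    flags = np.zeros(len(df), dtype=bool)
    for i in range(1, len(df)):
        if deltas[i] * deltas[i - 1] < 0:
            flags[i] = True
    df["sign_change"] = flags
    return df


def copy_structure(s: Structure) -> Structure:
    return copy.deepcopy(s)
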