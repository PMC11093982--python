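"""Lightweight macromolecular structure containers and PDB/mmCIF I/O.

The hierarchy is deliberately small: a :class:`Structure` holds ordered
chains of :class:`Residue` objects, each an ordered list of
:class:`Atom` records with coordinates in Å.  Parsing of both PDB and
mmCIF dialects is delegated to :mod:`gemmi`; this module only resolves
alternate locations (highest occupancy wins, ties broken by file order)
and attaches the classification flags the downstream stages need
(polymer / water / ligand).

Residues are addressed throughout the package by a *residue key* string
``"<chain>/<seqnum>[<icode>]"``, e.g. ``"A/164"``.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Transform",
    "Selection",
    "read_structure",
    "write_structure",
    "apply_transform",
    "select",
]

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be 3 finite numbers")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element symbol must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    is_polymer: bool = True
    is_water: bool = False
    is_ligand: bool = False

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(
                f"residue {self.key}: duplicate atom names {dupes}"
            )
        if sum((self.is_polymer, self.is_water, self.is_ligand)) > 1:
            raise ValueError(f"residue {self.key}: classification flags must be exclusive")

    @property
    def key(self) -> str:
        return f"{self.chain_id}/{self.seq_id}{self.icode}"

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.key} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else self.atoms
        if not atoms:
            return np.zeros((0, 3))
        return np.stack([a.coords for a in atoms])


@dataclass
class Transform:
    """Rigid-body map x -> R·x + t used to build symmetry/assembly mates."""

    rotation: np.ndarray  # 3x3
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("transform needs a 3x3 rotation and a 3-vector translation")
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-6:
            raise ValueError(f"rotation determinant {det} != +1")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthonormal")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class Structure:
    entry_id: str = ""
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None
    assembly_operators: list[Transform] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cell is not None and any(x <= 0 for x in self.cell[:3]):
            raise ValueError("cell lengths must be positive")

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    def atom_count(self, heavy_only: bool = False) -> int:
        return sum(
            1 for a in self.atoms() if not (heavy_only and a.is_hydrogen)
        )

    def residue(self, key: str) -> Residue:
        chain_id, _, rest = key.partition("/")
        for res in self.chains.get(chain_id, []):
            if f"{res.seq_id}{res.icode}" == rest:
                return res
        raise KeyError(f"no residue {key!r} in structure {self.entry_id!r}")

    def all_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms()]
        return np.stack(pts) if pts else np.zeros((0, 3))

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# I/O


def _classify(res: gemmi.Residue, in_polymer: bool) -> tuple[bool, bool, bool]:
    name = res.name.strip().upper()
    if name in _WATER_NAMES or res.is_water():
        return False, True, False
    if in_polymer and res.het_flag != "H":
        return True, False, False
    return False, False, True


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Collapse alternate locations: per atom name keep the highest-occupancy
    conformer, first-in-file on ties."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in res:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > prev.occ:
            best[atom.name] = atom
    return [best[name] for name in order]


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All ATOM/HETATM records are retained, waters flagged, and alternate
    locations resolved to the highest-occupancy conformer.  Unit cell and
    space group are captured when the file carries them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        elif fmt == "auto":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path.name}: {exc}") from exc

    st.setup_entities()
    out = Structure(entry_id=st.name or path.stem)
    if st.cell and st.cell.a > 0:
        c = st.cell
        out.cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    if st.spacegroup_hm:
        out.space_group = st.spacegroup_hm

    if len(st) == 0:
        return out
    model = st[0]
    for chain in model:
        polymer_names = {r.name for r in chain.get_polymer()}
        residues: list[Residue] = []
        for gres in chain:
            in_poly = gres.name in polymer_names and gres.het_flag != "H"
            is_poly, is_wat, is_lig = _classify(gres, in_poly)
            atoms = []
            for ga in _resolve_altlocs(gres):
                element = ga.element.name if ga.element.name else _infer_element(ga.name)
                atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=ga.name,
                        element=element,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        b_factor=ga.b_iso,
                    )
                )
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_id=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    res_name=gres.name,
                    atoms=atoms,
                    is_polymer=is_poly,
                    is_water=is_wat,
                    is_ligand=is_lig,
                )
            )
        if residues:
            out.chains[chain.name] = residues
    return out


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if len(stripped) >= 2 and stripped[:2].upper() in VDW_TWO_LETTER:
        return stripped[:2].capitalize()
    return stripped[0].upper()


VDW_TWO_LETTER = {"CL", "BR", "ZN", "MG", "FE", "MN", "SE", "NA"}


def write_structure(s: Structure, path: str | Path) -> None:
    """Write *s* as PDB text; a CRYST1 record is emitted when the cell is set."""
    st = gemmi.Structure()
    st.name = s.entry_id or "XXXX"
    if s.cell is not None:
        st.cell = gemmi.UnitCell(*s.cell)
    if s.space_group:
        st.spacegroup_hm = s.space_group
    model = gemmi.Model("1")
    for chain_id, residues in s.chains.items():
        if len(chain_id) > 2:
            raise ValueError(f"chain id {chain_id!r} too wide for PDB format")
        chain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            gres.het_flag = "A" if res.is_polymer else "H"
            for a in res.atoms:
                if len(a.name) > 4:
                    raise ValueError(f"atom name {a.name!r} unrepresentable in PDB")
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# Geometry and selection


def apply_transform(s: Structure, t: Transform, new_chain_suffix: str = "") -> Structure:
    """Return a copy of *s* with coordinates mapped through *t* and chain ids
    suffixed by *new_chain_suffix*; the input is untouched."""
    out = s.copy()
    new_chains: dict[str, list[Residue]] = {}
    for chain_id, residues in out.chains.items():
        new_id = chain_id + new_chain_suffix
        for res in residues:
            res.chain_id = new_id
            for a in res.atoms:
                a.coords = t.apply(a.coords)
        new_chains[new_id] = residues
    out.chains = new_chains
    return out


@dataclass
class Selection:
    """Declarative atom-set predicate used by :func:`select`."""

    chains: Sequence[str] | None = None
    residue_ranges: Sequence[tuple[int, int]] | None = None
    res_names: Sequence[str] | None = None
    waters: bool | None = None
    ligands: bool | None = None
    polymer: bool | None = None

    def matches(self, res: Residue) -> bool:
        if self.chains is not None and res.chain_id not in self.chains:
            return False
        if self.residue_ranges is not None and not any(
            lo <= res.seq_id <= hi for lo, hi in self.residue_ranges
        ):
            return False
        if self.res_names is not None and res.res_name not in self.res_names:
            return False
        if self.waters is not None and res.is_water != self.waters:
            return False
        if self.ligands is not None and res.is_ligand != self.ligands:
            return False
        if self.polymer is not None and res.is_polymer != self.polymer:
            return False
        return True


def select(s: Structure, predicate: Selection) -> Structure:
    """Subset *s* to residues matching *predicate*.  Idempotent; an empty
    match yields an empty Structure rather than an error."""
    out = Structure(
        entry_id=s.entry_id,
        cell=s.cell,
        space_group=s.space_group,
        assembly_operators=list(s.assembly_operators),
    )
    for chain_id, residues in s.chains.items():
        kept = [copy.deepcopy(r) for r in residues if predicate.matches(r)]
        if kept:
            out.chains[chain_id] = kept
    return out


def pairwise_min_distance(res_a: Residue, res_b: Residue, heavy_only: bool = True) -> float:
    """Minimum interatomic distance between two residues, Å."""
    ca = res_a.coords(heavy_only=heavy_only)
    cb = res_b.coords(heavy_only=heavy_only)
    if ca.size == 0 or cb.size == 0:
        return math.inf
    diff = ca[:, None, :] - cb[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=-1)).min())
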