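"""Synthetic fixtures with planted ground truth.

Every analysis stage in the package can be exercised without any
deposited structure or instrument export: this module builds small
protein-like structures with a catalytic residue and a pseudo-ligand,
dimer "interfaces" with exactly known numbers of salt bridges, hydrogen
bonds and nonbonded contacts, reactive systems whose energy along the
reacting-pair distance has an analytically solvable single barrier, and
noisy 1:1 Langmuir sensorgrams at stated rate constants.  Geometry is
idealized — canonical bond lengths on regular grids — because fixtures
exist to make cutoff logic and oracles exact, not to fold proteins.

All randomness flows through one seeded generator (default seed
20240514); regenerating with the same seed reproduces the fixture
bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .active_site import ActiveSiteModel, assign_mobility
from .scan import PairPotentialBackend, avoided_crossing
from .spr import Sensorgram, simulate_sensorgram
from .structures import Atom, Residue, Structure

__all__ = [
    "FixtureManifest",
    "make_toy_receptor",
    "make_dimer_fixture",
    "make_scan_system",
    "make_sensorgram_set",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20240514


@dataclass
class FixtureManifest:
    seed: int
    kind: str
    truth: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"seed": self.seed, "kind": self.kind, "truth": self.truth},
            indent=2,
            sort_keys=True,
            default=_json_default,
        )
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Toy receptor with a defined catalytic residue and pocket ligand

# local template: idealized backbone + CB, coordinates in Å
_TEMPLATE = {
    "N": np.array([0.0, 0.0, 0.0]),
    "CA": np.array([1.46, 0.0, 0.0]),
    "C": np.array([2.02, 1.37, 0.0]),
    "O": np.array([3.24, 1.49, 0.0]),
    "CB": np.array([1.95, -0.77, 1.21]),
}


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


_CB = _TEMPLATE["CB"]
_D1 = _unit([0.5, -1.0, 0.85])
# idealized side chains at canonical bond lengths, per residue name
_SIDE_CHAINS: dict[str, dict[str, np.ndarray]] = {
    "ALA": {},
    "CYS": {"SG": _CB + 1.81 * _D1},
    "SER": {"OG": _CB + 1.41 * _D1},
    "LEU": {
        "CG": _CB + 1.52 * _D1,
        "CD1": _CB + 1.52 * _D1 + 1.52 * _unit([1.0, 0.3, -0.2]),
        "CD2": _CB + 1.52 * _D1 + 1.52 * _unit([-0.3, -0.5, 1.0]),
    },
}


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _build_residue(
    chain: str, seq: int, name: str, origin: np.ndarray, rot: np.ndarray, serial0: int,
) -> Residue:
    atoms = []
    serial = serial0
    locals_ = dict(_TEMPLATE)
    locals_.update(_SIDE_CHAINS.get(name, {}))
    for aname, local in locals_.items():
        atoms.append(
            Atom(serial=serial, name=aname, element=aname[0], coords=origin + rot @ local)
        )
        serial += 1
    return Residue(chain_id=chain, seq_id=seq, res_name=name, atoms=atoms)


def make_toy_receptor(
    n_residues: int = 40,
    pocket_radius: float = 4.0,
    seed: int = DEFAULT_SEED,
) -> tuple[Structure, FixtureManifest]:
    """Concave pseudo-receptor: one catalytic cysteine at the pocket center,
    the remaining residues scattered at scripted radial distances (avoiding
    the 12.0 Å inclusion boundary), and a rigid pseudo-ligand seated
    *pocket_radius* Å from the catalytic thiol.

    The manifest records brute-force minimum heavy-atom distances of every
    residue to the catalytic residue and the resulting inclusion set at
    12.0 Å, plus the ligand atom names.
    """
    if n_residues < 5:
        raise ValueError("need at least 5 residues")
    rng = np.random.default_rng(seed)
    st = Structure(entry_id=f"TOYR{seed % 10000:04d}")
    residues: list[Residue] = []

    cat_seq = n_residues // 2
    serial = 1
    cat = _build_residue("A", cat_seq, "CYS", np.zeros(3), np.eye(3), serial)
    serial += len(cat.atoms)

    # radial distances scripted away from the 12.0 Å boundary
    names = ["ALA", "SER", "LEU"]
    placed: dict[int, Residue] = {cat_seq: cat}
    for i in range(n_residues - 1):
        seq = i if i < cat_seq else i + 1
        while True:
            r = rng.uniform(5.0, 20.0)
            if abs(r - 12.0) > 0.8:
                break
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        rot = _random_rotation(rng)
        res = _build_residue(
            "A", seq, names[i % 3], direction * r, rot, serial
        )
        serial += len(res.atoms)
        placed[seq] = res
    residues = [placed[k] for k in sorted(placed)]
    st.chains["A"] = residues

    # pseudo-ligand: short thioester-like chain near the catalytic SG
    sg = cat.atom("SG").coords
    towards = sg / (np.linalg.norm(sg) + 1e-9) if np.linalg.norm(sg) > 1e-6 else np.array([1.0, 0, 0])
    base = sg + np.array([1.0, 0.2, 0.1]) / np.linalg.norm([1.0, 0.2, 0.1]) * pocket_radius
    lig_atoms = [
        Atom(serial=serial, name="C1", element="C", coords=base),
        Atom(serial=serial + 1, name="O1", element="O", coords=base + np.array([0.0, 1.23, 0.0])),
        Atom(serial=serial + 2, name="C2", element="C", coords=base + np.array([1.52, 0.0, 0.0])),
        Atom(serial=serial + 3, name="C3", element="C", coords=base + np.array([2.28, 1.32, 0.0])),
        Atom(serial=serial + 4, name="S1P", element="S", coords=base + np.array([3.7, 1.3, 0.6])),
    ]
    ligand = Residue(
        chain_id="L", seq_id=1, res_name="LIG", atoms=lig_atoms,
        is_polymer=False, is_ligand=True,
    )
    st.chains["L"] = [ligand]

    # brute-force distance oracle for the manifest
    cat_coords = cat.coords(heavy_only=True)
    min_dist: dict[str, float] = {}
    for res in residues:
        cc = res.coords(heavy_only=True)
        diff = cc[:, None, :] - cat_coords[None, :, :]
        min_dist[res.key] = float(np.sqrt((diff**2).sum(axis=-1)).min())
    inclusion = sorted(k for k, d in min_dist.items() if d <= 12.0)

    lig_min = min(
        float(np.linalg.norm(a.coords - b.coords))
        for a in lig_atoms
        for res in residues
        for b in res.heavy_atoms()
    )
    manifest = FixtureManifest(
        seed=seed,
        kind="toy_receptor",
        truth={
            "catalytic_residue": cat.key,
            "min_distance_to_catalytic": min_dist,
            "inclusion_set_12A": inclusion,
            "ligand_atoms": [a.name for a in lig_atoms],
            "ligand_clash": lig_min < 2.0,
            "n_residues": n_residues,
        },
    )
    return st, manifest


# ---------------------------------------------------------------------------
# Dimer fixture with planted interaction counts


def _single_atom_residue(
    chain: str, seq: int, res_name: str, atom_name: str, element: str,
    pos: np.ndarray, serial: int,
) -> Residue:
    return Residue(
        chain_id=chain,
        seq_id=seq,
        res_name=res_name,
        atoms=[Atom(serial=serial, name=atom_name, element=element, coords=pos)],
    )


def make_dimer_fixture(
    k_bridges: int = 6,
    m_hbonds: int = 32,
    p_contacts: int = 318,
    seed: int = DEFAULT_SEED,
) -> tuple[tuple[Structure, Structure], FixtureManifest]:
    """Two pseudo-protomers with exactly the requested interaction counts
    under the default cutoffs: salt bridges at 3.95 Å (inside the 4.0 Å
    bridge cutoff, outside both the 3.35 Å H-bond and 3.9 Å nonbonded
    cutoffs), hydrogen bonds at 2.90 Å, plain carbon contacts at 3.70 Å.
    Interaction units sit on an 8 Å grid so no cross-unit pair falls inside
    any cutoff; decoy atoms sit 5.5 Å across the interface.
    """
    if min(k_bridges, m_hbonds, p_contacts) < 0:
        raise ValueError("counts must be non-negative")
    total = k_bridges + m_hbonds + p_contacts
    if total > 2500:
        raise ValueError("requested interaction density is geometrically infeasible")
    rng = np.random.default_rng(seed)
    pitch = 8.0
    side = max(int(np.ceil(np.sqrt(max(total + 4, 1)))), 2)

    a = Structure(entry_id="DIMA")
    b = Structure(entry_id="DIMB")
    a.chains["A"] = []
    b.chains["B"] = []
    serial_a = serial_b = 1
    seq_a = seq_b = 1

    kinds = (
        [("bridge", 3.95)] * k_bridges
        + [("hbond", 2.90)] * m_hbonds
        + [("contact", 3.70)] * p_contacts
        + [("decoy", 5.50)] * 4
    )
    for unit, (kind, dz) in enumerate(kinds):
        gx, gy = divmod(unit, side)
        jitter = rng.uniform(-0.3, 0.3, size=2)
        x, y = gx * pitch + jitter[0], gy * pitch + jitter[1]
        pos_a = np.array([x, y, 0.0])
        pos_b = np.array([x, y, -dz])
        if kind == "bridge":
            ra = _single_atom_residue("A", seq_a, "ASP", "OD1", "O", pos_a, serial_a)
            rb = _single_atom_residue("B", seq_b, "ARG", "NH1", "N", pos_b, serial_b)
        elif kind == "hbond":
            ra = _single_atom_residue("A", seq_a, "SER", "OG", "O", pos_a, serial_a)
            rb = _single_atom_residue("B", seq_b, "SER", "OG", "O", pos_b, serial_b)
        elif kind == "contact":
            ra = _single_atom_residue("A", seq_a, "ALA", "CB", "C", pos_a, serial_a)
            rb = _single_atom_residue("B", seq_b, "ALA", "CB", "C", pos_b, serial_b)
        else:  # decoy: polar pair outside every cutoff + 1.0 Å margin
            ra = _single_atom_residue("A", seq_a, "GLY", "O", "O", pos_a, serial_a)
            rb = _single_atom_residue("B", seq_b, "GLY", "N", "N", pos_b, serial_b)
        a.chains["A"].append(ra)
        b.chains["B"].append(rb)
        seq_a += 1
        seq_b += 1
        serial_a += 1
        serial_b += 1

    manifest = FixtureManifest(
        seed=seed,
        kind="dimer",
        truth={
            "salt_bridges": k_bridges,
            "hbonds": m_hbonds,
            "nonbonded_contacts": p_contacts,
            "decoys": 4,
        },
    )
    return (a, b), manifest


# ---------------------------------------------------------------------------
# Reactive system with an analytically known barrier


def _measure_barrier(
    f, lo: float, hi: float, ref: float, grid: float = 0.001
) -> tuple[float, float]:
    """Dense-grid maximum of f on [lo, hi] relative to f(ref): (height, position)."""
    d = np.arange(lo, hi + grid / 2, grid)
    e = np.asarray(f(d))
    if e.shape != d.shape:  # non-vectorizable potential
        e = np.array([f(x) for x in d])
    i = int(np.argmax(e))
    return float(e[i] - f(ref)), float(d[i])


def _solve_crossing(
    barrier_height: float,
    barrier_position: float,
    r_p: float,
    r_r: float,
    k2: float,
    w: float,
):
    """Solve the reactant stiffness k1 and diabat offset dH so the lower
    adiabat has a stationary point of the requested height (relative to the
    start r_r) at the requested position; confirm on a dense grid that the
    stationary point is the global maximum of the scan window."""

    def build(k1: float, dh: float):
        e1 = lambda d: k1 * (d - r_r) ** 2
        e2 = lambda d: k2 * (d - r_p) ** 2 + dh
        return avoided_crossing(e1, e2, w)

    def adiabat_slope(f, d, eps=1e-6):
        return (f(d + eps) - f(d - eps)) / (2 * eps)

    def equations(params):
        k1, dh = params
        if k1 <= 1e-6:
            return np.array([1e3, 1e3])
        f = build(k1, dh)
        return np.array(
            [
                f(barrier_position) - f(r_r) - barrier_height,
                adiabat_slope(f, barrier_position),
            ]
        )

    k1_0 = (barrier_height + w) / (barrier_position - r_r) ** 2
    dh_0 = k1_0 * (barrier_position - r_r) ** 2 - k2 * (barrier_position - r_p) ** 2
    sol = least_squares(equations, x0=[k1_0, dh_0], xtol=1e-14, ftol=1e-14)
    k1, dh = sol.x
    f = build(k1, dh)
    h, p = _measure_barrier(f, r_p, r_r, r_r)
    if abs(h - barrier_height) > 0.05 or abs(p - barrier_position) > 0.02:
        raise ValueError(
            f"solved height {h:.3f} at {p:.3f} vs requested "
            f"{barrier_height} at {barrier_position} (k2={k2:.2f}, W={w:.2f})"
        )
    return float(k1), float(dh), f, h, p


def make_scan_system(
    barrier_height: float = 40.0,
    barrier_position: float = 2.6,
    covalent_target: float = 1.81,
    seed: int = DEFAULT_SEED,
    start_distance: float | None = None,
    coupling: float | None = None,
) -> tuple[ActiveSiteModel, PairPotentialBackend, FixtureManifest]:
    """Two-state avoided-crossing system along a C···S reacting pair.

    The reactant diabat is harmonic about the start separation, the
    product diabat harmonic about the covalent distance; the diabat offset
    and reactant stiffness are solved so that the dense-grid barrier of
    the lower adiabat equals *barrier_height* (kcal/mol, relative to the
    start point) within 0.05 and sits at *barrier_position* within 0.02 Å.
    """
    rng = np.random.default_rng(seed)
    if start_distance is None:
        start_distance = covalent_target + rng.uniform(2.3, 2.8)
    if not covalent_target + 0.2 < barrier_position < start_distance - 0.2:
        raise ValueError("barrier_position must lie between covalent target and start")
    r_r, r_p = start_distance, covalent_target
    last_error = "no parameter draw attempted"
    for _attempt in range(12):
        # soft diabats + moderate coupling keep the top-of-barrier curvature
        # modest (|E''| ~ 40 kcal/mol/Å²) so a 0.05 Å step resolves the
        # height to well under 0.1 kcal/mol, while the maximum stays interior
        w = rng.uniform(12.0, 18.0) if coupling is None else float(coupling)
        k2 = rng.uniform(6.0, 10.0)
        try:
            k1, dh, f, h, p = _solve_crossing(
                barrier_height, barrier_position, covalent_target,
                start_distance, k2, w,
            )
            break
        except ValueError as exc:
            last_error = str(exc)
            if coupling is not None:
                raise
    else:
        raise ValueError(f"unattainable barrier specification: {last_error}")

    # minimal model: catalytic CYS (rigid) + single-atom ligand (mobile)
    cat = _build_residue("A", 1, "CYS", np.zeros(3), np.eye(3), 1)
    sg = cat.atom("SG").coords
    lig = Residue(
        chain_id="L",
        seq_id=1,
        res_name="LIG",
        atoms=[
            Atom(serial=10, name="C1", element="C",
                 coords=sg + np.array([start_distance, 0.0, 0.0]))
        ],
        is_polymer=False,
        is_ligand=True,
    )
    model = ActiveSiteModel(
        source_entry="SCANSYS",
        catalytic_residue=cat.key,
        inclusion_radius=12.0,
        residues=[cat],
        ligand=lig,
    )
    model = assign_mobility(model, reactive_residues=set())

    # atom order in the model: catalytic residue atoms then ligand
    keys = [k for k, _ in model.atoms()]
    pair = (keys.index("L/1:C1"), keys.index("A/1:SG"))
    backend = PairPotentialBackend(pair, f, name=f"avoided-crossing(seed={seed})")

    manifest = FixtureManifest(
        seed=seed,
        kind="scan_system",
        truth={
            "barrier_height_kcal_mol": h,
            "barrier_position_A": p,
            "covalent_target_A": covalent_target,
            "start_distance_A": start_distance,
            "reacting_pair": ["L/1:C1", "A/1:SG"],
            "params": {"k1": float(k1), "k2": float(k2), "dH": float(dh), "W": float(w)},
        },
    )
    return model, backend, manifest


# ---------------------------------------------------------------------------
# Sensorgram sets


def make_sensorgram_set(
    ka: float = 1.0e4,
    kd: float = 1.0e-2,
    rmax: float = 120.0,
    concs: list[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = DEFAULT_SEED,
    t_assoc_end: float = 120.0,
    t_total: float = 360.0,
    dt: float = 1.0,
) -> tuple[list[Sensorgram], FixtureManifest]:
    """1:1 Langmuir sensorgrams at each concentration, with Gaussian noise
    drawn from one seeded stream; the manifest records the kinetic truth."""
    kd_const = kd / ka
    if concs is None:
        concs = [0.2 * kd_const, 0.5 * kd_const, kd_const, 2.0 * kd_const, 5.0 * kd_const]
    times = np.arange(dt, t_total + dt / 2, dt)
    rng = np.random.default_rng(seed)
    out = []
    for c in concs:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        out.append(
            simulate_sensorgram(ka, kd, rmax, c, times, t_assoc_end, noise_sd, sub_seed)
        )
    manifest = FixtureManifest(
        seed=seed,
        kind="sensorgrams",
        truth={
            "ka": ka,
            "kd": kd,
            "Rmax": rmax,
            "KD": kd_const,
            "concs_M": list(concs),
            "noise_sd_RU": noise_sd,
        },
    )
    return out, manifest
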