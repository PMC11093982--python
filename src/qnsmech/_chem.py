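"""Element tables shared by the geometric modules.

Van der Waals radii follow Bondi's compilation (values in Å); covalent
radii are single-bond values used to infer connectivity and to default
the "expected covalent distance" of a reaction scan.
"""

from __future__ import annotations

# Bondi-style van der Waals radii, Å.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "FE": 1.63,
    "MN": 1.61,
}

# Single-bond covalent radii, Å (Cordero-style, rounded).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
    "F": 0.57,
    "CL": 1.02,
    "BR": 1.20,
    "SE": 1.20,
}

# Ideal cap-hydrogen bond lengths by heavy-atom element, Å.
CAP_H_BOND: dict[str, float] = {"N": 1.01, "C": 1.09, "O": 0.96, "S": 1.34}


def vdw_radius(element: str) -> float:
    """Bondi van der Waals radius for *element* (case-insensitive).

    Raises ``KeyError`` naming the element when it is not tabulated.
    """
    try:
        return VDW_RADII[element.upper()]
    except KeyError:
        raise KeyError(f"no van der Waals radius tabulated for element {element!r}")


def covalent_distance(elem_a: str, elem_b: str) -> float:
    """Sum of single-bond covalent radii, e.g. C–S -> 1.81 Å."""
    try:
        return COVALENT_RADII[elem_a.upper()] + COVALENT_RADII[elem_b.upper()]
    except KeyError as exc:
        raise KeyError(f"no covalent radius tabulated for element {exc.args[0]!r}")
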