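"""Element tables used to assign scattering properties to atoms.

Van der Waals radii are the Bondi (1964) values for the elements common in
proteins, supplemented with the Alvarez (2013) consensus values for metals
Bondi did not tabulate.  Electron counts are atomic numbers (neutral atoms).
Elements missing from the table fall back to ``DEFAULT_VDW_RADIUS`` with a
logged warning.
"""

from __future__ import annotations

# Å
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "SE": 1.90,
    "NA": 2.27,
    "MG": 1.73,
    "K": 2.75,
    "CA": 2.31,
    "MN": 2.45,
    "FE": 2.44,
    "ZN": 1.39,
    "CU": 1.40,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1,
    "C": 6,
    "N": 7,
    "O": 8,
    "F": 9,
    "NA": 11,
    "MG": 12,
    "P": 15,
    "S": 16,
    "CL": 17,
    "K": 19,
    "CA": 20,
    "MN": 25,
    "FE": 26,
    "CU": 29,
    "ZN": 30,
    "SE": 34,
}

# fallback for elements absent from the table (carbon-like)
DEFAULT_VDW_RADIUS = 1.70
DEFAULT_N_ELECTRONS = 6

HYDROGEN_SYMBOLS = frozenset({"H", "D", "T"})


def vdw_radius(element: str) -> float | None:
    """Tabulated van der Waals radius in Å, or None if unknown."""
    return VDW_RADII.get(element.strip().upper())


def n_electrons(element: str) -> int | None:
    """Electron count of the neutral atom, or None if unknown."""
    return ATOMIC_NUMBERS.get(element.strip().upper())
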