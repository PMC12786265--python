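"""Subunit structures and their conversion to helical scatterer sets.

A filament subunit (e.g. a G-actin monomer) is read from a PDB file, stripped
of hydrogens, and every remaining atom is assigned a van der Waals radius, an
electron count and an effective volume

    v_eff = volume_scale * (4/3) * pi * r_vdw**3.

With ``volume_scale=1`` (the default) the effective volumes are the raw vdW
sphere volumes; a 0.34 packing prefactor is selectable for users who prefer
effective (non-overlapping) atomic volumes.

Each atom then becomes one *scatterer site*: in cylindrical coordinates about
the filament axis it is characterised by its helix-cylinder radius r0, its
azimuth psi1 and axial offset z1 within the first monomer, an equivalent
sphere radius rs (from v_eff), and an electron-count weight.  Every site
defines its own discontinuous helix along the filament.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .elements import (
    DEFAULT_N_ELECTRONS,
    DEFAULT_VDW_RADIUS,
    HYDROGEN_SYMBOLS,
    n_electrons,
    vdw_radius,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ScattererSet",
    "load_monomer",
    "to_scatterers",
    "generate_synthetic_monomer",
    "write_scatterer_table",
    "read_scatterer_table",
]

_FOUR_THIRDS_PI = 4.0 / 3.0 * math.pi


@dataclass(frozen=True)
class AtomRecord:
    """One non-hydrogen atom of the subunit.

    position is Cartesian (x, y, z) in Å in the frame of the input structure;
    vdw_radius in Å; n_electrons the neutral-atom electron count; v_eff the
    effective atomic volume in ų.
    """

    element: str
    position: tuple[float, float, float]
    vdw_radius: float
    n_electrons: int
    v_eff: float


@dataclass
class ScattererSet:
    """Cylindrical-coordinate scatterer sites of one subunit.

    Arrays are aligned by site: helix-cylinder radius ``r0`` (Å), first-monomer
    azimuth ``psi1`` (rad), first-monomer axial offset ``z1`` (Å), equivalent
    sphere radius ``rs`` (Å) and electron-count ``weight``.
    """

    r0: np.ndarray
    psi1: np.ndarray
    z1: np.ndarray
    rs: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.r0 = np.asarray(self.r0, dtype=float)
        self.psi1 = np.asarray(self.psi1, dtype=float)
        self.z1 = np.asarray(self.z1, dtype=float)
        self.rs = np.asarray(self.rs, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        if not (
            self.r0.shape
            == self.psi1.shape
            == self.z1.shape
            == self.rs.shape
            == self.weight.shape
        ):
            raise ValueError("all ScattererSet arrays must have the same shape")
        if np.any(self.r0 < 0):
            raise ValueError("helix radii r0 must be >= 0")
        if np.any(self.rs <= 0):
            raise ValueError("sphere radii rs must be > 0")
        if np.any(self.weight <= 0):
            raise ValueError("weights must be > 0")

    @property
    def n_sites(self) -> int:
        return self.r0.size

    @property
    def total_weight(self) -> float:
        return float(self.weight.sum())


def _effective_volume(r_vdw: float, volume_scale: float) -> float:
    return volume_scale * _FOUR_THIRDS_PI * r_vdw**3


def load_monomer(path: str | Path, volume_scale: float = 1.0) -> list[AtomRecord]:
    """Read one subunit from a PDB file (ATOM/HETATM records).

    Hydrogens (and deuteriums) are dropped.  For alternate locations only the
    first altloc is kept; occupancies are ignored.  Unknown elements fall back
    to a carbon-like default radius with a warning.

    Raises ValueError for unparsable files or structures without heavy atoms.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise ValueError(f"could not parse PDB file {path}: {exc}") from None
    if len(st) == 0:
        raise ValueError(f"no models in structure {path}")

    records: list[AtomRecord] = []
    for chain in st[0]:
        for residue in chain:
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                symbol = atom.element.name.upper()
                if not symbol or symbol == "X":
                    symbol = (atom.name or "").strip().upper()[:1]
                if symbol in HYDROGEN_SYMBOLS:
                    continue
                r = vdw_radius(symbol)
                ne = n_electrons(symbol)
                if r is None or ne is None:
                    logger.warning(
                        "unknown element %r in %s: using default radius %.2f Å",
                        symbol,
                        path.name,
                        DEFAULT_VDW_RADIUS,
                    )
                    r = DEFAULT_VDW_RADIUS
                    ne = DEFAULT_N_ELECTRONS
                records.append(
                    AtomRecord(
                        element=symbol,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        vdw_radius=r,
                        n_electrons=ne,
                        v_eff=_effective_volume(r, volume_scale),
                    )
                )
    if not records:
        raise ValueError(f"structure {path} contains no heavy atoms")
    return records


def _axis_frame(axis) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal frame (origin, ex, ey, ez) for an axis override.

    ``axis`` is (origin, direction); direction must be nonzero.
    """
    origin = np.asarray(axis[0], dtype=float)
    direction = np.asarray(axis[1], dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("degenerate filament axis: zero direction vector")
    ez = direction / norm
    # deterministic transverse reference: the world axis least aligned with ez
    ref = np.eye(3)[int(np.argmin(np.abs(ez)))]
    ex = ref - ez * np.dot(ref, ez)
    ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)
    return origin, ex, ey, ez


def to_scatterers(
    atoms: Sequence[AtomRecord],
    axis: tuple[Sequence[float], Sequence[float]] | None = None,
) -> ScattererSet:
    """Convert atoms to cylindrical scatterer sites about the filament axis.

    By default the filament axis is the z axis of the input frame; ``axis``
    optionally supplies (origin, direction).  Sites on the axis get psi1 = 0
    by convention.  Total weight equals the summed electron counts exactly.
    """
    if len(atoms) == 0:
        raise ValueError("cannot build a ScattererSet from zero atoms")
    xyz = np.array([a.position for a in atoms], dtype=float)
    if axis is not None:
        origin, ex, ey, ez = _axis_frame(axis)
        rel = xyz - origin
        x = rel @ ex
        y = rel @ ey
        z = rel @ ez
    else:
        x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    r0 = np.hypot(x, y)
    psi1 = np.where(r0 > 0, np.arctan2(y, x), 0.0)
    v_eff = np.array([a.v_eff for a in atoms], dtype=float)
    rs = np.cbrt(v_eff / _FOUR_THIRDS_PI)
    weight = np.array([a.n_electrons for a in atoms], dtype=float)
    return ScattererSet(r0=r0, psi1=psi1, z1=z, rs=rs, weight=weight)


# Heavy-atom element composition of a typical globular protein (fractions of
# heavy atoms); used by the synthetic monomer generator.
_PROTEIN_COMPOSITION = (("C", 0.626), ("N", 0.172), ("O", 0.192), ("S", 0.010))


def generate_synthetic_monomer(
    n_atoms: int = 2991,
    radial_extent: float = 24.0,
    axial_extent: float = 22.0,
    seed: int = 0,
    radial_offset: float = 16.2,
    volume_scale: float = 1.0,
) -> list[AtomRecord]:
    """Generate a synthetic actin-like monomer (random atom cloud fixture).

    This is a *synthetic* stand-in for a real G-actin coordinate set: a seeded
    uniform cloud inside a spheroid with semi-axes (radial_extent,
    radial_extent, axial_extent) Å, centred ``radial_offset`` Å off the
    filament axis (the actin centre-of-mass helix radius is ~16.2 Å).  The
    defaults give 2991 heavy atoms — the heavy-atom count of a G-actin
    monomer — with a typical protein element composition, at a realistic
    packing density.  Same seed, same output.

    For a cloud centred on the axis (radial_offset=0) the mean cylinder radius
    of the sites is 3*pi/16 * radial_extent (uniform-spheroid closed form).
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if radial_extent <= 0 or axial_extent <= 0:
        raise ValueError("extents must be > 0")
    rng = np.random.default_rng(seed)
    # uniform points in the unit ball, then scaled to the spheroid
    pts = np.empty((n_atoms, 3))
    n_have = 0
    while n_have < n_atoms:
        cand = rng.uniform(-1.0, 1.0, size=(2 * (n_atoms - n_have) + 16, 3))
        cand = cand[(cand**2).sum(axis=1) <= 1.0]
        take = min(len(cand), n_atoms - n_have)
        pts[n_have : n_have + take] = cand[:take]
        n_have += take
    pts[:, 0] *= radial_extent
    pts[:, 1] *= radial_extent
    pts[:, 2] *= axial_extent
    pts[:, 0] += radial_offset

    symbols = [s for s, _ in _PROTEIN_COMPOSITION]
    probs = np.array([p for _, p in _PROTEIN_COMPOSITION])
    probs = probs / probs.sum()
    elements = rng.choice(symbols, size=n_atoms, p=probs)

    records = []
    for el, pos in zip(elements, pts):
        r = vdw_radius(el)
        assert r is not None
        records.append(
            AtomRecord(
                element=el,
                position=(float(pos[0]), float(pos[1]), float(pos[2])),
                vdw_radius=r,
                n_electrons=n_electrons(el),
                v_eff=_effective_volume(r, volume_scale),
            )
        )
    return records


_TABLE_HEADER = "r0_A psi1_rad z1_A rs_A weight_e"


def write_scatterer_table(sites: ScattererSet, path: str | Path) -> None:
    """Write sites as a whitespace-delimited text table."""
    data = np.column_stack([sites.r0, sites.psi1, sites.z1, sites.rs, sites.weight])
    np.savetxt(path, data, fmt="%.10e", header=_TABLE_HEADER)


def read_scatterer_table(path: str | Path) -> ScattererSet:
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] != 5:
        raise ValueError(f"expected 5 columns in scatterer table {path}")
    return ScattererSet(
        r0=data[:, 0], psi1=data[:, 1], z1=data[:, 2], rs=data[:, 3], weight=data[:, 4]
    )
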