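"""Relaxed and piecewise-strained discontinuous-helix filaments.

A filament is m_max copies of a subunit stacked with axial spacing p0 and
azimuthal rotation dpsi0 per monomer, so every scatterer site traces a
discontinuous helix.  Crossbridge forces are transferred at *load planes*
through monomer centres; the cumulative tension T_l changes stepwise at each
plane, accumulating from the free tip toward the Z-line, and stretches each
segment's monomer spacing to

    p_l = p0 * (1 + T_l / Ka),

with Ka the filament stretch modulus (pN).  Deformation is purely axial: the
azimuthal progression is unchanged.  Axial coordinates are deformed by a
piecewise-linear strain map of the relaxed coordinates, anchored at the tip;
sites whose relaxed coordinate straddles a load plane automatically acquire
the blended intersegment spacing (the two segment strains weighted by the
site's axial offset fractions about the plane).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure import ScattererSet

__all__ = [
    "ACTIN_P0",
    "ACTIN_DPSI0",
    "ACTIN_KA",
    "HelixParams",
    "SegmentedStrainProfile",
    "DeformedFilament",
    "build_relaxed_filament",
    "build_strain_profile",
    "uniform_strain_profile",
    "classify_boundary_region",
    "apply_deformation",
    "write_strain_file",
    "read_strain_file",
]

# Actin thin-filament study conditions: 27.36 Å monomer spacing, 13 monomers
# per 6 turns (left-handed genetic helix), 364 monomers (~1 µm filament),
# stretch modulus 0.65e5 pN.
ACTIN_P0 = 27.36
ACTIN_DPSI0 = -2.0 * math.pi * 6.0 / 13.0
ACTIN_KA = 0.65e5


@dataclass(frozen=True)
class HelixParams:
    """Helical symmetry: monomer spacing p0 (Å), signed azimuthal step dpsi0
    (rad/monomer; sign = handedness), monomer count m_max."""

    p0: float = ACTIN_P0
    dpsi0: float = ACTIN_DPSI0
    m_max: int = 364

    def __post_init__(self) -> None:
        if self.p0 <= 0:
            raise ValueError("p0 must be > 0")
        if self.m_max < 1:
            raise ValueError("m_max must be >= 1")

    @property
    def pitch(self) -> float:
        """Helical pitch P0 = 2*pi*p0/|dpsi0| in Å."""
        return 2.0 * math.pi * self.p0 / abs(self.dpsi0)

    @property
    def length(self) -> float:
        """Filament length m_max*p0 in Å."""
        return self.m_max * self.p0

    @classmethod
    def actin(cls, m_max: int = 364) -> "HelixParams":
        return cls(p0=ACTIN_P0, dpsi0=ACTIN_DPSI0, m_max=m_max)


@dataclass
class SegmentedStrainProfile:
    """Piecewise-constant spacing profile of a strained filament.

    ``plane_indices`` are the monomer indices (1-based) whose centre planes
    carry the crossbridge forces; segment l (l = 1..n_segments) lies between
    planes l-1 and l and has monomer spacing ``spacings[l-1]`` covering
    ``monomer_counts[l-1]`` inter-monomer spacings.  ``plane_z`` are the
    deformed axial plane positions (Å, tip at 0) and ``plane_z_relaxed`` the
    relaxed ones used by the strain map.
    """

    p0: float
    plane_indices: np.ndarray  # (L,) int
    plane_z_relaxed: np.ndarray  # (L,)
    plane_z: np.ndarray  # (L,)
    forces: np.ndarray  # (L,) pN
    spacings: np.ndarray  # (L+1,)
    monomer_counts: np.ndarray  # (L+1,) int
    dpsi0: float = ACTIN_DPSI0

    @property
    def n_segments(self) -> int:
        return len(self.spacings)

    @property
    def strains(self) -> np.ndarray:
        return self.spacings / self.p0 - 1.0

    @property
    def segment_lengths(self) -> np.ndarray:
        """L_l = M_l * p_l in Å (deformed)."""
        return self.monomer_counts * self.spacings

    @property
    def pitches(self) -> np.ndarray:
        """Per-segment helical pitch P_l = 2*pi*p_l/|dpsi0| in Å."""
        return 2.0 * math.pi * self.spacings / abs(self.dpsi0)


@dataclass
class DeformedFilament:
    """Per-site, per-monomer coordinates of a (possibly strained) filament.

    ``z`` and ``psi`` have shape (n_sites, m_max).  For strained filaments,
    ``intersegment_spacings`` has shape (n_sites, n_planes): the one monomer
    spacing of each site's helix that straddles each load plane (NaN where the
    plane falls outside the site's monomer range).
    """

    sites: ScattererSet
    params: HelixParams
    z: np.ndarray
    psi: np.ndarray
    profile: SegmentedStrainProfile | None = None
    intersegment_spacings: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return self.sites.n_sites


def build_relaxed_filament(sites: ScattererSet, params: HelixParams) -> DeformedFilament:
    """Stack the subunit m_max times with uniform spacing p0 and twist dpsi0."""
    m = np.arange(params.m_max, dtype=float)
    z = sites.z1[:, None] + m[None, :] * params.p0
    psi = sites.psi1[:, None] + m[None, :] * params.dpsi0
    return DeformedFilament(sites=sites, params=params, z=z, psi=psi)


def build_strain_profile(
    plane_positions: Sequence[float],
    plane_forces: Sequence[float],
    p0: float = ACTIN_P0,
    Ka: float = ACTIN_KA,
    m_max: int = 364,
    dpsi0: float = ACTIN_DPSI0,
    com_offset: float = 0.0,
) -> SegmentedStrainProfile:
    """Turn load-plane positions + forces into a segmented spacing profile.

    Positions (Å from the free tip) are snapped to the nearest monomer-centre
    plane (force transfer acts through the monomer centre of mass, offset
    ``com_offset`` within the monomer); forces snapping to the same monomer
    are summed.  Cumulative tension in segment l is the sum of the forces at
    all planes between the tip and that segment's proximal boundary, so the
    most-strained segment abuts the Z-line.  Raises on a resulting
    non-positive spacing (non-physical compression).
    """
    pos = np.asarray(plane_positions, dtype=float)
    frc = np.asarray(plane_forces, dtype=float)
    if pos.shape != frc.shape:
        raise ValueError("plane_positions and plane_forces must have equal length")
    if Ka <= 0:
        raise ValueError("Ka must be > 0")
    length = m_max * p0
    if pos.size and (pos.min() < 0 or pos.max() > length):
        raise ValueError("plane positions must lie within [0, filament length]")
    if pos.size and np.any(np.diff(pos) < 0):
        raise ValueError("plane positions must be non-decreasing")

    # snap to monomer-centre planes (1-based monomer index)
    idx = np.clip(np.rint((pos - com_offset) / p0).astype(int) + 1, 1, m_max)
    uniq, inverse = np.unique(idx, return_inverse=True)
    merged_forces = np.bincount(inverse, weights=frc)

    tension = np.concatenate([[0.0], np.cumsum(merged_forces)])  # per segment
    spacings = p0 * (1.0 + tension / Ka)
    if np.any(spacings <= 0):
        raise ValueError("non-physical compression: a segment spacing is <= 0")

    counts = np.empty(len(uniq) + 1, dtype=int)
    prev = 1
    for i, j in enumerate(uniq):
        counts[i] = j - prev
        prev = j
    counts[-1] = m_max - prev

    zeta = com_offset + (uniq - 1) * p0
    plane_z = _piecewise_map(zeta, zeta, spacings / p0)
    return SegmentedStrainProfile(
        p0=p0,
        plane_indices=uniq,
        plane_z_relaxed=zeta,
        plane_z=plane_z,
        forces=merged_forces,
        spacings=spacings,
        monomer_counts=counts,
        dpsi0=dpsi0,
    )


def uniform_strain_profile(
    delta: float,
    p0: float = ACTIN_P0,
    m_max: int = 364,
    dpsi0: float = ACTIN_DPSI0,
) -> SegmentedStrainProfile:
    """Single-segment profile with uniform axial strain ``delta``."""
    spacing = p0 * (1.0 + delta)
    if spacing <= 0:
        raise ValueError("non-physical compression: spacing would be <= 0")
    empty = np.array([])
    return SegmentedStrainProfile(
        p0=p0,
        plane_indices=np.array([], dtype=int),
        plane_z_relaxed=empty,
        plane_z=empty,
        forces=empty,
        spacings=np.array([spacing]),
        monomer_counts=np.array([m_max - 1], dtype=int),
        dpsi0=dpsi0,
    )


def classify_boundary_region(
    z_site_below: float, p_l: float, epsilon: float
) -> tuple[str, int]:
    """Classify a site's axial offset from a load plane into regions i–v.

    ``z_site_below`` is the signed axial coordinate of the site relative to
    the plane.  Returns the region label and the monomer-index adjustment
    relative to the monomer just below the plane (m_{l-1}): region ii keeps
    m_{l-1} (0), iii assigns the next monomer (+1), iv the previous (-1) and
    v two back (-2); region i (within ±epsilon of the plane) keeps 0 by
    convention.
    """
    if epsilon <= 0 or p_l <= 0:
        raise ValueError("epsilon and p_l must be > 0")
    z = float(z_site_below)
    if abs(z) <= epsilon:
        return "i", 0
    if -p_l <= z < -epsilon:
        return "ii", 0
    if z < -p_l:
        return "iii", 1
    if epsilon < z <= p_l:
        return "iv", -1
    return "v", -2


def _piecewise_map(z: np.ndarray, knots: np.ndarray, slopes: np.ndarray) -> np.ndarray:
    """Evaluate the anchored piecewise-linear map D with D(0)=0.

    ``knots`` (sorted, length L) are the relaxed plane coordinates; ``slopes``
    (length L+1) are 1+strain per segment; segment l applies on
    [knots[l-1], knots[l]).
    """
    z = np.asarray(z, dtype=float)
    if knots.size == 0:
        return slopes[0] * z
    # unanchored values at knots (F(knots[0]) = 0)
    fk = np.concatenate([[0.0], np.cumsum(slopes[1:-1] * np.diff(knots))])
    seg = np.searchsorted(knots, z, side="right")
    base_knot = np.where(seg > 0, knots[np.maximum(seg - 1, 0)], knots[0])
    base_val = np.where(seg > 0, fk[np.maximum(seg - 1, 0)], 0.0)
    f = base_val + slopes[seg] * (z - base_knot)
    # anchor at z = 0
    seg0 = int(np.searchsorted(knots, 0.0, side="right"))
    if seg0 > 0:
        f0 = fk[seg0 - 1] + slopes[seg0] * (0.0 - knots[seg0 - 1])
    else:
        f0 = slopes[0] * (0.0 - knots[0])
    return f - f0


def apply_deformation(
    relaxed: DeformedFilament,
    profile: SegmentedStrainProfile,
    epsilon: float | None = None,
) -> DeformedFilament:
    """Deform a relaxed filament axially according to a segmented profile.

    Relaxed coordinates within ``epsilon`` (default 1e-6*p0) of a load plane
    are treated as lying on the plane (region i) and take the Z-side segment
    spacing.  Azimuths are unchanged.  With an all-zero strain profile the
    relaxed coordinates are returned bit-exactly.
    """
    if relaxed.profile is not None:
        raise ValueError("apply_deformation expects a relaxed (single-segment) filament")
    params = relaxed.params
    if abs(profile.p0 - params.p0) > 1e-9:
        raise ValueError("profile p0 does not match the filament's helix parameters")
    if int(profile.monomer_counts.sum()) != params.m_max - 1:
        raise ValueError("profile monomer counts do not partition this filament")
    knots = np.asarray(profile.plane_z_relaxed, dtype=float)
    if knots.size and np.any(np.diff(knots) <= 0):
        raise ValueError("overlapping load planes")
    if epsilon is None:
        epsilon = 1e-6 * params.p0

    slopes = profile.spacings / profile.p0
    n_planes = knots.size

    if np.all(profile.spacings == profile.p0):
        # exact relaxed reconstruction (bit-identical coordinates)
        spacing_rows = np.full((relaxed.n_sites, n_planes), params.p0)
        return DeformedFilament(
            sites=relaxed.sites,
            params=params,
            z=relaxed.z.copy(),
            psi=relaxed.psi.copy(),
            profile=profile,
            intersegment_spacings=spacing_rows if n_planes else None,
        )

    z_rel = relaxed.z.copy()
    if n_planes:
        # snap region-i coordinates onto their plane
        for zeta in knots:
            near = np.abs(z_rel - zeta) <= epsilon
            z_rel[near] = zeta
    z_def = _piecewise_map(z_rel.ravel(), knots, slopes).reshape(z_rel.shape)

    inter = None
    if n_planes:
        inter = np.full((relaxed.n_sites, n_planes), np.nan)
        for j, zeta in enumerate(knots):
            upper = profile.spacings[j + 1]
            for i in range(relaxed.n_sites):
                row = z_rel[i]
                k = int(np.searchsorted(row, zeta, side="left"))
                if k < row.size and row[k] == zeta:  # region i (snapped)
                    inter[i, j] = upper
                elif 0 < k < row.size:
                    inter[i, j] = z_def[i, k] - z_def[i, k - 1]

    return DeformedFilament(
        sites=relaxed.sites,
        params=params,
        z=z_def,
        psi=relaxed.psi.copy(),
        profile=profile,
        intersegment_spacings=inter,
    )


def write_strain_file(path: str | Path, positions: Sequence[float], forces: Sequence[float]) -> None:
    """Write a two-column load-plane file: position (Å), force (pN)."""
    data = np.column_stack([np.asarray(positions, float), np.asarray(forces, float)])
    np.savetxt(path, data, fmt="%.6f", header="plane_position_A force_pN")


def read_strain_file(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        return np.array([]), np.array([])
    if data.shape[1] != 2:
        raise ValueError(f"expected 2 columns in strain file {path}")
    return data[:, 0], data[:, 1]
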