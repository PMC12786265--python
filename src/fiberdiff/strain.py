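"""Stochastic crossbridge force profiles and tension normalisation.

A full spatially-explicit sarcomere Monte Carlo (with its nine-state
actomyosin kinetic cycle) is deliberately out of scope; its published rate
constants are shipped as a reference parameter file only
(``data/crossbridge_cycle_reference.yaml``).  What this module provides is a
simplified stochastic surrogate: crossbridge attachments are drawn as a
Poisson count along the filament, positions snapped to monomer-centre planes,
and per-bridge axial forces drawn from a truncated normal that admits
occasional compressive (negative) values.  The defaults (3 ± 2 pN per bridge,
floor −2 pN, 105 attachments/µm) make the mean cumulative force at the Z-line
of a ~1 µm filament ≈ 315 pN, the mean isometric per-filament force in frog
sartorius muscle; they are illustrative operating conditions, not fitted
values.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .filament import ACTIN_P0

__all__ = [
    "CrossbridgeDraw",
    "simulate_crossbridges",
    "tension_from_filament_force",
    "load_reference_cycle_parameters",
]


@dataclass
class CrossbridgeDraw:
    """One stochastic draw of crossbridge attachments along a filament."""

    plane_positions: np.ndarray  # Å from the free tip, sorted
    forces: np.ndarray  # pN per plane
    seed: int
    density: float  # attachments per µm
    force_mean: float  # pN
    force_sd: float  # pN

    @property
    def total_force(self) -> float:
        """Cumulative force reaching the Z-line (pN)."""
        return float(self.forces.sum())


def simulate_crossbridges(
    filament_length: float,
    density: float = 105.0,
    force_mean: float = 3.0,
    force_sd: float = 2.0,
    seed: int = 0,
    p0: float = ACTIN_P0,
    min_force: float = -2.0,
) -> CrossbridgeDraw:
    """Draw a random set of bound crossbridges on a filament.

    ``filament_length`` is in Å and ``density`` in attachments per µm.  The
    attachment count is Poisson(density * length); positions are uniform along
    the filament, snapped to monomer-centre planes (spacing ``p0``); forces
    are normal(force_mean, force_sd) truncated below at ``min_force`` by
    redrawing.  Deterministic for a fixed seed.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if force_sd < 0:
        raise ValueError("force_sd must be >= 0")
    rng = np.random.default_rng(seed)
    length_um = filament_length / 1e4
    count = int(rng.poisson(density * length_um))
    positions = np.sort(rng.uniform(0.0, filament_length, size=count))
    positions = np.rint(positions / p0) * p0
    if force_sd == 0:
        forces = np.full(count, force_mean)
    else:
        forces = rng.normal(force_mean, force_sd, size=count)
        bad = forces < min_force
        while np.any(bad):
            forces[bad] = rng.normal(force_mean, force_sd, size=int(bad.sum()))
            bad = forces < min_force
    return CrossbridgeDraw(
        plane_positions=positions,
        forces=forces,
        seed=seed,
        density=density,
        force_mean=force_mean,
        force_sd=force_sd,
    )


def tension_from_filament_force(
    F_a: float,
    d10: float = 36.5,
    myofibril_fraction: float = 0.83,
    thin_per_thick: int = 2,
) -> float:
    """Convert a mean per-thin-filament force to muscle tension in kPa.

    In the vertebrate hexagonal lattice there are ``thin_per_thick`` (2) thin
    filaments per thick filament, each thick filament occupying a unit-cell
    cross-section A_cell = 2*d10**2/sqrt(3) (``d10`` in nm is the (1,0)
    lattice plane spacing); ``myofibril_fraction`` is the fraction of the
    fibre cross-section occupied by myofibrils.  T = thin_per_thick *
    fraction * F_a / A_cell, returned in kPa (1 pN/nm² = 1 MPa).
    """
    if d10 <= 0 or myofibril_fraction <= 0 or thin_per_thick <= 0:
        raise ValueError("all inputs must be positive")
    if F_a < 0:
        raise ValueError("F_a must be >= 0")
    a_cell = 2.0 * d10**2 / np.sqrt(3.0)  # nm² per thick filament
    tension_mpa = thin_per_thick * myofibril_fraction * F_a / a_cell
    return float(tension_mpa * 1e3)


def load_reference_cycle_parameters() -> dict:
    """Published nine-state crossbridge-cycle constants (reference only).

    These are shipped for documentation and downstream use; the kinetic cycle
    itself is not simulated by this package.
    """
    import yaml

    text = resources.files("fiberdiff").joinpath(
        "data/crossbridge_cycle_reference.yaml"
    ).read_text()
    return yaml.safe_load(text)
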