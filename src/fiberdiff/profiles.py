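"""1D profiles and peak metrics from 2D patterns.

Meridional (axial) profiles integrate the pattern over a narrow radial window
|R| <= R_window as a function of Z; radial / layer-line profiles integrate
over a narrow axial window about Z_center as a function of R (Z_center = 0
gives the equator).  Peak position is reported as a Bragg spacing d = 1/q
(no 2*pi), width as FWHM by linear interpolation at half height, and
integrated intensity by the trapezoid rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .diffraction import DiffractionPattern

__all__ = [
    "Profile1D",
    "PeakMetrics",
    "extract_axial_profile",
    "extract_radial_profile",
    "peak_metrics",
    "normalize_profiles",
    "write_profile",
    "read_profile",
]


@dataclass
class Profile1D:
    """A 1D intensity slice.  ``axis_values`` are reciprocal coordinates
    (Å⁻¹, strictly increasing); ``kind`` is meridional / equatorial /
    layer_line."""

    axis_values: np.ndarray
    intensities: np.ndarray
    kind: str
    integration_window: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis_values = np.asarray(self.axis_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.axis_values.ndim != 1 or self.axis_values.shape != self.intensities.shape:
            raise ValueError("axis and intensities must be matching 1-D arrays")
        if np.any(np.diff(self.axis_values) <= 0):
            raise ValueError("axis values must be strictly increasing")


@dataclass
class PeakMetrics:
    """Metrics of one reflection: Bragg spacing (Å) of the maximum, FWHM
    (Å⁻¹), peak height and trapezoid-integrated intensity (a.u.)."""

    position_spacing: float
    position_q: float
    fwhm: float
    height: float
    integrated: float


def _integrate_rows(axis: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Integrate a (window, n) block along the window axis; a single-row
    window returns that row unchanged (degenerate integration)."""
    if block.shape[0] == 1:
        return block[0].copy()
    return np.trapezoid(block, x=axis, axis=0)


def extract_axial_profile(pattern: DiffractionPattern, R_window: float = 0.004) -> Profile1D:
    """Meridional profile: intensity integrated over |R| <= R_window vs Z."""
    mask = pattern.R <= R_window + 1e-15
    if not mask.any():
        raise ValueError("R_window does not cover any grid column")
    if R_window > pattern.R.max() + 1e-15:
        raise ValueError("R_window extends beyond the pattern grid")
    vals = _integrate_rows(pattern.R[mask], pattern.intensity[mask, :])
    order = np.argsort(pattern.Z)
    return Profile1D(
        axis_values=pattern.Z[order],
        intensities=vals[order],
        kind="meridional",
        integration_window=R_window,
        metadata={"lorentz_applied": pattern.lorentz_applied},
    )


def extract_radial_profile(
    pattern: DiffractionPattern,
    Z_center: float = 0.0,
    Z_window: float = 0.002,
) -> Profile1D:
    """Radial profile along a layer line: intensity integrated over
    |Z - Z_center| <= Z_window vs R.  Z_center = 0 is the equator."""
    if Z_center - Z_window < pattern.Z.min() - 1e-15 or Z_center + Z_window > pattern.Z.max() + 1e-15:
        raise ValueError("Z window extends beyond the pattern grid")
    mask = np.abs(pattern.Z - Z_center) <= Z_window + 1e-15
    if not mask.any():
        raise ValueError("Z window does not cover any grid row")
    vals = _integrate_rows(pattern.Z[mask], pattern.intensity[:, mask].T)
    kind = "equatorial" if abs(Z_center) < 1e-15 else "layer_line"
    return Profile1D(
        axis_values=pattern.R,
        intensities=vals,
        kind=kind,
        integration_window=Z_window,
        metadata={"Z_center": Z_center, "lorentz_applied": pattern.lorentz_applied},
    )


def _interp_crossing(x0, y0, x1, y1, level):
    if y1 == y0:
        return x0
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def peak_metrics(
    profile: Profile1D, search_window: tuple[float, float] | None = None
) -> PeakMetrics | None:
    """Locate the strongest peak in a coordinate window.

    Peak position is refined by a three-point parabola through the maximum;
    FWHM is found by linear interpolation at half height on both flanks (NaN
    if a flank does not fall to half height inside the window).  Returns None
    for a flat (peakless) profile.
    """
    x, y = profile.axis_values, profile.intensities
    if search_window is not None:
        lo, hi = search_window
        mask = (x >= lo) & (x <= hi)
        if not mask.any():
            raise ValueError("empty search window")
        x, y = x[mask], y[mask]
    if x.size < 1 or np.ptp(y) == 0:
        return None
    k = int(np.argmax(y))
    height = float(y[k])
    # parabolic refinement of the apex
    if 0 < k < x.size - 1 and (2 * y[k] - y[k - 1] - y[k + 1]) > 0:
        denom = y[k - 1] - 2 * y[k] + y[k + 1]
        shift = 0.5 * (y[k - 1] - y[k + 1]) / denom
        q_peak = float(x[k] + shift * (x[k + 1] - x[k - 1]) / 2.0)
    else:
        q_peak = float(x[k])
    half = height / 2.0
    left = np.nan
    for i in range(k, 0, -1):
        if y[i - 1] < half <= y[i]:
            left = _interp_crossing(x[i - 1], y[i - 1], x[i], y[i], half)
            break
    right = np.nan
    for i in range(k, x.size - 1):
        if y[i + 1] < half <= y[i]:
            right = _interp_crossing(x[i], y[i], x[i + 1], y[i + 1], half)
            break
    fwhm = float(right - left) if np.isfinite(left) and np.isfinite(right) else float("nan")
    integrated = float(np.trapezoid(y, x=x)) if x.size > 1 else height
    spacing = float(1.0 / q_peak) if q_peak != 0 else float("inf")
    return PeakMetrics(
        position_spacing=spacing,
        position_q=q_peak,
        fwhm=fwhm,
        height=height,
        integrated=integrated,
    )


def normalize_profiles(
    profiles: list[Profile1D],
    mode: str = "reference_peak",
    reference: PeakMetrics | None = None,
    r0_values: list[float] | None = None,
    r0_ref: float = 16.2,
) -> list[Profile1D]:
    """Return scaled copies of profiles.

    reference_peak: divide every profile by the reference peak height (the
    reference profile's peak becomes 1).  r0_squared: divide profile i by
    (r0_values[i]/r0_ref)**2, removing the r0² intensity scaling of the helix
    transform.  none: identity copies.
    """
    out: list[Profile1D] = []
    if mode == "none":
        factors = [1.0] * len(profiles)
    elif mode == "reference_peak":
        if reference is None or reference.height <= 0:
            raise ValueError("reference_peak mode needs a reference with height > 0")
        factors = [1.0 / reference.height] * len(profiles)
    elif mode == "r0_squared":
        if r0_values is None or len(r0_values) != len(profiles):
            raise ValueError("r0_squared mode needs one r0 per profile")
        factors = [(r0_ref / r0) ** 2 for r0 in r0_values]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    for prof, fac in zip(profiles, factors):
        out.append(
            Profile1D(
                axis_values=prof.axis_values.copy(),
                intensities=prof.intensities * fac,
                kind=prof.kind,
                integration_window=prof.integration_window,
                metadata=dict(prof.metadata, normalization=mode, factor=fac),
            )
        )
    return out


def write_profile(profile: Profile1D, path: str | Path) -> None:
    header = (
        f"kind={profile.kind} integration_window={profile.integration_window}\n"
        "coordinate_invA intensity_au"
    )
    np.savetxt(
        path,
        np.column_stack([profile.axis_values, profile.intensities]),
        fmt="%.10e",
        header=header,
    )


def read_profile(path: str | Path) -> Profile1D:
    kind = "meridional"
    window = 0.0
    with open(path) as fh:
        first = fh.readline()
    for token in first.replace("#", "").split():
        if token.startswith("kind="):
            kind = token.split("=", 1)[1]
        elif token.startswith("integration_window="):
            window = float(token.split("=", 1)[1])
    data = np.loadtxt(path, ndmin=2)
    return Profile1D(
        axis_values=data[:, 0],
        intensities=data[:, 1],
        kind=kind,
        integration_window=window,
    )


def write_metrics(metrics: PeakMetrics, path: str | Path) -> None:
    """One-row delimited record: spacing Å, FWHM Å⁻¹, height, integrated."""
    np.savetxt(
        path,
        np.array([[metrics.position_spacing, metrics.fwhm, metrics.height, metrics.integrated]]),
        fmt="%.10e",
        header="position_spacing_A fwhm_invA height_au integrated_au",
    )
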