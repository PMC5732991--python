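"""Closed-form anatomical acuity calculations for a camera-type fish eye.

The anatomical spatial resolving power (SRP) of an eye is set by the focal
geometry and the sampling density of the receptor (or ganglion-cell) lattice.
For a teleost eye with a spherical lens, the posterior nodal distance (PND)
is the lens radius times Matthiessen's ratio (~2.55 across teleosts), and the
retinal magnification is ``pi * PND / 180`` mm per degree of visual angle.

For a hexagonal receptor lattice of areal density ``D`` (cells / mm^2), the
highest spatial frequency that can be sampled without aliasing (the Nyquist
frequency, in cycles per degree) is

    f_N = (pi * PND / 360) * sqrt((2 / sqrt(3)) * D)

The reciprocal of ``f_N`` is the minimal separable angle (MSA, degrees): the
smallest angular detail the mosaic can resolve.  Twin cones may be treated as
one signalling unit (conservative density: twin + single) or as two
independent members (maximal density: 2*twin + single).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "HEX_FACTOR",
    "round_half_up",
    "MATTHIESSEN_RATIO_TELEOST",
    "OpticalModel",
    "AcuityEstimate",
    "VisualFieldSpec",
    "posterior_nodal_distance",
    "foveal_density",
    "nyquist_srp",
    "msa_deg",
    "resolvable_distance",
    "horizontal_coverage",
    "acuity_estimate",
]

#: Hexagonal-lattice correction converting areal to linear receptor density.
HEX_FACTOR = 2.0 / math.sqrt(3.0)

#: Average ratio of posterior nodal distance to lens radius in teleost eyes.
MATTHIESSEN_RATIO_TELEOST = 2.55


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Report-style decimal rounding (half away from zero, e.g. 1.785 -> 1.79).

    Quantizes the shortest decimal representation of ``value``, so products of
    decimal inputs (0.70 * 2.55 = 1.785 up to float error) round the way the
    hand calculation would.
    """
    d = Decimal(f"{value:.12g}").quantize(Decimal(1).scaleb(-ndigits),
                                          rounding=ROUND_HALF_UP)
    return float(d)


def posterior_nodal_distance(lens_radius: float,
                             matthiessen_ratio: float = MATTHIESSEN_RATIO_TELEOST) -> float:
    """Posterior nodal distance in mm: lens radius times Matthiessen's ratio.

    Full precision is retained; round only at the reporting layer.
    """
    if lens_radius <= 0 or matthiessen_ratio <= 0:
        raise ValueError("lens_radius and matthiessen_ratio must be positive")
    return lens_radius * matthiessen_ratio


def foveal_density(twin_peak: float, single_peak: float, mode: str) -> float:
    """Combined foveal receptor density (cells/mm^2) under a signalling assumption.

    mode="conservative": each twin cone signals as one unit (twin + single).
    mode="maximal": each twin member signals individually (2*twin + single).
    """
    if twin_peak < 0 or single_peak < 0:
        raise ValueError("densities must be non-negative")
    if mode == "conservative":
        return twin_peak + single_peak
    if mode == "maximal":
        return 2.0 * twin_peak + single_peak
    raise ValueError(f"unknown density mode: {mode!r}")


def nyquist_srp(pnd: float, density: float) -> float:
    """Nyquist spatial resolving power in cycles/degree for a hexagonal mosaic.

    f_N = (pi * pnd / 360) * sqrt(HEX_FACTOR * density); density in cells/mm^2,
    pnd in mm.
    """
    if pnd <= 0:
        raise ValueError("pnd must be positive")
    if density < 0:
        raise ValueError("density must be non-negative")
    return (math.pi * pnd / 360.0) * math.sqrt(HEX_FACTOR * density)


def msa_deg(nyquist: float) -> float:
    """Minimal separable angle in degrees: the reciprocal of the Nyquist frequency."""
    if nyquist <= 0:
        raise ValueError("nyquist must be positive")
    return 1.0 / nyquist


def resolvable_distance(target_size: float, msa: float, *, exact: bool = False) -> float:
    """Distance (same unit as target_size) at which a target subtends the MSA.

    Small-angle form d = size / (msa in radians); ``exact=True`` uses
    d = size / (2 tan(msa/2)), which differs by < 1e-5 relative at sub-degree
    angles.
    """
    if target_size <= 0 or msa <= 0:
        raise ValueError("target_size and msa must be positive")
    theta = math.radians(msa)
    if exact:
        return target_size / (2.0 * math.tan(theta / 2.0))
    return target_size / theta


@dataclass(frozen=True)
class OpticalModel:
    """Spherical-lens eye model: PND = lens_radius * matthiessen_ratio."""

    lens_radius: float
    matthiessen_ratio: float = MATTHIESSEN_RATIO_TELEOST

    def __post_init__(self) -> None:
        if self.lens_radius <= 0 or self.matthiessen_ratio <= 0:
            raise ValueError("lens_radius and matthiessen_ratio must be positive")

    @property
    def pnd(self) -> float:
        return posterior_nodal_distance(self.lens_radius, self.matthiessen_ratio)


@dataclass(frozen=True)
class AcuityEstimate:
    """One acuity calculation: density assumption, Nyquist limit and MSA."""

    density_mode: str
    density: float
    nyquist: float
    msa: float
    hex_factor: float = HEX_FACTOR


@dataclass(frozen=True)
class VisualFieldSpec:
    """Monocular optical field width and horizontal eye-rotation range, degrees."""

    monocular_optical_field: float
    eye_rotation_range: float

    def __post_init__(self) -> None:
        for v in (self.monocular_optical_field, self.eye_rotation_range):
            if not 0.0 <= v <= 360.0:
                raise ValueError("field angles must lie in [0, 360] degrees")


def horizontal_coverage(spec: VisualFieldSpec) -> tuple[float, float]:
    """Horizontal visual-field arithmetic for a mobile-eyed, foveate fish.

    Returns (per_eye_total, foveate_total) in degrees: an eye sweeping its
    optical field through the rotation range covers optical_field + rotation
    (capped at 360); the two foveal axes together sweep 2 * rotation.
    """
    per_eye = min(spec.monocular_optical_field + spec.eye_rotation_range, 360.0)
    foveate = min(2.0 * spec.eye_rotation_range, 360.0)
    return per_eye, foveate


def acuity_estimate(model: OpticalModel, twin_peak: float, single_peak: float,
                    mode: str) -> AcuityEstimate:
    """Run the full SRP chain for one density assumption."""
    d = foveal_density(twin_peak, single_peak, mode)
    f_n = nyquist_srp(model.pnd, d)
    return AcuityEstimate(density_mode=mode, density=d, nyquist=f_n,
                          msa=msa_deg(f_n) if f_n > 0 else math.inf)
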