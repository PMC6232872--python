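"""Two-dimensional receptor--ligand collision kinetics.

When a TRAIL-bearing liposome (riding on a leukocyte) collides with a
circulating tumor cell, ligand and receptor meet as two apposed 2D surfaces
rather than through 3D solution diffusion.  This module derives the 2D
association and dissociation rate constants for that encounter from the
encounter geometry and flow, following the Chang--Hammer treatment of
advection-enhanced surface reaction (with the Bell construction as an
independent check), plus the surface-density bookkeeping needed to express
all scenario inputs in molecules/cm^2.

Three regimes are provided:

``sheared``
    Slip velocity V = S*d between the surfaces; high-Peclet asymptotics
    Nu = 2 Pe / pi and encounter duration tau = 8a / (3 |V| pi).
``unsheared``
    No slip velocity (Pe = 0); Nu = 2 / ln(b/a) and tau = a^2 / (8 D).
``bell``
    Bell's diffusion-limited construction k_o = 2 pi D, k_off = 2 D / a^2.

In the sheared and unsheared regimes the intrinsic reactivity enters through
the dimensionless encounter duration Lambda = tau D / a^2 and the Damkohler
number delta = a^2 k_in / D: the probability that an encounter produces a
bond is P = Lambda*delta / (1 + Lambda*delta), the overall forward rate is
k_f = k_o * P, and the off-rate follows by inverting
k_f = k_o * k_in / (k_in + k_off).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .constants import AVOGADRO

__all__ = [
    "InvalidGeometryError",
    "RegimeValidityError",
    "EncounterGeometry",
    "KineticRegime",
    "SurfaceDensitySpec",
    "slip_velocity",
    "derive_sheared_regime",
    "derive_unsheared_regime",
    "derive_bell_regime",
    "liposome_surface_density",
    "cell_surface_density",
    "plasma_to_surface_density",
    "volumetric_to_areal_rate",
    "MIN_SHEARED_PECLET",
]

#: Validity floor for the high-Peclet Nusselt asymptote Nu = 2 Pe / pi.
#: The asymptote is meaningless near Pe ~ 1; the physiological case sits at
#: Pe = 5000, far above this floor.
MIN_SHEARED_PECLET = 100.0


class InvalidGeometryError(ValueError):
    """An encounter-geometry or density input is non-physical."""


class RegimeValidityError(ValueError):
    """The requested asymptotic regime does not apply to this geometry."""


def _require_positive(**values: Optional[float]) -> None:
    for name, value in values.items():
        if value is None:
            raise InvalidGeometryError(f"{name} is required for this regime")
        if not (value > 0) or not math.isfinite(value):
            raise InvalidGeometryError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class EncounterGeometry:
    """Physical parameters of one liposome--CTC encounter.

    Parameters
    ----------
    diffusivity
        Sum of the lateral diffusivities of ligand and receptor, D (cm^2/s).
    reactive_radius
        Reactive radius a of the ligand/receptor pair (cm).
    half_spacing
        Half the mean ligand--receptor spacing b (cm); only consumed by the
        unsheared regime, where it must exceed ``reactive_radius``.
    shear_rate
        Uniform shear rate S (1/s); zero for static encounters.
    center_distance
        Center-to-center distance d of the colliding cells (cm); together
        with S it sets the slip velocity V = S*d.
    intrinsic_rate
        Intrinsic forward reaction rate k_in of the apposed pair (1/s).
    """

    diffusivity: float
    reactive_radius: float
    half_spacing: Optional[float] = None
    shear_rate: float = 0.0
    center_distance: Optional[float] = None
    intrinsic_rate: Optional[float] = None

    def __post_init__(self) -> None:
        _require_positive(diffusivity=self.diffusivity, reactive_radius=self.reactive_radius)
        if self.shear_rate < 0:
            raise InvalidGeometryError("shear_rate must be >= 0")
        if self.half_spacing is not None:
            _require_positive(half_spacing=self.half_spacing)
        if self.center_distance is not None:
            _require_positive(center_distance=self.center_distance)
        if self.intrinsic_rate is not None:
            _require_positive(intrinsic_rate=self.intrinsic_rate)

    @property
    def slip_velocity(self) -> float:
        """Relative surface velocity V = S*d (cm/s)."""
        if self.center_distance is None:
            raise InvalidGeometryError("center_distance is required to form a slip velocity")
        return slip_velocity(self.shear_rate, self.center_distance)


@dataclass(frozen=True)
class KineticRegime:
    """Derived binding quantities for one transport regime.

    All rate quantities are carried at full floating-point precision;
    the printed-value comparisons in the tests round, this type never does.
    """

    regime: str                      # "sheared" | "unsheared" | "bell"
    k_o: float                       # encounter-limited on-rate, cm^2/(molecule s)
    k_off: float                     # dissociation rate, 1/s
    slip_velocity: float = 0.0       # cm/s
    peclet: float = 0.0
    nusselt: Optional[float] = None
    encounter_duration: Optional[float] = None   # tau, s
    duration_dimless: Optional[float] = None     # Lambda
    damkohler: Optional[float] = None            # delta
    binding_probability: Optional[float] = None  # P in (0, 1]
    k_f: Optional[float] = field(default=None)   # k_o * P, cm^2/(molecule s)

    def __post_init__(self) -> None:
        if self.binding_probability is not None and not (0 < self.binding_probability <= 1):
            raise ValueError("binding probability must lie in (0, 1]")
        if self.k_f is not None and self.k_f > self.k_o * (1 + 1e-9):
            raise ValueError("internal consistency: k_f exceeds k_o")
        if self.k_off < 0:
            raise ValueError("k_off must be non-negative")


@dataclass(frozen=True)
class SurfaceDensitySpec:
    """A molecule count together with the carrier geometry that turns it
    into a surface density."""

    copies: float
    area: float                 # cm^2
    density: float              # molecules/cm^2
    per_cell: Optional[float] = None  # molecules per carrier, when meaningful


def slip_velocity(shear_rate: float, center_distance: float) -> float:
    """Relative velocity V = S*d of two cell centers passing in shear.

    Parameters are the uniform shear rate S (1/s) and the center-to-center
    distance d (cm, the sum of the two cell radii).
    """
    if shear_rate < 0:
        raise InvalidGeometryError("shear_rate must be >= 0")
    _require_positive(center_distance=center_distance)
    return shear_rate * center_distance


def _close_regime(
    regime: str,
    geom: EncounterGeometry,
    *,
    k_o: float,
    tau: float,
    V: float,
    Pe: float,
    Nu: float,
) -> KineticRegime:
    """Fill in Lambda, delta, P, k_f and k_off common to both Chang--Hammer
    regimes once k_o and tau are known."""
    _require_positive(intrinsic_rate=geom.intrinsic_rate)
    D, a, k_in = geom.diffusivity, geom.reactive_radius, geom.intrinsic_rate
    lam = tau * D / a**2
    delta = a**2 * k_in / D
    lam_delta = lam * delta            # = tau * k_in
    P = lam_delta / (1.0 + lam_delta)
    k_f = k_o * P
    # invert k_f = k_o * k_in / (k_in + k_off)  =>  k_off = k_in (1/P - 1)
    k_off = k_in * (1.0 / P - 1.0)
    return KineticRegime(
        regime=regime,
        slip_velocity=V,
        peclet=Pe,
        nusselt=Nu,
        encounter_duration=tau,
        duration_dimless=lam,
        damkohler=delta,
        binding_probability=P,
        k_o=k_o,
        k_f=k_f,
        k_off=k_off,
    )


def derive_sheared_regime(geom: EncounterGeometry) -> KineticRegime:
    """Chang--Hammer rates for a sheared encounter (Pe >> 1).

    Uses Pe = V a / D, the high-Peclet asymptote Nu = 2 Pe / pi,
    k_o = pi D Nu, and encounter duration tau = 8 a / (3 |V| pi).

    Raises
    ------
    RegimeValidityError
        If the geometry's Peclet number falls below ``MIN_SHEARED_PECLET``,
        where the asymptote does not hold.
    """
    D, a = geom.diffusivity, geom.reactive_radius
    V = geom.slip_velocity
    Pe = V * a / D
    if Pe < MIN_SHEARED_PECLET:
        raise RegimeValidityError(
            f"Pe = {Pe:.3g} is below the high-Peclet validity floor "
            f"{MIN_SHEARED_PECLET:g}; the Nu = 2 Pe / pi asymptote does not apply"
        )
    Nu = 2.0 * Pe / math.pi
    k_o = math.pi * D * Nu
    tau = 8.0 * a / (3.0 * abs(V) * math.pi)
    return _close_regime("sheared", geom, k_o=k_o, tau=tau, V=V, Pe=Pe, Nu=Nu)


def derive_unsheared_regime(geom: EncounterGeometry) -> KineticRegime:
    """Chang--Hammer rates for an unsheared (Pe = 0) encounter.

    Uses Nu = 2 / ln(b/a) (natural logarithm) and tau = a^2 / (8 D),
    where b is half the mean ligand--receptor spacing.
    """
    D, a, b = geom.diffusivity, geom.reactive_radius, geom.half_spacing
    _require_positive(half_spacing=b)
    if b <= a:
        raise InvalidGeometryError(
            f"half_spacing b = {b!r} must exceed the reactive radius a = {a!r}"
        )
    Nu = 2.0 / math.log(b / a)
    k_o = math.pi * D * Nu
    tau = a**2 / (8.0 * D)
    return _close_regime("unsheared", geom, k_o=k_o, tau=tau, V=0.0, Pe=0.0, Nu=Nu)


def derive_bell_regime(geom: EncounterGeometry) -> KineticRegime:
    """Bell's diffusion-limited construction: k_o = 2 pi D, k_off = 2 D / a^2.

    Serves as an order-of-magnitude check on the unsheared Chang--Hammer
    values; Lambda, delta and P are not defined for this construction.
    """
    D, a = geom.diffusivity, geom.reactive_radius
    return KineticRegime(
        regime="bell",
        k_o=2.0 * math.pi * D,
        k_off=2.0 * D / a**2,
    )


def liposome_surface_density(copies: float, diameter: float) -> SurfaceDensitySpec:
    """Surface density of ligand on a spherical liposome.

    ``copies`` molecules spread over a sphere of the given ``diameter`` (cm):
    sigma = copies / (pi d^2).
    """
    _require_positive(copies=copies, diameter=diameter)
    area = math.pi * diameter**2
    return SurfaceDensitySpec(copies=copies, area=area, density=copies / area,
                              per_cell=copies)


def cell_surface_density(copies: float, cell_volume: float) -> SurfaceDensitySpec:
    """Surface density of receptor on a sphere-equivalent cell.

    The cell of volume V (cm^3) is treated as a sphere of radius
    r = (3V / 4 pi)^(1/3); sigma = copies / (4 pi r^2).
    """
    _require_positive(copies=copies, cell_volume=cell_volume)
    r = (3.0 * cell_volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    area = 4.0 * math.pi * r**2
    return SurfaceDensitySpec(copies=copies, area=area, density=copies / area,
                              per_cell=copies)


def plasma_to_surface_density(
    mass_conc: float,
    molar_mass: float,
    cell_volume: float,
) -> SurfaceDensitySpec:
    """Express a plasma mass concentration of soluble ligand as an effective
    cell-surface density.

    ``mass_conc`` (g/cm^3) is converted to molecules per cell volume
    (``mass_conc * N_A / molar_mass * cell_volume``) and then spread over
    the sphere-equivalent cell surface area.  A zero concentration is
    permitted (control scenario) and maps to zero density.
    """
    if mass_conc == 0:
        area = cell_surface_density(1.0, cell_volume).area
        return SurfaceDensitySpec(copies=0.0, area=area, density=0.0, per_cell=0.0)
    _require_positive(mass_conc=mass_conc, molar_mass=molar_mass, cell_volume=cell_volume)
    per_cell = mass_conc * AVOGADRO / molar_mass * cell_volume
    area = cell_surface_density(per_cell, cell_volume).area
    return SurfaceDensitySpec(copies=per_cell, area=area, density=per_cell / area,
                              per_cell=per_cell)


def volumetric_to_areal_rate(k3d: float, cell_area: float, cell_volume: float) -> float:
    """Convert a volumetric association constant (1/(M s)) to a 2D areal one
    (cm^2/(molecule s)).

    The molar constant is first made per-molecule volumetric,
    k3d * (1e3 cm^3/L) / N_A  [cm^3/(molecule s)], then multiplied by the
    cell's area-to-volume ratio so that surface densities replace volume
    concentrations.  A zero ``k3d`` maps to zero.
    """
    if k3d == 0:
        return 0.0
    _require_positive(k3d=k3d, cell_area=cell_area, cell_volume=cell_volume)
    per_molecule = k3d * 1e3 / AVOGADRO
    return per_molecule * cell_area / cell_volume
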