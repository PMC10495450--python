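"""Closed-form lumped-parameter physics of a single vessel segment.

Each arterial segment is idealised as a straight elastic cylinder of
diameter ``D`` and length ``l`` carrying fully developed laminar flow.
Two scalar properties summarise its hemodynamic behaviour:

* hydraulic (Poiseuille) resistance ``R = 128 mu l / (pi D^4)`` in
  kg m^-4 s^-1, where ``mu`` is the dynamic blood viscosity, and
* elastic compliance (volume stored per unit pressure)
  ``C = pi D^3 l / (4 G h)`` in kg^-1 m^4 s^2, where ``G`` is the
  Young's modulus of the wall and ``h`` the wall thickness.

Only the product ``G*h`` is identifiable from a compliance value, so the
two wall parameters are carried jointly as a single stiffness product in
Pa m.  All quantities are SI internally; millimetre columns of segment
tables are converted at I/O time only.

A Carreau viscosity curve is provided for shear-thinning blood rheology;
it is *not* folded into the resistance formula, which deliberately uses a
constant (infinite-shear) viscosity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VesselSegment",
    "FluidProperties",
    "WallProperties",
    "CarreauParams",
    "LumpedElement",
    "SEGMENT_GROUPS",
    "DEFAULT_BLOOD",
    "NEWTONIAN_BLOOD",
    "CARREAU_BLOOD",
    "GH_DEFAULTS",
    "poiseuille_resistance",
    "elastic_compliance",
    "calibrate_stiffness_product",
    "carreau_viscosity",
]

#: Recognised subtree tags for a vessel segment.
SEGMENT_GROUPS = ("ica-distal", "eca-distal", "ophthalmic", "proximal")


def _require_positive(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")
    return value


@dataclass(frozen=True)
class VesselSegment:
    """Geometry record for one vessel branch.

    Parameters are stored in SI units (metres).  ``multiplicity`` counts
    identical parallel copies of the segment (perforator bundles are
    tallied fractionally, e.g. 7.6); it is pure metadata here and is
    consumed only during network reduction.
    """

    label: str
    name: str
    diameter: float  # m
    length: float  # m
    multiplicity: float = 1.0
    group: str = "proximal"

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("label must be a non-empty string")
        _require_positive(self.diameter, f"{self.label}: diameter")
        _require_positive(self.length, f"{self.label}: length")
        _require_positive(self.multiplicity, f"{self.label}: multiplicity")
        if self.group not in SEGMENT_GROUPS:
            raise ValueError(
                f"{self.label}: unknown group {self.group!r}; expected one of {SEGMENT_GROUPS}"
            )

    @classmethod
    def from_mm(
        cls,
        label: str,
        name: str,
        diameter_mm: float,
        length_mm: float,
        multiplicity: float = 1.0,
        group: str = "proximal",
    ) -> "VesselSegment":
        """Build a segment from millimetre geometry (the tabulated units)."""
        return cls(label, name, float(diameter_mm) * 1e-3, float(length_mm) * 1e-3,
                   multiplicity, group)


@dataclass(frozen=True)
class FluidProperties:
    """Bulk blood properties: dynamic viscosity (Pa s) and density (kg/m^3).

    Density is carried for documentation of simulator runs; the lumped
    resistance/compliance formulas use viscosity only.
    """

    viscosity: float = 0.0035
    density: float = 1060.0

    def __post_init__(self) -> None:
        _require_positive(self.viscosity, "viscosity")
        _require_positive(self.density, "density")


#: Default blood used for atlas reproduction (infinite-shear Carreau value).
DEFAULT_BLOOD = FluidProperties(viscosity=0.0035, density=1060.0)

#: Alternative Newtonian viscosity quoted for simplified CFD set-ups.
NEWTONIAN_BLOOD = FluidProperties(viscosity=0.004, density=1060.0)


@dataclass(frozen=True)
class WallProperties:
    """Elastic wall description via the stiffness product ``G*h`` (Pa m)."""

    stiffness_product: float

    def __post_init__(self) -> None:
        _require_positive(self.stiffness_product, "stiffness_product")


#: Per-subtree default stiffness products (Pa m), the medians obtained by
#: inverting the atlas's reference compliances subtree by subtree.
GH_DEFAULTS = {
    "ica-distal": 2700.0,
    "eca-distal": 2333.0,
    "ophthalmic": 23400.0,
    "proximal": 2700.0,
}


@dataclass(frozen=True)
class CarreauParams:
    """Carreau shear-thinning parameters.

    mu(gdot) = mu_inf + (mu_0 - mu_inf) * (1 + (lambda*gdot)^2)^((n-1)/2)
    """

    time_constant: float = 3.313  # s
    power_index: float = 0.3568
    zero_shear_viscosity: float = 0.056  # Pa s
    inf_shear_viscosity: float = 0.0035  # Pa s

    def __post_init__(self) -> None:
        _require_positive(self.time_constant, "time_constant")
        _require_positive(self.power_index, "power_index")
        _require_positive(self.zero_shear_viscosity, "zero_shear_viscosity")
        _require_positive(self.inf_shear_viscosity, "inf_shear_viscosity")
        if self.zero_shear_viscosity < self.inf_shear_viscosity:
            raise ValueError(
                "zero_shear_viscosity must be >= inf_shear_viscosity"
            )


#: Carreau blood rheology used by the patient-specific simulations.
CARREAU_BLOOD = CarreauParams()


@dataclass(frozen=True)
class LumpedElement:
    """Paired hydraulic resistance and compliance of a segment or subtree."""

    resistance: float  # kg m^-4 s^-1
    compliance: float  # kg^-1 m^4 s^2

    def __post_init__(self) -> None:
        for attr in ("resistance", "compliance"):
            v = getattr(self, attr)
            if not math.isfinite(v) or v < 0.0:
                raise ValueError(f"{attr} must be finite and >= 0, got {v!r}")


def poiseuille_resistance(segment: VesselSegment, fluid: FluidProperties = DEFAULT_BLOOD) -> float:
    """Hydraulic resistance of a *single* copy of ``segment``.

    R = 128 mu l / (pi D^4), in kg m^-4 s^-1.  Multiplicity is ignored
    here; parallel copies are accounted for during network reduction.
    """
    return 128.0 * fluid.viscosity * segment.length / (math.pi * segment.diameter ** 4)


def elastic_compliance(segment: VesselSegment, wall: WallProperties) -> float:
    """Elastic compliance of a single copy of ``segment``.

    C = pi D^3 l / (4 G h), in kg^-1 m^4 s^2, for a thin-walled elastic
    tube with stiffness product ``G*h``.
    """
    return (
        math.pi * segment.diameter ** 3 * segment.length
        / (4.0 * wall.stiffness_product)
    )


def calibrate_stiffness_product(
    diameter: float, length: float, target_compliance: float
) -> float:
    """Invert the compliance formula for the wall stiffness product.

    Given geometry (SI metres) and a known compliance, returns the
    ``G*h`` value (Pa m) that reproduces it:  Gh = pi D^3 l / (4 C).
    The round trip through :func:`elastic_compliance` recovers the
    target compliance to machine precision.
    """
    diameter = _require_positive(diameter, "diameter")
    length = _require_positive(length, "length")
    target_compliance = _require_positive(target_compliance, "target_compliance")
    return math.pi * diameter ** 3 * length / (4.0 * target_compliance)


def carreau_viscosity(shear_rate, params: CarreauParams = CARREAU_BLOOD):
    """Effective Carreau viscosity at the given shear rate(s) (1/s).

    Accepts scalars or arrays; monotonically non-increasing in shear rate.
    """
    gdot = np.asarray(shear_rate, dtype=float)
    if np.any(gdot < 0) or not np.all(np.isfinite(gdot)):
        raise ValueError("shear_rate must be finite and >= 0")
    mu0 = params.zero_shear_viscosity
    mu_inf = params.inf_shear_viscosity
    lam = params.time_constant
    n = params.power_index
    mu = mu_inf + (mu0 - mu_inf) * (1.0 + (lam * gdot) ** 2) ** ((n - 1.0) / 2.0)
    if np.ndim(shear_rate) == 0:
        return float(mu)
    return mu
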