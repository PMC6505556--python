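"""Cross-sections, bulbs, materials and the assembled haltere model.

The haltere is idealised as a slender cantilever stalk (length ``x_d`` to the
bulb centre of mass) carrying a rigid end bulb.  Two stalk profiles are
supported: a hollow circular tube ("CS") and a plus-sign open section ("PS")
built from two orthogonal rectangles.  The two profiles are designed so that
the bending second moment of area ``I`` matches while the Saint-Venant
torsion constant ``J`` differs by more than an order of magnitude, which is
what makes the open section torsionally compliant.

All geometric inputs are micrometres; SI conversion happens when the finite
element system is assembled (:mod:`haltere.structure`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "InvalidGeometryError",
    "CrossSection",
    "MaterialSpec",
    "BulbSpec",
    "HaltereModel",
    "annulus_section",
    "plus_section",
    "equal_volume_ellipsoid",
    "bulb_properties",
    "match_second_moment",
]

UM = 1e-6  # metres per micrometre


class InvalidGeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric input."""


@dataclass(frozen=True)
class CrossSection:
    """Stalk cross-section with derived stiffness properties (μm units).

    Attributes
    ----------
    kind : str
        ``"annulus"`` or ``"plus"``.
    area : float
        Cross-sectional area, μm².
    I_y, I_z : float
        Second moments of area about the two transverse axes, μm⁴.
    J : float
        Saint-Venant torsion constant, μm⁴.
    c : float
        Outer fibre distance from the neutral axis, μm (strain recovery
        radius).
    dims : dict
        The defining dimensions.
    """

    kind: str
    area: float
    I_y: float
    I_z: float
    J: float
    c: float
    dims: dict = field(default_factory=dict)

    @property
    def I_polar(self) -> float:
        """Polar second moment of area I_y + I_z (μm⁴), used for the
        distributed rotary inertia of the stalk in torsion."""
        return self.I_y + self.I_z


def annulus_section(r_out: float, r_in: float) -> CrossSection:
    """Hollow circular section (outer radius ``r_out``, inner ``r_in``, μm).

    For a circular tube the torsion constant equals the polar moment,
    ``J = 2 I``.
    """
    if r_in < 0 or r_out <= r_in:
        raise InvalidGeometryError(
            f"annulus requires r_out > r_in >= 0, got ({r_out}, {r_in})"
        )
    area = math.pi * (r_out**2 - r_in**2)
    I = math.pi / 4.0 * (r_out**4 - r_in**4)
    return CrossSection(
        kind="annulus",
        area=area,
        I_y=I,
        I_z=I,
        J=2.0 * I,
        c=r_out,
        dims={"r_out": r_out, "r_in": r_in},
    )


def _rect_torsion_coeff(aspect_ratio: float) -> float:
    # Saint-Venant torsion of a single slender rectangle (membrane analogy):
    # J = k(h/t) * h * t^3, k -> 1/3 as h/t -> inf.
    return (1.0 / 3.0) * (1.0 - 0.63 / aspect_ratio + 0.052 / aspect_ratio**5)


def plus_section(h: float, t: float) -> CrossSection:
    """Plus-sign section from two orthogonal ``h`` x ``t`` rectangles (μm).

    The central t x t overlap is physically a single piece of material, so
    its area and second moment are counted once.  The torsion constant uses
    the thin open-section Saint-Venant result per rectangle with the
    finite-aspect-ratio correction; junction effects at the cross centre are
    neglected (checked against a Prandtl stress-function solution in the
    test suite).
    """
    if t <= 0 or h <= t:
        raise InvalidGeometryError(f"plus section requires h > t > 0, got ({h}, {t})")
    area = 2.0 * h * t - t**2
    # vertical limb (1/12) t h^3 + horizontal limb (1/12) h t^3 - overlap once
    I = (t * h**3 + h * t**3 - t**4) / 12.0
    J = 2.0 * _rect_torsion_coeff(h / t) * h * t**3
    return CrossSection(
        kind="plus",
        area=area,
        I_y=I,
        I_z=I,
        J=J,
        c=h / 2.0,
        dims={"h": h, "t": t},
    )


def equal_volume_ellipsoid(sphere_radius: float, semi_major: float) -> float:
    """Semi-minor axis ``b`` of a prolate spheroid with semi-major axis
    ``semi_major`` whose volume equals that of a sphere of ``sphere_radius``.

    Solves a·b² = r³.  Units are whatever the inputs are (μm here).
    """
    if sphere_radius <= 0 or semi_major <= 0:
        raise InvalidGeometryError("radii must be positive")
    return math.sqrt(sphere_radius**3 / semi_major)


def match_second_moment(aspect_ratio: float, target_I: float) -> tuple[float, float]:
    """Dimensions ``(h, t)`` of a plus section with ``h/t = aspect_ratio``
    whose second moment of area equals ``target_I`` (μm⁴).

    ``I`` is monotone increasing in ``h`` at fixed aspect ratio (I ∝ h⁴), so
    the root is bracketed and found by Brent's method.
    """
    if aspect_ratio <= 1 or target_I <= 0:
        raise InvalidGeometryError("need aspect_ratio > 1 and target_I > 0")

    def f(hh: float) -> float:
        return plus_section(hh, hh / aspect_ratio).I_y - target_I

    lo, hi = 1e-6, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("no root in bracket for match_second_moment")
    h = brentq(f, lo, hi, xtol=1e-10, rtol=1e-14)
    return h, h / aspect_ratio


@dataclass(frozen=True)
class MaterialSpec:
    """Linear elastic isotropic material (SI units).

    Defaults are nanoindentation-derived cuticle values: E = 1.5 GPa,
    ρ = 1200 kg m⁻³, ν = 0.33.
    """

    E: float = 1.5e9
    rho: float = 1200.0
    nu: float = 0.33

    def __post_init__(self) -> None:
        if self.E <= 0 or self.rho <= 0 or not (0.0 < self.nu < 0.5):
            raise InvalidGeometryError("material constants out of range")

    @property
    def G(self) -> float:
        """Shear modulus E / (2(1+ν)), Pa."""
        return self.E / (2.0 * (1.0 + self.nu))


@dataclass(frozen=True)
class BulbSpec:
    """Rigid end bulb: a (possibly offset) solid ellipsoid.

    ``semi_axes`` are the semi-axes (a_x, a_y, a_z) in μm along the local
    spanwise / lateral / stroke-plane axes; ``offset`` is the centre-of-mass
    offset (Δy′, Δz′) in μm relative to the stalk tip node.  Density is
    kg m⁻³.
    """

    semi_axes: tuple[float, float, float] = (500.0, 500.0, 500.0)
    offset: tuple[float, float] = (0.0, 0.0)
    density: float = 1200.0

    @classmethod
    def sphere(cls, radius: float, density: float = 1200.0,
               offset: tuple[float, float] = (0.0, 0.0)) -> "BulbSpec":
        return cls((radius, radius, radius), offset, density)

    @property
    def volume_m3(self) -> float:
        a, b, c = (s * UM for s in self.semi_axes)
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def mass(self) -> float:
        """Bulb mass, kg."""
        return self.volume_m3 * self.density

    @property
    def inertia_com(self) -> np.ndarray:
        """Inertia tensor about the centre of mass, kg m² (principal axes
        aligned with the local frame)."""
        m = self.mass
        a, b, c = (s * UM for s in self.semi_axes)
        return np.diag(
            [m / 5.0 * (b**2 + c**2), m / 5.0 * (a**2 + c**2), m / 5.0 * (a**2 + b**2)]
        )

    @property
    def offset_m(self) -> np.ndarray:
        """COM offset vector (0, Δy′, Δz′) in metres."""
        return np.array([0.0, self.offset[0] * UM, self.offset[1] * UM])


def bulb_properties(spec: BulbSpec) -> tuple[float, np.ndarray, np.ndarray]:
    """(mass kg, COM offset vector μm, inertia tensor about COM kg m²)."""
    off = np.array([0.0, spec.offset[0], spec.offset[1]])
    return spec.mass, off, spec.inertia_com


@dataclass(frozen=True)
class HaltereModel:
    """Full haltere: stalk geometry + material + rigid bulb + discretisation.

    ``length`` is the distance x_d from the clamped base to the bulb centre
    of mass (μm).  The stalk is meshed with ``n_el`` equal beam elements
    spanning [0, x_d]; the bulb is attached at the distal node through a
    rigid offset.
    """

    length: float = 5000.0
    section: CrossSection = field(default_factory=lambda: annulus_section(150.0, 50.0))
    material: MaterialSpec = field(default_factory=MaterialSpec)
    bulb: BulbSpec = field(default_factory=BulbSpec)
    n_el: int = 31

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvalidGeometryError("stalk length must be positive")
        if self.n_el < 4:
            raise InvalidGeometryError("need at least 4 stalk elements")

    @property
    def length_m(self) -> float:
        return self.length * UM

    @property
    def stalk_mass(self) -> float:
        """Stalk mass, kg."""
        return self.section.area * 1e-12 * self.length_m * self.material.rho
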