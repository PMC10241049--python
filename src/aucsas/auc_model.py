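"""Hydrodynamic conversions of analytical-ultracentrifugation observables.

Sedimentation-velocity AUC resolves a protein solution into species with
sedimentation coefficients s_20,w (Svedberg) and a shared frictional ratio
f/f0.  This module converts those observables into the quantities the
monomer-profile reconstruction needs:

* the molar mass of each species, via the Svedberg/Stokes-Einstein relation
  for a sphere of equal mass inflated by the frictional ratio;
* integer association numbers (j-mer assignment) by mass ratio;
* the bare shape anisotropy (prolate axial ratio p) hidden inside f/f0,
  obtained by stripping a hydration layer and inverting the Perrin
  translational friction factor.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .sas_io import SpeciesDistribution

logger = logging.getLogger(__name__)

#: Avogadro's number, mol^-1 (CODATA 2018 exact).
AVOGADRO = 6.02214076e23

#: Viscosity of water at 293 K, poise.
WATER_VISCOSITY_20C = 0.01002

#: Density of water at 293 K, g cm^-3.
WATER_DENSITY_20C = 0.99823

#: 1 Svedberg in seconds.
SVEDBERG = 1e-13

#: Default hydration, g water per g protein (textbook value for proteins).
DEFAULT_HYDRATION = 0.3


@dataclass(frozen=True)
class SolventConditions:
    """Solvent and solute constants entering the Svedberg mass relation.

    Parameters
    ----------
    vbar : float
        Partial specific volume of the solute, cm^3 g^-1.
    eta : float
        Solvent viscosity at the reference condition (water, 293 K), poise.
    rho : float
        Solvent density at the reference condition, g cm^-3.
    temperature : float
        Kelvin; informational only, because s values are assumed already
        normalized to s_20,w upstream.
    """

    vbar: float = 0.735
    eta: float = WATER_VISCOSITY_20C
    rho: float = WATER_DENSITY_20C
    temperature: float = 293.0

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.rho <= 0:
            raise ValueError("viscosity and density must be positive")
        if self.vbar * self.rho >= 1.0:
            raise ValueError(
                "vbar*rho >= 1: particle would not sediment (buoyancy term "
                "1 - vbar*rho must be positive)"
            )


@dataclass(frozen=True)
class SubunitShape:
    """Ellipsoid-of-revolution model of the monomer (subunit of an aggregate).

    Semi-axes are ``semi_axis`` (twice, equatorial) and
    ``axial_ratio * semi_axis`` (polar), so ``axial_ratio`` >= 1 is prolate.
    The gyration radius satisfies rg^2 = r^2 (2 + p^2) / 5.
    """

    axial_ratio: float
    semi_axis: float

    def __post_init__(self) -> None:
        if self.axial_ratio <= 0 or self.semi_axis <= 0:
            raise ValueError("axial_ratio and semi_axis must be positive")

    @property
    def rg(self) -> float:
        """Gyration radius of the ellipsoid, Angstrom."""
        return self.semi_axis * math.sqrt((2.0 + self.axial_ratio**2) / 5.0)

    @classmethod
    def from_rg(cls, rg: float, axial_ratio: float) -> "SubunitShape":
        """Shape of given gyration radius: r = rg * sqrt(5 / (2 + p^2))."""
        if rg <= 0:
            raise ValueError("rg must be positive")
        r = rg * math.sqrt(5.0 / (2.0 + axial_ratio**2))
        return cls(axial_ratio=axial_ratio, semi_axis=r)


def molar_mass_from_sedimentation(
    s20w: float, friction_ratio: float, solvent: SolventConditions
) -> float:
    """Molar mass (g/mol) of a species from s_20,w and f/f0.

    Combines the Svedberg equation s = M(1 - vbar*rho)/(N_A f) with the
    Stokes friction f = 6*pi*eta*R_s of a sphere of radius
    R_s = (f/f0)*(3 M vbar / 4 pi N_A)^(1/3) and solves for M in closed
    form:

        M = [ s*(f/f0)*6*pi*eta*(3*vbar/(4*pi))^(1/3)*N_A^(2/3)
              / (1 - vbar*rho) ]^(3/2)

    with s in CGS seconds.  M is homogeneous of degree 3/2 in both s and
    f/f0.
    """
    if s20w <= 0:
        raise ValueError("sedimentation coefficient must be positive")
    if friction_ratio < 1.0:
        raise ValueError("frictional ratio must be >= 1")
    s_cgs = s20w * SVEDBERG
    base = (
        s_cgs
        * friction_ratio
        * 6.0
        * math.pi
        * solvent.eta
        * (3.0 * solvent.vbar / (4.0 * math.pi)) ** (1.0 / 3.0)
        * AVOGADRO ** (2.0 / 3.0)
        / (1.0 - solvent.vbar * solvent.rho)
    )
    return base**1.5


def sedimentation_from_molar_mass(
    molar_mass: float, friction_ratio: float, solvent: SolventConditions
) -> float:
    """Inverse of :func:`molar_mass_from_sedimentation`: s_20,w in Svedberg.

    Forward Svedberg relation for a particle of mass ``molar_mass`` whose
    Stokes radius is (f/f0) times the equal-mass anhydrous sphere radius.
    Used by the synthetic generator to emit species tables consistent with
    its ground truth.
    """
    r0 = (3.0 * molar_mass * solvent.vbar / (4.0 * math.pi * AVOGADRO)) ** (
        1.0 / 3.0
    )
    f = 6.0 * math.pi * solvent.eta * friction_ratio * r0
    s_cgs = molar_mass * (1.0 - solvent.vbar * solvent.rho) / (AVOGADRO * f)
    return s_cgs / SVEDBERG


def assign_association_numbers(
    distribution: SpeciesDistribution,
    solvent: SolventConditions,
) -> SpeciesDistribution:
    """Fill molar masses and integer j-mer assignments for every species.

    Masses come from :func:`molar_mass_from_sedimentation`; the association
    number is round(M_j / M_1), clipped to >= 1.  The method's
    applicability prerequisites are checked here and reported as warnings,
    never as errors: aggregates should be tetramer at most and the total
    aggregate weight fraction r_a = 1 - r_1 below 0.2, otherwise the sample
    would normally be re-purified.

    Idempotent: reassigning an already-assigned distribution is a no-op.
    """
    masses = [
        molar_mass_from_sedimentation(sp.s20w, distribution.friction_ratio, solvent)
        for sp in distribution.species
    ]
    m1 = masses[0]
    new_species = []
    for sp, m in zip(distribution.species, masses):
        j = max(1, round(m / m1))
        new_species.append(replace(sp, molar_mass=m, association_number=j))
    out = SpeciesDistribution(
        species=new_species, friction_ratio=distribution.friction_ratio
    )
    jmax = max(sp.association_number for sp in out.species)
    if jmax > 4:
        warnings.warn(
            f"largest association number j={jmax} exceeds the method's "
            "prerequisite (aggregates assumed tetramer at most); results "
            "may be unreliable",
            stacklevel=2,
        )
    ra = out.aggregate_fraction
    if ra > 0.2:
        warnings.warn(
            f"aggregate weight fraction r_a={ra:.3f} exceeds the 0.2 "
            "prerequisite; the sample should be re-purified",
            stacklevel=2,
        )
    return out


def perrin_factor(p: float) -> float:
    """Perrin translational friction factor F_P(p) of a prolate ellipsoid.

    Ratio of the friction of an ellipsoid of revolution with semi-axes
    (p*r, r, r), p >= 1, to that of the equal-volume sphere:

        F_P(p) = p^(-1/3) * sqrt(p^2 - 1) / ln(p + sqrt(p^2 - 1))

    F_P(1) = 1.  Strictly increasing on p > 1.
    """
    if p < 1.0:
        raise ValueError("prolate convention requires p >= 1")
    if p == 1.0:
        return 1.0
    ecc = math.sqrt(p * p - 1.0)
    return p ** (-1.0 / 3.0) * ecc / math.log(p + ecc)


def perrin_factor_oblate(p: float) -> float:
    """Perrin factor for an oblate ellipsoid with semi-axes (r/p, r, r), p>=1.

        F_P(p) = p^(1/3) * sqrt(p^2 - 1) / (p * atan(sqrt(p^2 - 1)))
    """
    if p < 1.0:
        raise ValueError("oblate convention requires p >= 1")
    if p == 1.0:
        return 1.0
    ecc = math.sqrt(p * p - 1.0)
    return p ** (1.0 / 3.0) * ecc / (p * math.atan(ecc))


_P_MAX = 100.0


def axial_ratio_from_friction(
    friction_ratio: float,
    hydration: float = DEFAULT_HYDRATION,
    solvent: SolventConditions | None = None,
    oblate: bool = False,
) -> float:
    """Bare shape axial ratio p from the measured frictional ratio.

    The experimental f/f0 mixes hydration and shape.  The hydration
    contribution is stripped first,

        (f/f0)_shape = (f/f0) / (1 + delta/(vbar*rho))^(1/3),

    with ``hydration`` = delta in g water per g protein, and the remaining
    shape factor is inverted through the Perrin function by bracketed root
    finding on p in [1+1e-6, 100].  Returns p = 1 whenever the stripped
    ratio does not exceed 1 (sphere; hydration accounts for everything).
    """
    if friction_ratio < 1.0:
        raise ValueError("frictional ratio must be >= 1")
    if hydration < 0:
        raise ValueError("hydration must be >= 0")
    solvent = solvent or SolventConditions()
    shape = friction_ratio / (1.0 + hydration / (solvent.vbar * solvent.rho)) ** (
        1.0 / 3.0
    )
    if shape <= 1.0:
        return 1.0
    fp = perrin_factor_oblate if oblate else perrin_factor
    if shape > fp(_P_MAX):
        raise ValueError(
            f"(f/f0)_shape = {shape:.3f} exceeds the Perrin factor of a "
            f"{_P_MAX:.0f}:1 ellipsoid; re-examine f/f0, hydration or vbar"
        )
    return brentq(lambda p: fp(p) - shape, 1.0 + 1e-6, _P_MAX, xtol=1e-12)


def friction_from_axial_ratio(
    p: float,
    hydration: float = DEFAULT_HYDRATION,
    solvent: SolventConditions | None = None,
) -> float:
    """Forward map: measured f/f0 of a hydrated prolate ellipsoid of ratio p."""
    solvent = solvent or SolventConditions()
    return perrin_factor(p) * (
        1.0 + hydration / (solvent.vbar * solvent.rho)
    ) ** (1.0 / 3.0)
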