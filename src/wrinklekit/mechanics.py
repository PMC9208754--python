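"""Buckling-delamination mechanics of an adherent, growing elastic film.

A biofilm growing in a confined microchannel builds up equi-biaxial
compressive stress sigma. Above a critical stress the film buckles away from
the substrate over a circular delaminated blister of radius R,

    sigma_c = 1.2235 * E_f / (1 - nu_f**2) * (h / R)**2,

and the subsequent growth of the blister is governed by the interface-crack
energy release rate G relative to the elastic energy per unit area stored in
the unbuckled film, G0 = (1 - nu_f) * h * sigma**2 / E_f:

    G / G0 = c2 * (1 - (sigma_c / sigma)**2),   c2 = 1 / (1 + 0.9021 * (1 - nu_f)).

The crack advances only while G exceeds the interface toughness Gamma, which
is proportional to the film-substrate adhesive strength. The module also
provides the parallel-plate hydrodynamics (mean velocity, wall shear stress)
of the rectangular growth channel.

All quantities are SI internally. The literature shear-modulus magnitude
(~1000 Pa for P. aeruginosa biofilms) is conventionally plugged in directly
as ``youngs_modulus``; the model exposes it as a plain parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

BUCKLING_COEFF = 1.2235  #: prefactor of the circular-blister buckling criterion
MODE_MIX_COEFF = 0.9021  #: coefficient in c2 = 1 / (1 + 0.9021 (1 - nu))


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


@dataclass(frozen=True)
class ElasticFilm:
    """Isotropic elastic film: Young's modulus E_f (Pa), Poisson ratio nu_f, thickness h (m)."""

    youngs_modulus: float
    poisson_ratio: float
    thickness: float

    def __post_init__(self) -> None:
        _require(self.youngs_modulus > 0, f"youngs_modulus must be > 0, got {self.youngs_modulus}")
        _require(0 <= self.poisson_ratio < 0.5, f"poisson_ratio must be in [0, 0.5), got {self.poisson_ratio}")
        _require(self.thickness > 0, f"thickness must be > 0, got {self.thickness}")


@dataclass(frozen=True)
class Blister:
    """Circular delaminated region of radius R (m)."""

    radius: float

    def __post_init__(self) -> None:
        _require(self.radius > 0, f"radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class StressState:
    """Uniform equi-biaxial compressive stress sigma (Pa, magnitude)."""

    compressive_stress: float

    def __post_init__(self) -> None:
        _require(self.compressive_stress >= 0, f"compressive_stress must be >= 0, got {self.compressive_stress}")


@dataclass(frozen=True)
class InterfaceToughness:
    """Resistance Gamma (J m^-2) to interface-crack propagation.

    ``mode_mix_angle`` (radians) is descriptive metadata only: the deformation
    mode stays essentially constant during delamination, so no functional
    dependence Gamma(psi) is modelled.
    """

    toughness: float
    mode_mix_angle: float | None = None

    def __post_init__(self) -> None:
        _require(self.toughness >= 0, f"toughness must be >= 0, got {self.toughness}")


@dataclass(frozen=True)
class ChannelFlow:
    """Rectangular-channel flow: width, height (m), flow rate (m^3 s^-1), viscosity (Pa s)."""

    width: float
    height: float
    flow_rate: float
    viscosity: float

    def __post_init__(self) -> None:
        _require(self.width > 0, f"width must be > 0, got {self.width}")
        _require(self.height > 0, f"height must be > 0, got {self.height}")
        _require(self.flow_rate >= 0, f"flow_rate must be >= 0, got {self.flow_rate}")
        _require(self.viscosity > 0, f"viscosity must be > 0, got {self.viscosity}")


class Verdict(str, Enum):
    GROWS = "grows"
    ARRESTED = "arrested"


def critical_stress(film: ElasticFilm, blister: Blister) -> float:
    """Critical compressive stress (Pa) for the film to buckle away over the blister.

    Scales linearly with the modulus and quadratically with h/R: halving the
    blister radius quadruples the stress needed to buckle.
    """
    return (
        BUCKLING_COEFF
        * film.youngs_modulus
        / (1.0 - film.poisson_ratio**2)
        * (film.thickness / blister.radius) ** 2
    )


def baseline_energy_release(film: ElasticFilm, stress: StressState) -> float:
    """Elastic energy per unit area (J m^-2) stored in the unbuckled film.

    G0 = (1 - nu_f) h sigma^2 / E_f; the upper bound that the crack driving
    force G approaches at large stress.
    """
    return (
        (1.0 - film.poisson_ratio)
        * film.thickness
        * stress.compressive_stress**2
        / film.youngs_modulus
    )


def mode_mix_factor(poisson_ratio: float) -> float:
    """c2 = 1 / (1 + 0.9021 (1 - nu_f)), the large-stress asymptote of G/G0."""
    _require(0 <= poisson_ratio < 0.5, f"poisson_ratio must be in [0, 0.5), got {poisson_ratio}")
    return 1.0 / (1.0 + MODE_MIX_COEFF * (1.0 - poisson_ratio))


@dataclass(frozen=True)
class EnergyReleaseRatio:
    """Normalized crack driving force G/G0 with an unbuckled-state flag."""

    ratio: float
    buckled: bool


def normalized_energy_release(
    stress: StressState, critical: float, poisson_ratio: float
) -> EnergyReleaseRatio:
    """G/G0 = c2 (1 - (sigma_c/sigma)^2) for sigma >= sigma_c.

    Below the critical stress the film is unbuckled and the energy release
    rate of the interface crack is zero; this is a distinct physical state and
    is returned as ``EnergyReleaseRatio(0.0, buckled=False)`` rather than an
    error, so sweeps over a growing stress history are convenient.
    """
    _require(critical > 0, f"critical stress must be > 0, got {critical}")
    sigma = stress.compressive_stress
    if sigma < critical:
        return EnergyReleaseRatio(0.0, buckled=False)
    c2 = mode_mix_factor(poisson_ratio)
    return EnergyReleaseRatio(c2 * (1.0 - (critical / sigma) ** 2), buckled=True)


def delamination_verdict(g: float, toughness: InterfaceToughness) -> Verdict:
    """``grows`` iff the crack driving force G strictly exceeds Gamma, else ``arrested``."""
    _require(g >= 0, f"energy release rate must be >= 0, got {g}")
    return Verdict.GROWS if g > toughness.toughness else Verdict.ARRESTED


def min_buckling_radius(film: ElasticFilm, stress: StressState) -> float:
    """Smallest blister radius (m) that buckles at the given stress.

    Inverse of :func:`critical_stress` in R: blisters larger than this radius
    have a critical stress below ``stress``. Zero stress cannot buckle any
    finite blister, so the radius is infinite.
    """
    sigma = stress.compressive_stress
    if sigma == 0:
        return math.inf
    return film.thickness * math.sqrt(
        BUCKLING_COEFF * film.youngs_modulus / ((1.0 - film.poisson_ratio**2) * sigma)
    )


def mean_velocity(flow: ChannelFlow) -> float:
    """Cross-section-averaged velocity U = Q / (w h) in m s^-1."""
    return flow.flow_rate / (flow.width * flow.height)


def wall_shear_stress(flow: ChannelFlow) -> float:
    """Average wall shear stress tau = 6 mu U / h (Pa).

    Uses the laminar infinite-parallel-plate profile, adequate for the 5:1
    width:height aspect ratio of the growth channel; the exact rectangular
    duct series solution is deliberately not implemented.
    """
    return 6.0 * flow.viscosity * mean_velocity(flow) / flow.height


# --- unit helpers for config/CLI boundaries (SI internally) ---------------

def ml_per_h_to_m3_per_s(q: float) -> float:
    return q * 1e-6 / 3600.0


def um_to_m(x: float) -> float:
    return x * 1e-6


def mpa_s_to_pa_s(mu: float) -> float:
    return mu * 1e-3


def summarize(
    film: ElasticFilm,
    blister: Blister,
    stress: StressState,
    flow: ChannelFlow | None = None,
    toughness: InterfaceToughness | None = None,
) -> dict:
    """One-shot record of the mechanics observables for reporting."""
    sc = critical_stress(film, blister)
    g0 = baseline_energy_release(film, stress)
    ratio = normalized_energy_release(stress, sc, film.poisson_ratio)
    out = {
        "critical_stress_Pa": sc,
        "G0_J_per_m2": g0,
        "G_over_G0": ratio.ratio,
        "buckled": ratio.buckled,
        "G_J_per_m2": ratio.ratio * g0,
    }
    if toughness is not None:
        out["verdict"] = delamination_verdict(out["G_J_per_m2"], toughness).value
    if flow is not None:
        out["mean_velocity_m_per_s"] = mean_velocity(flow)
        out["wall_shear_stress_Pa"] = wall_shear_stress(flow)
    return out
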