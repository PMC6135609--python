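"""Mass-action kinetic models of PARP1-DNA association and DNA-dependent dissociation.

Three reaction schemes are modelled, all in units of nM and seconds:

* ``ASSOCIATION`` -- a single reversible binding step between free protein P
  and labeled DNA D* (rate constants ``k1``, ``k_m1``).
* ``SIMPLE_COMPETITION`` -- dissociation in the presence of excess unlabeled
  competitor DNA under the assumption that release of the pre-bound DNA is
  rate-limiting: the probe complex dissociates reversibly while freed protein
  is captured irreversibly by competitor.
* ``TERNARY`` -- DNA-dependent ("monkey bar" / intersegment-transfer)
  dissociation: the competitor binds the probe-bound protein to form a ternary
  complex D*.P.D before the pre-bound probe is released.  ``k2``/``k_m2`` are
  competitor on/off the labeled binary complex; ``k3`` releases the pre-bound
  labeled DNA from the ternary complex and ``k_m3`` re-forms it from the
  competitor-bound protein plus free labeled DNA.  The asymmetry ``k2 != k_m3``
  and ``k_m2 != k3`` is deliberate: the two DNA sites on the protein are not
  equivalent.

Species (state-vector order): P, Dstar, D, PDstar, PD, T.  One DNA oligomer is
treated as a single binding equivalent because anisotropy only detects the
first binding event on the probe.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from enum import Enum

import numpy as np
from numba import njit

__all__ = [
    "Scheme",
    "RateParameters",
    "SpeciesState",
    "ConservedTotals",
    "CompetitorSpec",
    "Reaction",
    "SPECIES",
    "reaction_network",
    "ode_rhs",
    "pre_equilibrate",
    "kd_from_rates",
    "per_site_rescale",
    "approx_kobs_ternary",
]

SPECIES = ("P", "Dstar", "D", "PDstar", "PD", "T")


class Scheme(Enum):
    """Identifier of one of the three kinetic schemes."""

    ASSOCIATION = "association"
    SIMPLE_COMPETITION = "simple_competition"
    TERNARY = "ternary"

    @classmethod
    def parse(cls, value: "Scheme | str") -> "Scheme":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            valid = ", ".join(s.value for s in cls)
            raise ValueError(
                f"unknown scheme {value!r}; valid schemes are: {valid}"
            ) from None


def _check_nonneg(name: str, value: float | None) -> None:
    if value is None:
        return
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class RateParameters:
    """The rate constants of the three schemes.

    Second-order constants (``k1``, ``k2``, ``k_m3``, ``k1_prime``) are in
    nM^-1 s^-1; first-order constants (``k_m1``, ``k_m2``, ``k3``) in s^-1.
    Constants not used by a given scheme may be left as ``None``.
    ``k1_prime`` is the competitor-capture rate of the simple-competition
    scheme and defaults to ``k1`` (same chemistry, unlabeled molecule).
    """

    k1: float | None = None
    k_m1: float | None = None
    k2: float | None = None
    k_m2: float | None = None
    k3: float | None = None
    k_m3: float | None = None
    k1_prime: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            _check_nonneg(f.name, getattr(self, f.name))

    def evolve(self, **changes: float) -> "RateParameters":
        return replace(self, **changes)

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"rate constants {missing} are required but unset")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations (nM) of the six chemical species."""

    P: float = 0.0
    Dstar: float = 0.0
    D: float = 0.0
    PDstar: float = 0.0
    PD: float = 0.0
    T: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"species {f.name} must be a finite non-negative "
                    f"concentration, got {v!r}"
                )

    def to_array(self) -> np.ndarray:
        return np.array([self.P, self.Dstar, self.D, self.PDstar, self.PD, self.T])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SpeciesState":
        return cls(*(float(v) for v in y))

    def evolve(self, **changes: float) -> "SpeciesState":
        return replace(self, **changes)

    def totals(self) -> "ConservedTotals":
        return ConservedTotals(
            totalP=self.P + self.PDstar + self.PD + self.T,
            totalDstar=self.Dstar + self.PDstar + self.T,
            totalD=self.D + self.PD + self.T,
        )


@dataclass(frozen=True)
class ConservedTotals:
    """Mass-balance totals conserved along any trajectory (nM)."""

    totalP: float
    totalDstar: float
    totalD: float


@dataclass(frozen=True)
class CompetitorSpec:
    """A competitor DNA particle carrying one or more protein binding sites.

    An 18-mer oligomer has one site; a 4.5 kb plasmid anywhere from 5 (the
    minimum needed for 5 nM plasmid to strip a 25 nM probe complex) to ~450
    (one site per 10 bp).  Kinetics depend only on the effective site
    concentration ``molar_concentration * sites_per_particle``.
    """

    molar_concentration: float
    sites_per_particle: int = 1

    def __post_init__(self) -> None:
        _check_nonneg("molar_concentration", self.molar_concentration)
        if int(self.sites_per_particle) != self.sites_per_particle or self.sites_per_particle < 1:
            raise ValueError(
                f"sites_per_particle must be an integer >= 1, got {self.sites_per_particle!r}"
            )

    @property
    def site_concentration(self) -> float:
        return self.molar_concentration * self.sites_per_particle


@dataclass(frozen=True)
class Reaction:
    """One elementary step: reactants -> products with a forward rate label
    and, for reversible steps, a reverse label."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    forward: str
    reverse: str | None = None


def reaction_network(scheme: Scheme | str) -> list[Reaction]:
    """Return the elementary reactions of a scheme.

    The ternary scheme includes the binary binding steps so that any free
    protein present at mixing can capture either DNA directly.
    """
    scheme = Scheme.parse(scheme)
    bind_probe = Reaction(("P", "Dstar"), ("PDstar",), "k1", "k_m1")
    if scheme is Scheme.ASSOCIATION:
        return [bind_probe]
    if scheme is Scheme.SIMPLE_COMPETITION:
        # Irreversible competitor capture: valid when k1' * [D] >> k_m1.
        return [bind_probe, Reaction(("P", "D"), ("PD",), "k1_prime", None)]
    return [
        bind_probe,
        Reaction(("P", "D"), ("PD",), "k1", "k_m1"),
        Reaction(("PDstar", "D"), ("T",), "k2", "k_m2"),
        Reaction(("PD", "Dstar"), ("T",), "k_m3", "k3"),
    ]


# Internal rate-constant vector layout shared by the jitted RHS/Jacobian:
# [0] probe on, [1] probe off, [2] competitor capture on, [3] competitor
# capture off, [4] ternary formation (k2), [5] ternary loss of competitor
# (k_m2), [6] ternary loss of probe (k3), [7] ternary re-formation (k_m3).


def rate_vector(scheme: Scheme | str, params: RateParameters) -> np.ndarray:
    scheme = Scheme.parse(scheme)
    k = np.zeros(8)
    params.require("k1", "k_m1")
    k[0], k[1] = params.k1, params.k_m1
    if scheme is Scheme.SIMPLE_COMPETITION:
        k[2] = params.k1 if params.k1_prime is None else params.k1_prime
    elif scheme is Scheme.TERNARY:
        params.require("k2", "k_m2", "k3", "k_m3")
        k[2], k[3] = params.k1, params.k_m1
        k[4], k[5], k[6], k[7] = params.k2, params.k_m2, params.k3, params.k_m3
    return k


@njit(cache=False)
def _mass_action_rhs(y, t, k):  # pragma: no cover - exercised via wrappers
    P, Ds, D, PDs, PD, T = y[0], y[1], y[2], y[3], y[4], y[5]
    v1 = k[0] * P * Ds - k[1] * PDs
    vc = k[2] * P * D - k[3] * PD
    v2 = k[4] * PDs * D - k[5] * T
    v3 = k[7] * PD * Ds - k[6] * T
    out = np.empty(6)
    out[0] = -v1 - vc
    out[1] = -v1 - v3
    out[2] = -vc - v2
    out[3] = v1 - v2
    out[4] = vc - v3
    out[5] = v2 + v3
    return out


@njit(cache=False)
def _mass_action_jac(y, t, k):  # pragma: no cover - exercised via wrappers
    P, Ds, D, PDs, PD, T = y[0], y[1], y[2], y[3], y[4], y[5]
    J = np.zeros((6, 6))
    J[0, 0] = -k[0] * Ds - k[2] * D
    J[0, 1] = -k[0] * P
    J[0, 2] = -k[2] * P
    J[0, 3] = k[1]
    J[0, 4] = k[3]
    J[1, 0] = -k[0] * Ds
    J[1, 1] = -k[0] * P - k[7] * PD
    J[1, 3] = k[1]
    J[1, 4] = -k[7] * Ds
    J[1, 5] = k[6]
    J[2, 0] = -k[2] * D
    J[2, 2] = -k[2] * P - k[4] * PDs
    J[2, 3] = -k[4] * D
    J[2, 4] = k[3]
    J[2, 5] = k[5]
    J[3, 0] = k[0] * Ds
    J[3, 1] = k[0] * P
    J[3, 2] = -k[4] * PDs
    J[3, 3] = -k[1] - k[4] * D
    J[3, 5] = k[5]
    J[4, 0] = k[2] * D
    J[4, 1] = -k[7] * PD
    J[4, 2] = k[2] * P
    J[4, 4] = -k[3] - k[7] * Ds
    J[4, 5] = k[6]
    J[5, 1] = k[7] * PD
    J[5, 2] = k[4] * PDs
    J[5, 3] = k[4] * D
    J[5, 4] = k[7] * Ds
    J[5, 5] = -k[5] - k[6]
    return J


def ode_rhs(
    scheme: Scheme | str, params: RateParameters, state: SpeciesState
) -> np.ndarray:
    """Time derivative (nM/s) of each species, in ``SPECIES`` order.

    Derivatives are signed sums of mass-action fluxes; each conserved total
    has an exactly zero derivative by construction.
    """
    k = rate_vector(scheme, params)
    return np.asarray(_mass_action_rhs(state.to_array(), 0.0, k))


def pre_equilibrate(
    total_p: float, total_dstar: float, k1: float, k_m1: float
) -> SpeciesState:
    """Equilibrium of the single-site binding step P + D* <-> PD*.

    Returns the unique physical root of the binding quadratic with
    K_D = k_m1/k1 (the smaller root, computed in its numerically stable
    form), with free P and D* by difference and all other species zero.
    This is the t = 0 state of a dissociation experiment, where protein and
    probe are pre-mixed before the competitor is added.
    """
    _check_nonneg("total_p", total_p)
    _check_nonneg("total_dstar", total_dstar)
    _check_nonneg("k_m1", k_m1)
    if not k1 or k1 < 0:
        raise ValueError(f"k1 must be > 0 to define a binding equilibrium, got {k1!r}")
    kd = k_m1 / k1
    b = total_p + total_dstar + kd
    disc = b * b - 4.0 * total_p * total_dstar
    denom = b + math.sqrt(max(disc, 0.0))
    pdstar = 0.0 if denom == 0.0 else 2.0 * total_p * total_dstar / denom
    pdstar = min(pdstar, total_p, total_dstar)
    return SpeciesState(
        P=total_p - pdstar, Dstar=total_dstar - pdstar, PDstar=pdstar
    )


def kd_from_rates(k_off: float, k_on: float) -> float:
    """Equilibrium dissociation constant K_D = k_off / k_on (nM)."""
    _check_nonneg("k_off", k_off)
    if not k_on or k_on < 0:
        raise ValueError(f"k_on must be > 0, got {k_on!r}")
    return k_off / k_on


def per_site_rescale(
    k_per_site: float, sites_assumed: int, sites_target: int
) -> float:
    """Re-express a per-site second-order rate constant under a different
    binding-site count per particle.

    A fit performed assuming ``sites_assumed`` sites per competitor particle
    yields ``k_per_site``; the same data under ``sites_target`` sites imply
    ``k_per_site * sites_assumed / sites_target`` (the product of per-site
    rate and site concentration is what the data constrain).
    """
    for name, n in (("sites_assumed", sites_assumed), ("sites_target", sites_target)):
        if int(n) != n or n < 1:
            raise ValueError(f"{name} must be an integer >= 1, got {n!r}")
    _check_nonneg("k_per_site", k_per_site)
    return k_per_site * sites_assumed / sites_target


def approx_kobs_ternary(params: RateParameters, d_sites: float) -> float:
    """Steady-state closed-form apparent rate of probe release (s^-1).

    kobs = k3*k2*[D] / (k2*[D] + k_m2 + k3).  Valid when rebinding of the
    released labeled DNA is negligible (large competitor excess); strictly
    increasing in the competitor site concentration with asymptote k3.
    Used as an independent oracle for the full ODE simulations.
    """
    _check_nonneg("d_sites", d_sites)
    params.require("k2", "k_m2", "k3")
    num = params.k3 * params.k2 * d_sites
    den = params.k2 * d_sites + params.k_m2 + params.k3
    return 0.0 if den == 0.0 else num / den
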