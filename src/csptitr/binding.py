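"""Equilibrium binding models for protein–oligonucleotide titrations.

A protein A binds one of ``n_sites`` independent, identical sites on an
oligonucleotide B.  Under this model the fraction of protein bound,
``P_AB``, follows the quadratic (ligand-depletion) isotherm

    P_AB = (c_A + N c_B + K_D - sqrt((c_A + N c_B + K_D)^2 - 4 N c_A c_B))
           / (2 c_A)

where ``c_A`` and ``c_B`` are *total* molar concentrations of protein and
oligonucleotide, ``N`` the number of sites per oligonucleotide and ``K_D``
the per-site dissociation constant.  The explicit total-concentration form
is required because in both fluorescence and NMR titrations the protein
concentration is comparable to, or far above, ``K_D``, so the free-ligand
approximation of the hyperbolic isotherm does not hold.

In the stoichiometric (tight-binding) limit ``K_D << c_A`` the isotherm
degenerates to the kinked line ``P_AB = min(1, N c_B / c_A)``: every
added site is filled until the protein is exhausted, which is what makes
the breakpoint of an NMR titration at millimolar concentrations a direct
read-out of the stoichiometry ``N``.

Two NMR observables are derived from ``P_AB``:

* fast exchange — a single resonance at the population-weighted average
  position, ``delta = P_AB * delta_bound + (1 - P_AB) * delta_free``; the
  normalized shift change ``ddelta / ddelta_end`` then equals ``P_AB``;
* slow exchange — separate free and bound resonances whose integrals are
  proportional to the populations ``1 - P_AB`` and ``P_AB``.

Tryptophan fluorescence quenching is modelled as a linear mix of the free
and saturated intensities, ``F = F0 * (1 - q * P_AB)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BindingSystem",
    "ShiftEndpoints",
    "QuenchParameters",
    "fraction_bound",
    "fraction_bound_tight",
    "observed_shift_fast",
    "slow_exchange_intensities",
    "quenched_intensity",
    "linewidth_mass_scaling",
]


def _check_finite_nonneg(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative, got {value!r}")
    return arr


@dataclass(frozen=True)
class BindingSystem:
    """Total concentrations and binding parameters of one titration point.

    Parameters
    ----------
    c_protein
        Total protein concentration ``c_A`` in mol/L, > 0.
    c_ligand
        Total oligonucleotide concentration ``c_B`` in mol/L, >= 0.  May be
        an array to evaluate a whole titration schedule at once.
    n_sites
        Number of independent, identical protein-binding sites per
        oligonucleotide, > 0.  Real-valued: fits return non-integer
        estimates such as 1.99.
    kd
        Per-site dissociation constant in mol/L, >= 0.  ``kd = 0`` selects
        the stoichiometric limit exactly.
    """

    c_protein: float
    c_ligand: float | np.ndarray
    n_sites: float = 2.0
    kd: float = 0.0

    def __post_init__(self) -> None:
        c_a = _check_finite_nonneg("c_protein", self.c_protein)
        if not np.all(c_a > 0):
            raise ValueError(f"c_protein must be > 0, got {self.c_protein!r}")
        _check_finite_nonneg("c_ligand", self.c_ligand)
        n = _check_finite_nonneg("n_sites", self.n_sites)
        if not np.all(n > 0):
            raise ValueError(f"n_sites must be > 0, got {self.n_sites!r}")
        _check_finite_nonneg("kd", self.kd)


@dataclass(frozen=True)
class ShiftEndpoints:
    """Chemical shifts (ppm) of one resonance in the free and bound state."""

    free_shift: float
    bound_shift: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.free_shift) and math.isfinite(self.bound_shift)):
            raise ValueError("shift endpoints must be finite")

    @property
    def delta_end(self) -> float:
        """Full-saturation shift change ``delta_bound - delta_free`` (ppm)."""
        return self.bound_shift - self.free_shift


@dataclass(frozen=True)
class QuenchParameters:
    """Forward-model parameters of a tryptophan-quench titration.

    ``f0`` is the intensity of the fully free protein (arbitrary units);
    ``max_quench`` the fractional intensity loss at full saturation, so the
    predicted intensity always lies in ``[f0 * (1 - max_quench), f0]``.
    """

    f0: float = 1.0
    max_quench: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.f0) and self.f0 > 0):
            raise ValueError(f"f0 must be positive and finite, got {self.f0!r}")
        if not (0.0 <= self.max_quench <= 1.0):
            raise ValueError(f"max_quench must lie in [0, 1], got {self.max_quench!r}")


def fraction_bound(system: BindingSystem):
    """Bound protein fraction ``P_AB`` under the quadratic isotherm.

    Evaluated in the cancellation-free form
    ``P_AB = 2 N c_B / (b + sqrt(b^2 - 4 N c_A c_B))`` with
    ``b = c_A + N c_B + K_D``, algebraically identical to the textbook
    quadratic root but stable when ``K_D`` is many orders of magnitude
    below the concentrations (nanomolar ``K_D`` at millimolar protein).

    Returns a scalar for scalar ``c_ligand``, else an array.
    """
    c_a = float(np.asarray(system.c_protein))
    c_b = np.asarray(system.c_ligand, dtype=float)
    n = float(system.n_sites)
    kd = float(system.kd)

    b = c_a + n * c_b + kd
    disc = b * b - 4.0 * n * c_a * c_b
    # roundoff can push the discriminant a hair below zero at the kink
    disc = np.maximum(disc, 0.0)
    p = 2.0 * n * c_b / (b + np.sqrt(disc))
    p = np.clip(p, 0.0, 1.0)
    if np.isscalar(system.c_ligand) or np.ndim(system.c_ligand) == 0:
        return float(p)
    return p


def fraction_bound_tight(system: BindingSystem):
    """Bound fraction in the stoichiometric limit (``K_D`` neglected).

    ``P_AB = (c_A + N c_B - |c_A - N c_B|) / (2 c_A) = min(1, N c_B / c_A)``.
    The ``kd`` field of the system is ignored.
    """
    c_a = float(np.asarray(system.c_protein))
    c_b = np.asarray(system.c_ligand, dtype=float)
    n = float(system.n_sites)
    p = (c_a + n * c_b - np.abs(c_a - n * c_b)) / (2.0 * c_a)
    p = np.clip(p, 0.0, 1.0)
    if np.isscalar(system.c_ligand) or np.ndim(system.c_ligand) == 0:
        return float(p)
    return p


def _check_fraction(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"bound fraction must lie in [0, 1], got {p!r}")
    return arr


def observed_shift_fast(p_bound, endpoints: ShiftEndpoints):
    """Observed resonance position (ppm) under fast exchange.

    Population-weighted average of the free and bound shifts; an affine
    interpolation, so the result always lies between the two endpoints.
    """
    p = _check_fraction(p_bound)
    out = p * endpoints.bound_shift + (1.0 - p) * endpoints.free_shift
    if np.ndim(p_bound) == 0:
        return float(out)
    return out


def slow_exchange_intensities(p_bound):
    """Integral fractions ``(free, bound)`` of the two slow-exchange peaks.

    Intensities are proportional to populations only; differential
    relaxation between the free and bound resonance is ignored, matching
    the population read-out from peak integrals.  The pair sums to 1.
    """
    p = _check_fraction(p_bound)
    if np.ndim(p_bound) == 0:
        return (1.0 - float(p), float(p))
    return (1.0 - p, p)


def quenched_intensity(system: BindingSystem, quench: QuenchParameters):
    """Predicted fluorescence intensity ``F0 * (1 - q * P_AB)``.

    Monotonically non-increasing in ``c_ligand``; no baseline drift or
    inner-filter correction is applied.
    """
    p = fraction_bound(system)
    return quench.f0 * (1.0 - quench.max_quench * np.asarray(p)) if np.ndim(p) else float(
        quench.f0 * (1.0 - quench.max_quench * p)
    )


def linewidth_mass_scaling(mass_ratio: float) -> float:
    """Approximate linewidth broadening factor for a change in molecular mass.

    Models the broadening as the cube root of the mass ratio — the scaling
    of the hydrodynamic radius of a rigid sphere of constant density.
    Doubling the mass (e.g. by dimerization on the ligand) broadens lines
    by 2**(1/3) ≈ 1.26 under this rule.
    """
    if not (math.isfinite(mass_ratio) and mass_ratio > 0):
        raise ValueError(f"mass_ratio must be positive and finite, got {mass_ratio!r}")
    return float(mass_ratio) ** (1.0 / 3.0)
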