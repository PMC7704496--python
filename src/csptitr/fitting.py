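"""Nonlinear least-squares estimation of binding parameters.

Two estimation problems are covered:

* ``fit_kd_fluorescence`` — per-site dissociation constant from a
  tryptophan-quench titration, fitting ``(K_D, F0, q)`` to the quadratic
  isotherm with the site count fixed;
* ``fit_stoichiometry`` — site count ``N`` (and a saturation amplitude)
  from a normalized NMR shift titration with ``K_D`` fixed to the value
  obtained by fluorescence.

Both use bounded trust-region least squares (`scipy.optimize.least_squares`)
with multi-start initialisation; ``K_D`` is optimised on a log10 scale
because plausible values span several orders of magnitude.  Uncertainties
come from the local curvature (Gauss-Newton covariance) and optionally
from a case-resampling bootstrap over titration points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .binding import BindingSystem, fraction_bound

__all__ = [
    "FluorescenceCurve",
    "NormalizedShiftSeries",
    "FitResult",
    "fit_kd_fluorescence",
    "fit_stoichiometry",
    "bootstrap_uncertainty",
    "normalize_to_final",
]

DEFAULT_BOOTSTRAP_SEED = 1729
KD_LOG10_BOUNDS = (-12.0, -3.0)  # mol/L; spans picomolar to millimolar


@dataclass(frozen=True)
class FluorescenceCurve:
    """One fluorescence-quench titration at fixed total protein.

    ``c_ligand`` (mol/L) must be strictly increasing; at least 5 points are
    required for the 3-parameter fit.  Intensities are arbitrary units,
    positive; fits are invariant to a uniform rescaling.
    """

    c_ligand: np.ndarray
    intensity: np.ndarray
    c_protein: float
    temperature_label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.c_ligand, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "c_ligand", c)
        object.__setattr__(self, "intensity", y)
        if c.ndim != 1 or y.shape != c.shape:
            raise ValueError("c_ligand and intensity must be 1-D arrays of equal length")
        if len(c) < 5:
            raise ValueError(f"need >= 5 titration points for a 3-parameter fit, got {len(c)}")
        if np.any(np.diff(c) <= 0) or np.any(c < 0):
            raise ValueError("ligand concentrations must be non-negative and strictly increasing")
        if not np.all(np.isfinite(y)) or np.any(y <= 0):
            raise ValueError("intensities must be finite and positive")
        if not (np.isfinite(self.c_protein) and self.c_protein > 0):
            raise ValueError(f"c_protein must be positive, got {self.c_protein!r}")


@dataclass(frozen=True)
class NormalizedShiftSeries:
    """Normalized shift changes versus ligand:protein molar ratio.

    ``values`` are ``ddelta / ddelta_end`` (dimensionless), conventionally
    anchored by setting the change at the final titration point to 1;
    under fast exchange they estimate the bound fraction directly.
    ``residue_averaged`` records whether the series is a mean over residues
    or a single resonance.
    """

    ratios: np.ndarray
    values: np.ndarray
    c_protein: float
    residue_averaged: bool = True

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "ratios", r)
        object.__setattr__(self, "values", v)
        if r.ndim != 1 or v.shape != r.shape:
            raise ValueError("ratios and values must be 1-D arrays of equal length")
        if np.any(r < 0) or np.any(np.diff(r) <= 0):
            raise ValueError("ratios must be non-negative and strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("shift values must be finite")
        if not (np.isfinite(self.c_protein) and self.c_protein > 0):
            raise ValueError(f"c_protein must be positive, got {self.c_protein!r}")


@dataclass
class FitResult:
    """Point estimates and diagnostics of one least-squares fit."""

    estimates: dict[str, float]
    std_errors: dict[str, float]
    residual_norm: float
    converged: bool
    n_points: int
    seed: int | None = None
    bootstrap_std: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.converged:
            vals = list(self.estimates.values()) + [self.residual_norm]
            if not np.all(np.isfinite(vals)):
                raise ValueError("a converged fit must carry finite estimates and residual norm")


def normalize_to_final(values: Sequence[float]) -> np.ndarray:
    """Normalize a shift-change series by its final titration point."""
    v = np.asarray(values, dtype=float)
    if v[-1] == 0:
        raise ValueError("cannot normalize: shift change at the final point is zero")
    return v / v[-1]


def _multistart_least_squares(residuals, starts, bounds):
    """Run `least_squares` from several starts, return the best solution."""
    best = None
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=bounds, method="trf")
        except Exception:  # singular step, bad start — try the next one
            continue
        if sol.x is not None and np.all(np.isfinite(sol.x)):
            if best is None or sol.cost < best.cost:
                best = sol
    return best


def _curvature_std(sol, n_points: int, n_params: int) -> np.ndarray:
    """Gauss-Newton standard errors from the jacobian at the optimum."""
    dof = max(n_points - n_params, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(n_params, np.nan)


def fit_kd_fluorescence(
    curve: FluorescenceCurve,
    n_sites: float = 2.0,
    *,
    n_starts: int = 8,
    n_boot: int = 0,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> FitResult:
    """Estimate ``K_D`` (with ``F0`` and quench amplitude ``q``) from a quench curve.

    The forward model is ``F(c_B) = F0 * (1 - q * P_AB(c_A, c_B, N, K_D))``
    with the site count ``N`` fixed (default 2 protein molecules per
    heptanucleotide).  ``K_D`` is searched on a log10 grid of ``n_starts``
    starting points spanning picomolar to millimolar; the best local
    optimum is kept.  Non-convergence of every start is reported via
    ``converged=False`` rather than an exception.

    With ``n_boot > 0`` a case-resampling bootstrap over titration points
    adds empirical standard deviations in ``bootstrap_std``.
    """
    if n_sites <= 0 or not np.isfinite(n_sites):
        raise ValueError(f"n_sites must be positive, got {n_sites!r}")
    y = curve.intensity
    scale = float(np.max(y))

    def residuals(theta, c=curve.c_ligand, yobs=y):
        log_kd, f0, q = theta
        sys = BindingSystem(curve.c_protein, c, n_sites, 10.0 ** log_kd)
        return f0 * (1.0 - q * np.asarray(fraction_bound(sys))) - yobs / scale

    f0_init = float(y[0] / scale)
    q_init = min(max(1.0 - float(np.min(y) / np.max(y)), 0.05), 0.95)
    lo, hi = KD_LOG10_BOUNDS
    starts = [
        (lk, f0_init, q_init) for lk in np.linspace(lo + 0.5, hi - 0.5, n_starts)
    ]
    bounds = ([lo, 1e-12, 0.0], [hi, np.inf, 1.0])
    sol = _multistart_least_squares(residuals, starts, bounds)

    names = ("kd", "f0", "q")
    if sol is None or not sol.success:
        est = dict.fromkeys(names, np.nan)
        return FitResult(est, dict.fromkeys(names, np.nan), np.nan, False, len(y), seed)

    log_kd, f0, q = sol.x
    kd = 10.0 ** log_kd
    se = _curvature_std(sol, len(y), 3)
    estimates = {"kd": kd, "f0": f0 * scale, "q": q}
    std_errors = {
        "kd": float(np.log(10.0) * kd * se[0]),  # delta method from log10 scale
        "f0": float(se[1] * scale),
        "q": float(se[2]),
    }
    result = FitResult(
        estimates, std_errors, float(2.0 * sol.cost * scale**2), True, len(y), seed
    )
    if n_boot:
        def refit(idx: np.ndarray) -> Mapping[str, float]:
            order = np.argsort(curve.c_ligand[idx])
            c = curve.c_ligand[idx][order]
            yb = y[idx][order] / scale
            def res_b(theta):
                lk, f0b, qb = theta
                sys = BindingSystem(curve.c_protein, c, n_sites, 10.0 ** lk)
                return f0b * (1.0 - qb * np.asarray(fraction_bound(sys))) - yb
            sb = _multistart_least_squares(res_b, [sol.x], bounds)
            if sb is None:
                return {}
            return {"kd": 10.0 ** sb.x[0], "f0": sb.x[1] * scale, "q": sb.x[2]}

        result.bootstrap_std = bootstrap_uncertainty(
            refit, len(y), n_boot=n_boot, seed=seed, min_unique=3
        )
    return result


def fit_stoichiometry(
    series: NormalizedShiftSeries,
    kd: float,
    *,
    n_starts: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0, 6.0),
    n_boot: int = 0,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
) -> FitResult:
    """Estimate the site count ``N`` from a normalized NMR shift titration.

    Fits ``ddelta/ddelta_end = amplitude * P_AB(c_A, ratio * c_A, N, K_D)``
    over ``(N, amplitude)`` with ``K_D`` held at the fluorescence value.
    At millimolar protein and nanomolar ``K_D`` the model is effectively
    the stoichiometric kink curve, whose breakpoint at ratio ``1/N`` pins
    the site count; the amplitude absorbs imperfect normalization and
    should come out near 1.
    """
    if kd < 0 or not np.isfinite(kd):
        raise ValueError(f"kd must be non-negative and finite, got {kd!r}")
    y = series.values
    if np.all(y == 0):
        raise ValueError("all shift changes are zero; nothing to fit")
    c_a = series.c_protein

    def residuals(theta, r=series.ratios, yobs=y):
        n, amp = theta
        sys = BindingSystem(c_a, r * c_a, n, kd)
        return amp * np.asarray(fraction_bound(sys)) - yobs

    amp_init = max(float(np.max(np.abs(y))), 0.1)
    starts = [(n0, amp_init) for n0 in n_starts]
    bounds = ([1e-2, 1e-6], [50.0, 10.0])
    sol = _multistart_least_squares(residuals, starts, bounds)

    names = ("n_sites", "amplitude")
    if sol is None or not sol.success:
        est = dict.fromkeys(names, np.nan)
        return FitResult(est, dict.fromkeys(names, np.nan), np.nan, False, len(y), seed)

    se = _curvature_std(sol, len(y), 2)
    estimates = {"n_sites": float(sol.x[0]), "amplitude": float(sol.x[1])}
    std_errors = {"n_sites": float(se[0]), "amplitude": float(se[1])}
    result = FitResult(estimates, std_errors, float(2.0 * sol.cost), True, len(y), seed)
    if n_boot:
        def refit(idx: np.ndarray) -> Mapping[str, float]:
            order = np.argsort(series.ratios[idx])
            r = series.ratios[idx][order]
            yb = y[idx][order]
            def res_b(theta):
                n, amp = theta
                sys = BindingSystem(c_a, r * c_a, n, kd)
                return amp * np.asarray(fraction_bound(sys)) - yb
            sb = _multistart_least_squares(res_b, [sol.x], bounds)
            if sb is None:
                return {}
            return {"n_sites": float(sb.x[0]), "amplitude": float(sb.x[1])}

        result.bootstrap_std = bootstrap_uncertainty(
            refit, len(y), n_boot=n_boot, seed=seed, min_unique=2
        )
    return result


def bootstrap_uncertainty(
    refit: Callable[[np.ndarray], Mapping[str, float]],
    n_points: int,
    *,
    n_boot: int = 1000,
    seed: int = DEFAULT_BOOTSTRAP_SEED,
    min_unique: int = 1,
    max_retries: int = 100,
) -> dict[str, float]:
    """Case-resampling bootstrap standard deviations of fitted parameters.

    ``refit`` receives an index array into the original points and returns
    the re-estimated parameters (an empty mapping marks a failed refit,
    which is dropped).  Resamples with fewer than ``min_unique`` distinct
    points cannot constrain the fit and are redrawn, up to ``max_retries``
    times each.  Deterministic for a given ``seed``.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100 for stable standard deviations, got {n_boot}")
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {}
    for _ in range(n_boot):
        idx = rng.integers(0, n_points, size=n_points)
        retries = 0
        while len(np.unique(idx)) < min_unique:
            retries += 1
            if retries > max_retries:
                raise RuntimeError(
                    f"could not draw a resample with {min_unique} unique points "
                    f"in {max_retries} retries"
                )
            idx = rng.integers(0, n_points, size=n_points)
        params = refit(idx)
        for k, v in params.items():
            draws.setdefault(k, []).append(float(v))
    return {k: float(np.std(v, ddof=1)) for k, v in draws.items() if len(v) > 1}
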