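"""Seeded generators of synthetic titration data.

Every analysis stage in this package has a paired generator here whose
output has the statistical structure the stage assumes, so the full
pipeline is testable without any experimental download:

* ``simulate_fluorescence_titration`` — quadratic-isotherm quench curves
  in the concentration regimes of the fluorescence experiments (nanomolar
  to micromolar protein), with multiplicative intensity noise;
* ``simulate_shift_series`` — residue-averaged normalized fast-exchange
  shift trajectories at NMR concentrations (millimolar protein), where
  nanomolar dissociation constants put the system deep in the
  stoichiometric regime and the curve is the kinked tight-binding line;
* ``simulate_hsqc_titration`` — per-point peak lists with per-residue
  exchange regimes: fast (continuously shifting peak), slow (coexisting
  free/bound peaks trading integral), and intermediate ("disappear":
  the peak is dropped while the bound fraction sits mid-titration);
* ``simulate_epitope_profile`` — paired free/bound endpoint peak lists
  with a planted binding epitope, for the perturbation-mapping stage.

The simulated protein is a synthetic 66-residue sequence (it is not the
sequence of any real protein) with tryptophans at positions 7 and 29 and
a proline at 57, mirroring the residue types that matter downstream:
tryptophans contribute side-chain Nε1/Hε1 peaks, the proline has no
backbone amide and is therefore never evaluable.

All randomness flows from ``SimulationSpec.seed`` through one
``numpy.random.Generator``; a fixed seed reproduces every dataset
byte-for-byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binding import (
    BindingSystem,
    QuenchParameters,
    fraction_bound,
    quenched_intensity,
    slow_exchange_intensities,
)
from .csp import DEFAULT_ATOM_WEIGHTS
from .fitting import FluorescenceCurve, NormalizedShiftSeries
from .io import Peak, PeakList

__all__ = [
    "SimulationSpec",
    "synthetic_sequence",
    "saturation_schedule",
    "simulate_fluorescence_titration",
    "simulate_shift_series",
    "simulate_hsqc_titration",
    "simulate_epitope_profile",
]

#: Planted binding epitope of the synthetic protein: ends of strands 1-3
#: plus loop residues, echoing the interface layout of an OB-fold
#: nucleic-acid binder.
DEFAULT_EPITOPE = frozenset({7, 9, 10, 12, 13, 14, 16, 28, 29, 30, 33, 37, 41, 55, 63})
#: Epitope residues whose resonance broadens beyond detection (intermediate
#: exchange) and vanishes from the bound endpoint.
DEFAULT_DISAPPEAR = frozenset({9, 13, 37})
#: Epitope residues in slow exchange (two coexisting peaks mid-titration).
DEFAULT_SLOW = frozenset({29})

_N_WEIGHT = DEFAULT_ATOM_WEIGHTS["N"]


def synthetic_sequence(n_residues: int = 66) -> str:
    """Deterministic synthetic amino-acid sequence (one-letter codes).

    Purely artificial: drawn from a fixed internal seed, then tryptophans
    are placed at positions 7 and 29 and a proline at 57 (1-based) so the
    peak lists exercise side-chain amides and a proline gap.
    """
    alphabet = np.array(list("ADEFGHIKLMNQRSTVY"))
    rng = np.random.default_rng(20260101)
    seq = list(rng.choice(alphabet, size=n_residues))
    for pos, code in ((7, "W"), (29, "W"), (57, "P")):
        if pos <= n_residues:
            seq[pos - 1] = code
    return "".join(seq)


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth and noise model of one simulated titration study.

    Defaults reproduce the study conditions of the experiments this
    package analyses: 1 mM protein titrated to a ligand:protein ratio of
    0.625 in five equal steps for NMR; 5 nM protein and a 12-point
    log-spaced schedule to 99% saturation for fluorescence; two binding
    sites per heptanucleotide with a 4 nM per-site dissociation constant.
    """

    # concentrations / truth
    c_protein: float = 1e-3  # mol/L (NMR regime)
    ratios: tuple[float, ...] = (0.0, 0.125, 0.25, 0.375, 0.5, 0.625)
    c_ligand_schedule: tuple[float, ...] | None = None  # mol/L; fluorescence override
    n_sites: float = 2.0
    kd: float = 4e-9  # mol/L
    # fluorescence forward model
    f0: float = 1.0
    max_quench: float = 0.8
    fluorescence_noise: float = 0.01  # relative (multiplicative)
    n_fluorescence_points: int = 12
    # NMR noise model
    normalized_noise: float = 0.03  # on dimensionless normalized shifts
    shift_noise_ppm: float = 0.005  # 1H peak-position noise; 15N scaled by 1/0.14
    background_sigma_ppm: float = 0.01  # per-atom background perturbation scale
    effect_range: tuple[float, float] = (3.0, 8.0)  # epitope effect, x reference sigma
    epitope_sigma_ppm: float | None = None  # reference scale for the epitope effect;
    # defaults to background_sigma_ppm so effects are expressed as multiples of background
    # epitope layout
    n_residues: int = 66
    epitope_residues: frozenset[int] = DEFAULT_EPITOPE
    disappear_residues: frozenset[int] = DEFAULT_DISAPPEAR
    slow_residues: frozenset[int] = DEFAULT_SLOW
    disappear_band: tuple[float, float] = (0.2, 0.8)  # bound-fraction window
    seed: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        if np.any(r < 0) or np.any(np.diff(r) <= 0):
            raise ValueError("ratios must be non-negative and strictly increasing")
        if self.c_ligand_schedule is not None:
            c = np.asarray(self.c_ligand_schedule, dtype=float)
            if np.any(c < 0) or np.any(np.diff(c) <= 0):
                raise ValueError("ligand schedule must be non-negative and strictly increasing")
        if self.c_protein <= 0 or self.kd < 0 or self.n_sites <= 0:
            raise ValueError("invalid binding truth parameters")
        if not self.epitope_residues <= set(range(1, self.n_residues + 1)):
            raise ValueError("epitope residues outside the sequence")
        if not (self.disappear_residues | self.slow_residues) <= self.epitope_residues:
            raise ValueError("disappear/slow residues must be part of the epitope")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def saturation_schedule(
    c_protein: float,
    n_sites: float,
    kd: float,
    n_points: int = 12,
    saturation: float = 0.99,
    first_saturation: float = 0.05,
) -> np.ndarray:
    """Ligand schedule (mol/L) from ~``first_saturation`` to ``saturation``.

    Inverts the quadratic isotherm in closed form: at bound fraction ``P``
    the total ligand is ``c_B = (P c_A + K_D P / (1 - P)) / N``.  Returns
    a zero point followed by ``n_points`` log-spaced concentrations.
    """
    def c_at(p: float) -> float:
        return (p * c_protein + kd * p / (1.0 - p)) / n_sites

    lo, hi = c_at(first_saturation), c_at(saturation)
    return np.concatenate([[0.0], np.geomspace(lo, hi, n_points)])


def simulate_fluorescence_titration(
    spec: SimulationSpec,
) -> tuple[FluorescenceCurve, dict]:
    """Quench curve with multiplicative Gaussian intensity noise.

    Uses ``spec.c_ligand_schedule`` if given, else a log-spaced schedule
    to 99% saturation.  Warns (without failing) when the protein
    concentration is more than 100x the dissociation constant — the curve
    then pins the stoichiometric breakpoint but barely constrains K_D —
    and when the schedule stops short of 95% saturation.
    """
    if spec.kd > 0 and spec.c_protein > 100.0 * spec.kd:
        warnings.warn(
            "c_protein > 100 x K_D: titration is in the stoichiometric regime and "
            "K_D will be poorly resolved",
            stacklevel=2,
        )
    if spec.c_ligand_schedule is not None:
        c_b = np.asarray(spec.c_ligand_schedule, dtype=float)
    else:
        c_b = saturation_schedule(
            spec.c_protein, spec.n_sites, spec.kd, spec.n_fluorescence_points
        )
    sys = BindingSystem(spec.c_protein, c_b, spec.n_sites, spec.kd)
    p = np.asarray(fraction_bound(sys))
    if p[-1] < 0.95:
        warnings.warn(
            f"ligand schedule reaches only {p[-1]:.0%} saturation (< 95%)", stacklevel=2
        )
    clean = quenched_intensity(sys, QuenchParameters(spec.f0, spec.max_quench))
    rng = spec.rng()
    noisy = np.asarray(clean) * (1.0 + spec.fluorescence_noise * rng.standard_normal(len(c_b)))
    noisy = np.maximum(noisy, 1e-12 * spec.f0)
    curve = FluorescenceCurve(c_b, noisy, spec.c_protein, temperature_label="303 K")
    truth = {
        "kd": spec.kd,
        "n_sites": spec.n_sites,
        "f0": spec.f0,
        "max_quench": spec.max_quench,
        "seed": spec.seed,
    }
    return curve, truth


def simulate_shift_series(
    spec: SimulationSpec, normalize: bool = False
) -> tuple[NormalizedShiftSeries, dict]:
    """Residue-averaged normalized shift trajectory with Gaussian noise.

    The clean trajectory is the bound fraction at each ligand:protein
    ratio (fast exchange, amplitude 1); ``normalized_noise`` is added to
    every point.  With ``normalize=True`` the noisy series is re-anchored
    by its final point, the conventional treatment of an experimental
    series whose true endpoint is unknown.
    """
    ratios = np.asarray(spec.ratios, dtype=float)
    sys = BindingSystem(spec.c_protein, ratios * spec.c_protein, spec.n_sites, spec.kd)
    clean = np.asarray(fraction_bound(sys))
    rng = spec.rng()
    values = clean + spec.normalized_noise * rng.standard_normal(len(ratios))
    if normalize:
        if values[-1] == 0:
            raise ValueError("cannot normalize: final noisy point is zero")
        values = values / values[-1]
    series = NormalizedShiftSeries(ratios, values, spec.c_protein, residue_averaged=True)
    truth = {"n_sites": spec.n_sites, "kd": spec.kd, "amplitude": 1.0, "seed": spec.seed}
    return series, truth


def _residue_atoms(index: int, code: str) -> list[str]:
    """Observable amide atoms of one residue (backbone + Trp side chain)."""
    if code == "P":
        return []
    atoms = ["H", "N"]
    if code == "W":
        atoms += ["HE1", "NE1"]
    return atoms


def _base_shifts(spec: SimulationSpec, rng: np.random.Generator) -> dict[tuple[int, str], float]:
    """Random but seed-stable free-state peak positions (ppm)."""
    seq = synthetic_sequence(spec.n_residues)
    shifts: dict[tuple[int, str], float] = {}
    for idx, code in enumerate(seq, start=1):
        for atom in _residue_atoms(idx, code):
            if atom.startswith("H"):
                shifts[(idx, atom)] = float(rng.uniform(6.5, 10.5))
            else:
                shifts[(idx, atom)] = float(rng.uniform(105.0, 132.0))
    return shifts


def _endpoint_deltas(
    spec: SimulationSpec, rng: np.random.Generator
) -> dict[tuple[int, str], float]:
    """Per-atom full-saturation shift changes (ppm).

    Epitope residues: magnitude ``f x background sigma`` with ``f`` drawn
    once per residue from ``effect_range``, random sign per atom; nitrogen
    changes are scaled by the inverse nitrogen weight so both atom types
    contribute equally to the combined perturbation.  Background residues:
    zero-mean Gaussian at the background scale.
    """
    seq = synthetic_sequence(spec.n_residues)
    effect_sigma = (
        spec.background_sigma_ppm if spec.epitope_sigma_ppm is None else spec.epitope_sigma_ppm
    )
    deltas: dict[tuple[int, str], float] = {}
    for idx, code in enumerate(seq, start=1):
        atoms = _residue_atoms(idx, code)
        if not atoms:
            continue
        in_epitope = idx in spec.epitope_residues
        factor = float(rng.uniform(*spec.effect_range)) if in_epitope else float("nan")
        for atom in atoms:
            atom_scale = 1.0 if atom.startswith("H") else 1.0 / _N_WEIGHT
            if in_epitope:
                deltas[(idx, atom)] = (
                    float(rng.choice([-1.0, 1.0])) * factor * effect_sigma * atom_scale
                )
            else:
                deltas[(idx, atom)] = float(
                    rng.normal(0.0, spec.background_sigma_ppm * atom_scale)
                )
    return deltas


def simulate_hsqc_titration(spec: SimulationSpec) -> tuple[list[PeakList], dict]:
    """Peak lists for every titration point, plus the ground-truth record.

    Per-residue exchange regimes: fast residues shift continuously with
    the bound fraction; slow residues split into ``free``/``bound`` peaks
    whose intensities follow the populations; disappear residues are
    dropped while the bound fraction lies inside ``spec.disappear_band``
    (at higher saturation they reappear at the bound position).
    Measurement noise is added to every emitted peak position.
    """
    rng = spec.rng()
    seq = synthetic_sequence(spec.n_residues)
    base = _base_shifts(spec, rng)
    deltas = _endpoint_deltas(spec, rng)
    ratios = np.asarray(spec.ratios, dtype=float)
    sys = BindingSystem(spec.c_protein, ratios * spec.c_protein, spec.n_sites, spec.kd)
    p_bound = np.asarray(fraction_bound(sys))

    lists: list[PeakList] = []
    for p in p_bound:
        peaks: list[Peak] = []
        for idx, code in enumerate(seq, start=1):
            atoms = _residue_atoms(idx, code)
            for atom in atoms:
                noise_scale = spec.shift_noise_ppm * (
                    1.0 if atom.startswith("H") else 1.0 / _N_WEIGHT
                )
                free = base[(idx, atom)]
                bound = free + deltas[(idx, atom)]
                if idx in spec.disappear_residues:
                    lo, hi = spec.disappear_band
                    if lo <= p <= hi:
                        continue  # broadened beyond detection mid-titration
                    pos = free if p < lo else bound
                    peaks.append(
                        Peak(idx, code, atom, pos + rng.normal(0.0, noise_scale))
                    )
                elif idx in spec.slow_residues:
                    i_free, i_bound = slow_exchange_intensities(float(p))
                    if i_free > 0.02:
                        peaks.append(
                            Peak(idx, code, atom, free + rng.normal(0.0, noise_scale),
                                 intensity=i_free, state="free")
                        )
                    if i_bound > 0.02:
                        peaks.append(
                            Peak(idx, code, atom, bound + rng.normal(0.0, noise_scale),
                                 intensity=i_bound, state="bound")
                        )
                else:
                    pos = free + p * deltas[(idx, atom)]
                    peaks.append(Peak(idx, code, atom, pos + rng.normal(0.0, noise_scale)))
        lists.append(PeakList(peaks))

    truth = {
        "n_sites": spec.n_sites,
        "kd": spec.kd,
        "ratios": tuple(float(r) for r in ratios),
        "bound_fraction": tuple(float(x) for x in p_bound),
        "epitope_residues": sorted(spec.epitope_residues),
        "disappear_residues": sorted(spec.disappear_residues),
        "slow_residues": sorted(spec.slow_residues),
        "endpoint_deltas": {f"{i}:{a}": d for (i, a), d in sorted(deltas.items())},
        "seed": spec.seed,
    }
    return lists, truth


def simulate_epitope_profile(spec: SimulationSpec) -> tuple[PeakList, PeakList, dict]:
    """Free and bound-endpoint peak lists with a planted epitope.

    The bound list is the free list displaced by the per-atom endpoint
    changes (the endpoint ratio saturates the protein in the default
    stoichiometric regime) plus peak-position measurement noise on both
    endpoints; disappear-flagged residues are absent from the bound list.
    """
    if not spec.epitope_residues:
        raise ValueError("epitope residue set is empty")
    rng = spec.rng()
    seq = synthetic_sequence(spec.n_residues)
    base = _base_shifts(spec, rng)
    deltas = _endpoint_deltas(spec, rng)

    free_peaks: list[Peak] = []
    bound_peaks: list[Peak] = []
    for idx, code in enumerate(seq, start=1):
        for atom in _residue_atoms(idx, code):
            noise_scale = spec.shift_noise_ppm * (
                1.0 if atom.startswith("H") else 1.0 / _N_WEIGHT
            )
            free = base[(idx, atom)]
            free_peaks.append(Peak(idx, code, atom, free + rng.normal(0.0, noise_scale)))
            if idx in spec.disappear_residues:
                continue
            bound = free + deltas[(idx, atom)]
            bound_peaks.append(Peak(idx, code, atom, bound + rng.normal(0.0, noise_scale)))

    truth = {
        "epitope_residues": sorted(spec.epitope_residues),
        "disappear_residues": sorted(spec.disappear_residues),
        "endpoint_deltas": {f"{i}:{a}": d for (i, a), d in sorted(deltas.items())},
        "background_sigma_ppm": spec.background_sigma_ppm,
        "seed": spec.seed,
    }
    return PeakList(free_peaks), PeakList(bound_peaks), truth
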