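"""Chemical-shift-perturbation (CSP) epitope mapping.

The binding interface of a protein is mapped from endpoint spectra (free
protein versus the final titration point) by combining per-atom shift
changes into a single per-residue perturbation,

    ddelta_comb = sqrt( sum_i (w_i * ddelta_i)^2 ),

the weighted Euclidean norm over the available atoms (backbone amide H
and N, plus assignable side-chain amides such as tryptophan Nε1/Hε1).
Nitrogen shifts are scaled down (default weight 0.14) so that their much
larger ppm range contributes on the same footing as proton shifts.

Residues are classified against the population standard deviation
``sigma0`` of the measured perturbations: below ``sigma0`` — no evidence
of interaction; in ``[sigma0, 2 sigma0)`` — moderate; at or above
``2 sigma0`` — high.  Resonances that vanish at the titration endpoint
(intermediate exchange broadening, or slow-exchange peaks that could not
be re-assigned) carry real but unquantifiable perturbations: they are
imputed at ``2 sigma0`` and classed ``disappeared-high``.  ``sigma0`` is
computed *before* imputation, over measured residues only, so the imputed
values cannot feed back into the threshold.

A consensus epitope across two or more ligands keeps a residue iff it is
high (or disappeared-high) for at least one ligand and at least moderate
for every other.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ResidueStatus",
    "InteractionClass",
    "ResidueShiftRecord",
    "ResiduePerturbation",
    "EpitopeMap",
    "DEFAULT_ATOM_WEIGHTS",
    "atom_weight",
    "combined_shift",
    "perturbation_profile",
    "sigma0",
    "classify_residues",
    "consensus_epitope",
]

#: Default per-element weights for the combined shift norm, keyed by the
#: leading element letter of the atom name (PDB-style: H, HE1, N, NE1...).
#: 1.0 for protons; 0.14 for nitrogen, the conventional amide scaling.
#: Override per atom label via the ``weights`` argument of the operations.
DEFAULT_ATOM_WEIGHTS: dict[str, float] = {"H": 1.0, "N": 0.14}


class ResidueStatus(enum.Enum):
    MEASURED = "measured"
    DISAPPEARED = "disappeared"
    NOT_EVALUABLE = "not-evaluable"


class InteractionClass(enum.Enum):
    NONE = "none"
    MODERATE = "moderate"
    HIGH = "high"
    DISAPPEARED_HIGH = "disappeared-high"
    NOT_EVALUABLE = "not-evaluable"

    @property
    def interacting(self) -> bool:
        """True for any class counted as evidence of interaction."""
        return self in (
            InteractionClass.MODERATE,
            InteractionClass.HIGH,
            InteractionClass.DISAPPEARED_HIGH,
        )

    @property
    def high_confidence(self) -> bool:
        return self in (InteractionClass.HIGH, InteractionClass.DISAPPEARED_HIGH)


@dataclass(frozen=True)
class ResidueShiftRecord:
    """Free/bound shift pairs (ppm) for the atoms of one residue."""

    residue_index: int
    residue_code: str
    atom_shifts: Mapping[str, tuple[float, float]]  # atom -> (free, bound)
    status: ResidueStatus = ResidueStatus.MEASURED

    def __post_init__(self) -> None:
        if self.status is ResidueStatus.MEASURED and not self.atom_shifts:
            raise ValueError(
                f"residue {self.residue_index}{self.residue_code}: a measured record "
                "needs at least one atom pair"
            )
        if self.residue_code == "P":
            backbone = {"H", "N"} & set(self.atom_shifts)
            if backbone:
                raise ValueError(
                    f"proline {self.residue_index} cannot carry backbone amide atoms {backbone}"
                )


@dataclass(frozen=True)
class ResiduePerturbation:
    """Combined shift change of one residue, or its imputed stand-in."""

    residue_index: int
    residue_code: str
    delta_comb: float  # ppm, >= 0; NaN until imputation for disappeared residues
    status: ResidueStatus

    def __post_init__(self) -> None:
        if self.status is ResidueStatus.MEASURED and not (
            np.isfinite(self.delta_comb) and self.delta_comb >= 0
        ):
            raise ValueError(
                f"residue {self.residue_index}: delta_comb must be finite and >= 0, "
                f"got {self.delta_comb!r}"
            )


@dataclass
class EpitopeMap:
    """Per-residue interaction classes for one ligand."""

    ligand_label: str
    sigma0: float
    classes: dict[int, InteractionClass]
    delta_comb: dict[int, float] = field(default_factory=dict)

    @property
    def interacting_residues(self) -> set[int]:
        return {i for i, c in self.classes.items() if c.interacting}

    @property
    def high_residues(self) -> set[int]:
        return {i for i, c in self.classes.items() if c.high_confidence}


def atom_weight(atom: str, weights: Mapping[str, float] | None = None) -> float:
    """Resolve the combined-shift weight for one atom label.

    Exact labels take precedence over element-letter defaults; an atom
    whose element has no weight is a configuration error.
    """
    table = DEFAULT_ATOM_WEIGHTS if weights is None else weights
    if atom in table:
        return float(table[atom])
    element = atom[:1].upper()
    if element in table:
        return float(table[element])
    raise KeyError(
        f"no weight configured for atom {atom!r} (element {element!r}); "
        f"known keys: {sorted(table)}"
    )


def combined_shift(
    atom_deltas: Mapping[str, float], weights: Mapping[str, float] | None = None
) -> float:
    """Weighted Euclidean norm of per-atom shift changes (ppm)."""
    if not atom_deltas:
        raise ValueError("combined_shift needs at least one atom")
    total = 0.0
    for atom, delta in atom_deltas.items():
        w = atom_weight(atom, weights)
        total += (w * delta) ** 2
    return float(np.sqrt(total))


def perturbation_profile(
    free_peaks: Mapping[tuple[int, str], float],
    bound_peaks: Mapping[tuple[int, str], float],
    weights: Mapping[str, float] | None = None,
    residue_codes: Mapping[int, str] | None = None,
) -> list[ResiduePerturbation]:
    """Per-residue perturbations from endpoint peak sets.

    ``free_peaks`` and ``bound_peaks`` map ``(residue_index, atom)`` to the
    shift (ppm) in the free protein and at the final titration point.
    Residues with at least one atom present in both sets are measured;
    residues observed free but with no surviving bound peak are flagged
    disappeared (their ``delta_comb`` stays NaN until imputation); residues
    absent from the free list are not evaluable (e.g. prolines).
    """
    codes = residue_codes or {}
    residues: dict[int, dict[str, float]] = {}
    free_atoms: dict[int, set[str]] = {}
    for (idx, atom), free_shift in free_peaks.items():
        free_atoms.setdefault(idx, set()).add(atom)
        if (idx, atom) in bound_peaks:
            residues.setdefault(idx, {})[atom] = bound_peaks[(idx, atom)] - free_shift

    out: list[ResiduePerturbation] = []
    all_indices = sorted(set(free_atoms) | {i for i, _ in bound_peaks})
    for idx in all_indices:
        code = codes.get(idx, "X")
        if idx not in free_atoms:
            out.append(ResiduePerturbation(idx, code, float("nan"), ResidueStatus.NOT_EVALUABLE))
        elif idx in residues:
            out.append(
                ResiduePerturbation(
                    idx, code, combined_shift(residues[idx], weights), ResidueStatus.MEASURED
                )
            )
        else:
            out.append(ResiduePerturbation(idx, code, float("nan"), ResidueStatus.DISAPPEARED))
    return out


def sigma0(profile: Iterable[ResiduePerturbation]) -> float:
    """Population standard deviation of the measured perturbations (ppm).

    Disappeared and not-evaluable residues are excluded, so the imputation
    of disappeared residues at ``2 sigma0`` cannot influence the threshold
    it depends on.
    """
    vals = [p.delta_comb for p in profile if p.status is ResidueStatus.MEASURED]
    if len(vals) < 3:
        raise ValueError(
            f"need at least 3 measured residues to estimate sigma0, got {len(vals)}"
        )
    return float(np.std(vals))  # population (ddof=0)


def classify_residues(
    profile: Sequence[ResiduePerturbation],
    sigma0_value: float,
    ligand_label: str = "",
) -> EpitopeMap:
    """Classify residues against the ``sigma0`` / ``2 sigma0`` thresholds.

    Measured residues: ``< sigma0`` — none; ``[sigma0, 2 sigma0)`` —
    moderate; ``>= 2 sigma0`` — high.  Disappeared residues are imputed at
    ``2 sigma0`` and classed disappeared-high; the rest are not evaluable.
    """
    if not (np.isfinite(sigma0_value) and sigma0_value > 0):
        raise ValueError(f"sigma0 must be positive, got {sigma0_value!r}")
    classes: dict[int, InteractionClass] = {}
    values: dict[int, float] = {}
    for p in profile:
        if p.status is ResidueStatus.MEASURED:
            values[p.residue_index] = p.delta_comb
            if p.delta_comb >= 2.0 * sigma0_value:
                classes[p.residue_index] = InteractionClass.HIGH
            elif p.delta_comb >= sigma0_value:
                classes[p.residue_index] = InteractionClass.MODERATE
            else:
                classes[p.residue_index] = InteractionClass.NONE
        elif p.status is ResidueStatus.DISAPPEARED:
            values[p.residue_index] = 2.0 * sigma0_value
            classes[p.residue_index] = InteractionClass.DISAPPEARED_HIGH
        else:
            classes[p.residue_index] = InteractionClass.NOT_EVALUABLE
    return EpitopeMap(ligand_label, float(sigma0_value), classes, values)


def consensus_epitope(maps: Sequence[EpitopeMap]) -> set[int]:
    """Residues forming the cross-ligand consensus epitope.

    A residue is kept iff it is high-confidence (high or disappeared-high)
    in at least one map and at least moderate (any interacting class) in
    every other map.  Requires >= 2 maps over the same residue index space;
    symmetric in the order of the maps.
    """
    if len(maps) < 2:
        raise ValueError(f"a consensus needs at least 2 epitope maps, got {len(maps)}")
    spaces = [set(m.classes) for m in maps]
    if any(s != spaces[0] for s in spaces[1:]):
        raise ValueError("epitope maps cover different residue index spaces")
    consensus: set[int] = set()
    for idx in spaces[0]:
        klasses = [m.classes[idx] for m in maps]
        if any(k.high_confidence for k in klasses) and all(k.interacting for k in klasses):
            consensus.add(idx)
    return consensus
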