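"""Measured dissociation constants of TmCsp–heptanucleotide complexes.

Per-site dissociation constants of the Thermotoga maritima cold shock
protein bound to single-stranded homo-heptanucleotides, determined by
quenching of the intrinsic tryptophan fluorescence at three temperatures
and assuming two independent, identical protein-binding sites per
heptamer.  These values serve as ground truths for the synthetic-data
studies and as fixed inputs to the NMR stoichiometry fits.

Temperatures (K): 343 is near the physiological growth temperature of
T. maritima, 323 the onset of the cold-shock range, 303 full cold shock.
The three-orders-of-magnitude affinity gain of (dT)7 and (rU)7 on cooling
is the temperature-sensing signature this protein is studied for.
"""

from __future__ import annotations

__all__ = ["KD_TABLE", "kd", "kd_uncertainty", "OLIGONUCLEOTIDES", "TEMPERATURES"]

# (oligonucleotide, temperature K) -> (K_D in mol/L, standard uncertainty in mol/L)
KD_TABLE: dict[tuple[str, int], tuple[float, float]] = {
    ("dA7", 303): (5.0e-6, 0.2e-6),
    ("dA7", 323): (19.2e-6, 0.5e-6),
    ("dA7", 343): (25.2e-6, 0.6e-6),
    ("dC7", 303): (2.8e-6, 0.1e-6),
    ("dC7", 343): (11.0e-6, 0.1e-6),
    ("dG7", 303): (3.4e-6, 0.1e-6),
    ("dG7", 343): (5.6e-6, 0.1e-6),
    ("dT7", 303): (4.0e-9, 0.2e-9),
    ("dT7", 323): (0.44e-6, 0.02e-6),
    ("dT7", 343): (1.6e-6, 0.04e-6),
    ("rU7", 303): (10.8e-9, 0.8e-9),
    ("rU7", 323): (1.52e-6, 0.01e-6),
    ("rU7", 343): (17.4e-6, 0.1e-6),
}

OLIGONUCLEOTIDES = tuple(sorted({k[0] for k in KD_TABLE}))
TEMPERATURES = tuple(sorted({k[1] for k in KD_TABLE}))


def kd(oligo: str, temperature: int) -> float:
    """Per-site dissociation constant (mol/L) for ``oligo`` at ``temperature`` K."""
    try:
        return KD_TABLE[(oligo, temperature)][0]
    except KeyError:
        raise KeyError(
            f"no measured K_D for {oligo!r} at {temperature} K; "
            f"available: {sorted(KD_TABLE)}"
        ) from None


def kd_uncertainty(oligo: str, temperature: int) -> float:
    """Standard uncertainty (mol/L) of the tabulated dissociation constant."""
    try:
        return KD_TABLE[(oligo, temperature)][1]
    except KeyError:
        raise KeyError(
            f"no measured K_D for {oligo!r} at {temperature} K"
        ) from None
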