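"""Concentration unit handling.

Titration inputs quote concentrations in whatever unit is natural for the
experiment (nM protein in fluorescence, mM in NMR); everything internal is
mol/L.
"""

from __future__ import annotations

import re

__all__ = ["CONCENTRATION_UNITS", "to_molar", "parse_concentration", "format_concentration"]

CONCENTRATION_UNITS: dict[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}

_CONC_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(M|mM|uM|µM|nM|pM)\s*$")


def to_molar(value: float, unit: str) -> float:
    """Convert ``value`` expressed in ``unit`` to mol/L."""
    try:
        factor = CONCENTRATION_UNITS[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(CONCENTRATION_UNITS)}"
        ) from None
    return float(value) * factor


def parse_concentration(text: str | float) -> float:
    """Parse ``'5 nM'``, ``'0.5mM'`` or a bare number (taken as mol/L)."""
    if isinstance(text, (int, float)):
        return float(text)
    m = _CONC_RE.match(text)
    if m is None:
        try:
            return float(text)
        except ValueError:
            raise ValueError(f"cannot parse concentration {text!r}") from None
    return to_molar(float(m.group(1)), m.group(2))


def format_concentration(molar: float) -> str:
    """Render mol/L in the largest unit giving a mantissa >= 1."""
    for unit in ("M", "mM", "uM", "nM", "pM"):
        if abs(molar) >= CONCENTRATION_UNITS[unit] or unit == "pM":
            return f"{molar / CONCENTRATION_UNITS[unit]:g} {unit}"
    return f"{molar:g} M"
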