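"""Monoisotopic mass constants and small-molecule arithmetic.

Element and amino-acid residue masses come from :mod:`pyteomics.mass`;
only the handful of constants used throughout the package are re-exported
here so that every module agrees on the same values.
"""

from __future__ import annotations

import re

from pyteomics import mass as _pmass

#: Mass of a proton, Da (charge carrier for protonated ions).
PROTON: float = 1.007276

#: Monoisotopic mass of water, Da.
WATER: float = _pmass.calculate_mass(formula="H2O")

#: Monoisotopic mass of ammonia, Da (c ions = b + NH3).
NH3: float = _pmass.calculate_mass(formula="NH3")

#: Monoisotopic mass of a hydrogen atom, Da (z-dot convention).
H_ATOM: float = _pmass.nist_mass["H"][0][0]

#: Monoisotopic residue masses of the 20 standard amino acids, Da.
AA_RESIDUE_MASS: dict[str, float] = dict(_pmass.std_aa_mass)

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse an elemental formula like ``C8H13NO5`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed elemental formula: {text!r}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        if elem not in _pmass.nist_mass:
            raise ValueError(f"unknown element {elem!r} in formula {text!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(text) or not counts:
        raise ValueError(f"malformed elemental formula: {text!r}")
    return counts


def formula_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass of an element-count mapping, Da."""
    return sum(_pmass.nist_mass[el][0][0] * n for el, n in formula.items())


def peptide_mass(sequence: str, mod_deltas: float = 0.0) -> float:
    """Neutral monoisotopic mass of a peptide, Da (residues + water + mods)."""
    try:
        residues = sum(AA_RESIDUE_MASS[a] for a in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown amino acid {exc.args[0]!r} in {sequence!r}") from None
    return residues + WATER + mod_deltas


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of a neutral mass carrying ``charge`` protons."""
    return neutral_mass / charge + PROTON


def neutral_mass(mz_value: float, charge: int) -> float:
    """Neutral mass corresponding to an observed m/z at a given charge."""
    return (mz_value - PROTON) * charge


def ppm_window(mass: float, ppm: float) -> float:
    """Half-width of a +-ppm tolerance window around ``mass``."""
    return abs(mass) * ppm * 1e-6
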