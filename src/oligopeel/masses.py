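"""Atomic masses and repeat-unit constants for ethoxylate / propoxylate arithmetic.

Two mass scales are kept throughout the package:

* ``monoisotopic`` — lowest-isotope masses, appropriate for matching
  individual centroided peaks.
* ``average`` — standard atomic weights, appropriate for matching the apex
  of a broad, isotope-unresolved envelope.

Formulas are parsed with :class:`pyteomics.mass.Composition`; the element
tables here are deliberately small (the elements occurring in ethoxylated
surfactant raw materials) so the arithmetic is auditable.
"""

from __future__ import annotations

from pyteomics.mass import Composition

MONOISOTOPIC: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
    "K": 38.9637064864,
    "S": 31.97207069,
    "P": 30.97376151,
}

#: Standard atomic weights (abridged to the precision used in practice).
AVERAGE: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "K": 39.098,
    "S": 32.06,
    "P": 30.974,
}

MassMode = str  # "monoisotopic" | "average"


def formula_mass(formula: str, mode: MassMode = "monoisotopic") -> float:
    """Mass of an elemental formula such as ``"C3H8O3"`` on the chosen scale."""
    if mode == "monoisotopic":
        table = MONOISOTOPIC
    elif mode == "average":
        table = AVERAGE
    else:
        raise ValueError(f"unknown mass mode: {mode!r}")
    comp = Composition(formula=formula)
    try:
        return sum(count * table[el] for el, count in comp.items())
    except KeyError as exc:  # pragma: no cover - config error path
        raise ValueError(f"element {exc} not in mass table") from exc


# Repeat units of the two common alkoxylation monomers.
EO_MASS_MONO = formula_mass("C2H4O", "monoisotopic")  # 44.0262 Da
EO_MASS_AVG = formula_mass("C2H4O", "average")  # 44.053 Da
PO_MASS_MONO = formula_mass("C3H6O", "monoisotopic")  # 58.0419 Da
PO_MASS_AVG = formula_mass("C3H6O", "average")  # 58.080 Da

# Sodium cation adduct ([M+Na]+); the electron mass is far below any
# tolerance used here and is ignored.
SODIUM_MONO = MONOISOTOPIC["Na"]
SODIUM_AVG = AVERAGE["Na"]

#: +1 isotopologue offset (13C - 12C).
ISOTOPE_SPACING = 1.0034


def nominal_mass(mass: float) -> int:
    """Nearest-integer (nominal) mass of a monoisotopic value."""
    return int(round(mass))


def eo_mass(mode: MassMode) -> float:
    return EO_MASS_MONO if mode == "monoisotopic" else EO_MASS_AVG


def adduct_mass(adduct: str, mode: MassMode) -> float:
    """Mass of a cationizing adduct given by name ('Na', 'K') or formula."""
    table = MONOISOTOPIC if mode == "monoisotopic" else AVERAGE
    if adduct in table:
        return table[adduct]
    return formula_mass(adduct, mode)
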