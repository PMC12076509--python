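"""Element data: atomic numbers, covalent and van der Waals radii.

Radii come from gemmi's built-in tables (Cordero-type covalent radii,
Bondi-type vdW radii). Both tables can be overridden per element, which keeps
the bond-perception cutoff and the steric descriptors configurable without
editing any data file.
"""
from __future__ import annotations

import gemmi

__all__ = [
    "atomic_number",
    "covalent_radius",
    "vdw_radius",
    "is_metal",
    "normalize_symbol",
]

#: Elements treated as nonmetals for the counter-ion filter.  Metalloids that
#: can sit in a porphyrin pocket (Si, Ge, As, Sb, Te) are deliberately *not*
#: listed here as counter-ion metals are the concern, but they are accepted as
#: central atoms by the macrocycle module regardless of this set.
_NONMETALS = {
    "H", "He", "B", "C", "N", "O", "F", "Ne", "Si", "P", "S", "Cl", "Ar",
    "As", "Se", "Br", "Kr", "Te", "I", "Xe", "At", "Rn",
}


class UnknownElementError(KeyError):
    """Raised when an element symbol is not in the periodic table."""


def normalize_symbol(symbol: str) -> str:
    """Return the capitalized element symbol, validating it exists."""
    s = symbol.strip()
    # strip CIF-style labels such as "C12A" or charges such as "Fe3+"
    core = "".join(ch for ch in s if ch.isalpha())
    if not core:
        raise UnknownElementError(symbol)
    cand = core[:2].capitalize()
    if len(core) >= 2 and gemmi.Element(cand).atomic_number > 0 and cand != "D":
        sym = cand
    else:
        sym = core[0].upper()
    el = gemmi.Element(sym)
    if el.atomic_number == 0:
        raise UnknownElementError(symbol)
    return el.name


def _element(symbol: str) -> gemmi.Element:
    el = gemmi.Element(symbol.capitalize())
    if el.atomic_number == 0:
        raise UnknownElementError(symbol)
    return el


def atomic_number(symbol: str) -> int:
    return _element(symbol).atomic_number


def covalent_radius(symbol: str, overrides: dict[str, float] | None = None) -> float:
    """Covalent radius in Å (Cordero-type table)."""
    if overrides and symbol in overrides:
        return overrides[symbol]
    return float(_element(symbol).covalent_r)


def vdw_radius(symbol: str, overrides: dict[str, float] | None = None) -> float:
    """van der Waals radius in Å (Bondi-type table)."""
    if overrides and symbol in overrides:
        return overrides[symbol]
    return float(_element(symbol).vdw_r)


def is_metal(symbol: str) -> bool:
    return _element(symbol).name not in _NONMETALS
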