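"""Periodic-table element descriptors for element-embracing symmetry functions.

Each supported element (periods 1-5, H through Xe) carries three integer
descriptors read off the periodic table:

* ``n`` -- the period number (1-5),
* ``m`` -- the main-group number (1-8) for s/p-block elements, 0 for the
  d-block; helium counts as a noble gas with ``m = 8``,
* ``d`` -- the d-block group number (IUPAC groups 3-12), 0 for main-group
  elements.

These numbers weight neighbor contributions in the element-embracing
atom-centered symmetry functions so that the descriptor vector length does
not grow with the number of chemical elements.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ElementInfo", "element_descriptors", "supported_elements", "UnsupportedElementError"]

MAX_PERIOD = 5

# Symbols in order of atomic number, Z = 1 .. 54 (periods 1-5).
_SYMBOLS = (
    "H He "
    "Li Be B C N O F Ne "
    "Na Mg Al Si P S Cl Ar "
    "K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr "
    "Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe"
).split()

# (first Z, last Z) per period.
_PERIOD_RANGES = {1: (1, 2), 2: (3, 10), 3: (11, 18), 4: (19, 36), 5: (37, 54)}


class UnsupportedElementError(ValueError):
    """Raised for symbols outside the supported periods 1-5 table."""


@dataclass(frozen=True)
class ElementInfo:
    """Element descriptors (period ``n``, main group ``m``, d-group ``d``)."""

    symbol: str
    n: int
    m: int
    d: int


def _build_table() -> dict[str, ElementInfo]:
    table: dict[str, ElementInfo] = {}
    for z, symbol in enumerate(_SYMBOLS, start=1):
        period = next(p for p, (lo, hi) in _PERIOD_RANGES.items() if lo <= z <= hi)
        pos = z - _PERIOD_RANGES[period][0] + 1  # position within the period
        if period == 1:
            # H is group 1; He is treated as a noble gas (m = 8).
            m, d = (1, 0) if symbol == "H" else (8, 0)
        elif period in (2, 3):
            m, d = pos, 0
        else:  # periods 4-5, 18 positions: s-block, d-block, p-block
            if pos <= 2:
                m, d = pos, 0
            elif pos <= 12:
                m, d = 0, pos  # IUPAC group number equals the column, 3-12
            else:
                m, d = pos - 10, 0
        table[symbol] = ElementInfo(symbol, period, m, d)
    return table


_TABLE = _build_table()


def supported_elements() -> tuple[ElementInfo, ...]:
    """All 54 supported elements in order of atomic number."""
    return tuple(_TABLE[s] for s in _SYMBOLS)


def element_descriptors(symbol: str) -> tuple[int, int, int]:
    """Return the ``(n, m, d)`` descriptor triple for an element symbol.

    Raises
    ------
    UnsupportedElementError
        If the symbol is unknown or belongs to a period above 5.
    """
    try:
        info = _TABLE[symbol]
    except KeyError:
        raise UnsupportedElementError(
            f"element {symbol!r} is not supported (periods 1-{MAX_PERIOD}, H-Xe)"
        ) from None
    return info.n, info.m, info.d


def element_info(symbol: str) -> ElementInfo:
    """Return the full :class:`ElementInfo` record for a symbol."""
    element_descriptors(symbol)  # validates, raising for unsupported symbols
    return _TABLE[symbol]
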