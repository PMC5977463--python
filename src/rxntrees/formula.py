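"""Molecular-formula arithmetic.

Reference molecular weights for the bundled worked examples are computed
from plain Hill-style formulas (``C10H16N5O13P3``) using conventional
IUPAC atomic weights.  Only the elements that occur in small-molecule
metabolism are tabulated; anything else is a hard error rather than a
silent zero.
"""

from __future__ import annotations

import re

__all__ = ["formula_weight", "ATOMIC_WEIGHTS"]

# Conventional (abridged) IUPAC atomic weights, g/mol.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Na": 22.990,
    "K": 39.098,
    "Cl": 35.45,
    "Mg": 24.305,
    "Ca": 40.078,
    "Fe": 55.845,
    "Zn": 65.38,
    "Se": 78.971,
    "Co": 58.933,
    "Cu": 63.546,
    "Mn": 54.938,
    "I": 126.904,
    "Br": 79.904,
    "F": 18.998,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_weight(formula: str) -> float:
    """Molecular weight (g/mol) of a simple chemical formula.

    Parses element symbols with optional integer counts, e.g. ``H2O`` or
    ``C17H21N4O9P``.  Parenthesised groups and symbolic subscripts (``n``)
    are rejected: formulas with undefined repeat counts cannot be weighed.
    """
    if not formula:
        raise ValueError("empty formula")
    pos = 0
    total = 0.0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(
                f"unparseable formula {formula!r} at position {pos}"
            )
        symbol, count = match.group(1), match.group(2)
        if symbol not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {symbol!r} in formula {formula!r}")
        total += ATOMIC_WEIGHTS[symbol] * (int(count) if count else 1)
        pos = match.end()
    if pos != len(formula):
        raise ValueError(f"unparseable formula {formula!r} at position {pos}")
    return round(total, 3)
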