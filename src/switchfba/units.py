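"""Small unit helpers: molecular weights from elemental formulas."""

from __future__ import annotations

import re

# standard atomic weights (g/mol), elements common in metabolite formulas
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Na": 22.990, "K": 39.098, "Mg": 24.305, "Ca": 40.078,
    "Fe": 55.845, "Zn": 65.38, "Cl": 35.45, "Se": 78.971, "Co": 58.933,
    "Cu": 63.546, "Mn": 54.938, "Mo": 95.95, "Ni": 58.693,
}

_ELEM = re.compile(r"([A-Z][a-z]?)(\d*)")


def molecular_weight(formula: str) -> float:
    """Molecular weight in g/mol of a flat elemental formula like C32H26O14.

    Raises ValueError on unknown elements or unparseable input.
    """
    pos, total = 0, 0.0
    for m in _ELEM.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        elem, count = m.group(1), int(m.group(2) or 1)
        if elem not in ATOMIC_MASS:
            raise ValueError(f"unknown element {elem!r} in formula {formula!r}")
        total += ATOMIC_MASS[elem] * count
    if pos != len(formula) or total == 0.0:
        raise ValueError(f"cannot parse formula {formula!r}")
    return total


def ug_per_h_to_mmol(rate_ug: float, mw_g_per_mol: float) -> float:
    """Convert μg/gDW/h to mmol/gDW/h given a molecular weight in g/mol."""
    return rate_ug / mw_g_per_mol / 1000.0
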