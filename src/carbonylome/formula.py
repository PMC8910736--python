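"""Elemental formulas and exact-mass arithmetic.

All annotation in this package runs on monoisotopic masses of small
cations observed in positive-mode electrospray.  A formula is a plain
element -> count mapping plus an integer charge; for a protonated cation
([M + H]+) the hydrogen count already includes the ionizing proton and
the electron mass is subtracted from the summed atomic masses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ElementalFormula",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "monoisotopic_mass",
    "ppm_error",
]

#: Monoisotopic atomic masses (Da) of the most abundant isotope,
#: CODATA/IUPAC values.  The element set covers organic molecules with
#: optional phosphorus/sulfur, which is all this chemistry needs.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

#: Electron rest mass in Da; subtracted once per positive charge.
ELECTRON_MASS = 0.00054858

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element->count map for a neutral molecule or a singly charged cation.

    Parameters
    ----------
    counts : dict
        Mapping of element symbol to a non-negative integer count.
    charge : int
        0 for a neutral molecule, +1 for a protonated cation.
    """

    counts: dict[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if sym not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, (int,)) or n < 0:
                raise ValueError(f"negative or non-integer count for {sym}: {n}")
            if n > 0:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", clean)

    # -- construction ------------------------------------------------
    @classmethod
    def parse(cls, text: str, charge: int = 0) -> "ElementalFormula":
        """Parse a Hill-notation formula string such as ``"C17H22N3O5"``.

        A trailing ``+`` sets charge +1.
        """
        text = text.strip()
        if text.endswith("+"):
            charge = 1
            text = text[:-1]
        counts: dict[str, int] = {}
        pos = 0
        for m in _TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
            pos = m.end()
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        return cls(counts, charge)

    # -- arithmetic --------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return ElementalFormula(counts, self.charge + other.charge)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) - n
            if counts[sym] < 0:
                raise ValueError(
                    f"subtraction yields negative count for {sym}: "
                    f"{self.hill()} - {other.hill()}"
                )
        return ElementalFormula(counts, self.charge - other.charge)

    def contains(self, other: "ElementalFormula") -> bool:
        """True if every element count of *other* fits inside this formula."""
        return all(self.counts.get(sym, 0) >= n for sym, n in other.counts.items())

    def get(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    # -- presentation ------------------------------------------------
    def hill(self) -> str:
        """Hill-order string: C, H, then other elements alphabetically."""
        order = [s for s in ("C", "H") if s in self.counts]
        order += sorted(s for s in self.counts if s not in ("C", "H"))
        body = "".join(
            f"{s}{self.counts[s]}" if self.counts[s] > 1 else s for s in order
        )
        return body + ("+" * self.charge if self.charge > 0 else "")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass (neutral) or m/z (charge +1) of a formula, in Da.

    The sum of atomic monoisotopic masses minus one electron mass per
    positive charge.  For protonated cations the H count must already
    include the ionizing proton (compositions of [M + H]+ ions are
    conventionally written that way).
    """
    if formula.charge not in (0, 1):
        raise ValueError(f"only charge 0 or +1 supported, got {formula.charge}")
    total = sum(MONOISOTOPIC_MASS[sym] * n for sym, n in formula.counts.items())
    return total - formula.charge * ELECTRON_MASS


def ppm_error(observed_mz: float, calculated_mz: float) -> float:
    """Relative mass error in parts per million.

    Defined as ``(calculated - observed) / calculated * 1e6``, the sign
    convention under which an observed m/z above the theoretical value
    gives a negative error.
    """
    if observed_mz <= 0 or calculated_mz <= 0:
        raise ValueError("m/z values must be positive")
    return (calculated_mz - observed_mz) / calculated_mz * 1e6
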