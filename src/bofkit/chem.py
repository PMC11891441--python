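"""Elemental formulas: parsing, arithmetic and molar-mass evaluation.

This module is the numeric substrate for every unit conversion and balance
check in the package.  Formulas are plain element→count mappings with an
optional net charge; counts may be fractional because pseudo-metabolite
formulas are stoichiometry-weighted combinations of their constituents.

Atomic weights are bundled (IUPAC 2021 standard atomic weights, conventional
values for the interval elements) so that balance arithmetic never depends
on an external package version.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .errors import ChemistryError, FormulaParseError

#: IUPAC 2021 standard atomic weights (g/mol); conventional single values
#: are used for elements whose standard weight is an interval.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "He": 4.002602,
    "Li": 6.94,
    "Be": 9.0121831,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998403163,
    "Ne": 20.1797,
    "Na": 22.98976928,
    "Mg": 24.305,
    "Al": 26.9815384,
    "Si": 28.085,
    "P": 30.973761998,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.95,
    "K": 39.0983,
    "Ca": 40.078,
    "Ti": 47.867,
    "V": 50.9415,
    "Cr": 51.9961,
    "Mn": 54.938043,
    "Fe": 55.845,
    "Co": 58.933194,
    "Ni": 58.6934,
    "Cu": 63.546,
    "Zn": 65.38,
    "As": 74.921595,
    "Se": 78.971,
    "Br": 79.904,
    "Rb": 85.4678,
    "Sr": 87.62,
    "Mo": 95.95,
    "Ag": 107.8682,
    "Cd": 112.414,
    "Sn": 118.71,
    "I": 126.90447,
    "Cs": 132.90545196,
    "Ba": 137.327,
    "W": 183.84,
    "Hg": 200.592,
    "Pb": 207.2,
}

#: Placeholder symbols that occur in curated GEM formulas for generic
#: residues.  They parse fine but have no mass: molar-mass evaluation over
#: a formula containing one raises :class:`ChemistryError`.
PSEUDO_ELEMENTS: frozenset[str] = frozenset({"R", "X"})

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+(?:\.\d+)?|\.\d+)?")


@dataclass(frozen=True)
class Formula:
    """An elemental formula: element→count map plus optional net charge.

    ``charge`` is ``None`` when unknown (never silently zero); combining a
    formula of unknown charge with anything yields unknown charge.
    """

    counts: Mapping[str, float] = field(default_factory=dict)
    charge: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "counts", dict(self.counts))

    def __getitem__(self, element: str) -> float:
        return self.counts.get(element, 0.0)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return self.counts == dict(other.counts) and self.charge == other.charge

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Formula({format_formula(self)!r}, charge={self.charge})"

    @property
    def elements(self) -> set[str]:
        return set(self.counts)

    def is_empty(self) -> bool:
        return not self.counts


def parse_formula(formula_string: str, charge: float | None = None) -> Formula:
    """Parse a Hill-style formula string such as ``"C6H12O6"``.

    Counts may be decimal (``"C3.5H7O1.75"``); a missing count means 1;
    repeated symbols are summed.  Symbols must be tabulated elements or one
    of the accepted residue placeholders (``R``, ``X``).

    Raises
    ------
    FormulaParseError
        On an empty string, an unparseable token, or an unknown symbol;
        the error names the offending token and its position.
    """
    if not isinstance(formula_string, str) or not formula_string.strip():
        raise FormulaParseError("empty formula string")
    s = formula_string.strip()
    counts: dict[str, float] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if m is None:
            raise FormulaParseError(
                f"unparseable token {s[pos:]!r} at position {pos} in formula {s!r}",
                token=s[pos:],
                position=pos,
            )
        symbol, count_str = m.group(1), m.group(2)
        if symbol not in ATOMIC_WEIGHTS and symbol not in PSEUDO_ELEMENTS:
            raise FormulaParseError(
                f"unknown element symbol {symbol!r} at position {pos} in formula {s!r}",
                token=symbol,
                position=pos,
            )
        count = 1.0 if count_str is None else float(count_str)
        counts[symbol] = counts.get(symbol, 0.0) + count
        pos = m.end()
    return Formula(counts, charge)


def format_formula(f: Formula) -> str:
    """Serialize in Hill order (C, H, then alphabetical; all alphabetical
    when no carbon).  Fractional counts print with up to 10 decimals,
    trailing zeros trimmed, so output files are deterministic and diffable.
    """
    elements = sorted(f.counts)
    if "C" in f.counts:
        head = [e for e in ("C", "H") if e in f.counts]
        elements = head + [e for e in elements if e not in ("C", "H")]
    parts = []
    for e in elements:
        n = f.counts[e]
        if n == 1:
            parts.append(e)
        else:
            if float(n).is_integer():
                txt = str(int(n))
            else:
                # 10 decimals keeps the serialization residual far below the
                # 1e-6 balance tolerance even after summing over a reaction
                txt = f"{n:.10f}".rstrip("0").rstrip(".")
            parts.append(f"{e}{txt}")
    return "".join(parts)


def molar_mass(f: Formula, table: Mapping[str, float] | None = None) -> float:
    """Molar mass in g/mol: sum of count(e) * weight(e); 0 for empty formula.

    Raises :class:`ChemistryError` naming the element if any element of
    ``f`` has no weight in ``table`` (e.g. residue placeholders R/X).
    """
    weights = ATOMIC_WEIGHTS if table is None else table
    total = 0.0
    for element, count in f.counts.items():
        try:
            w = weights[element]
        except KeyError:
            raise ChemistryError(
                f"no atomic weight for element {element!r}; cannot compute molar mass"
            ) from None
        total += count * w
    return total


def weighted_combine(terms: Iterable[tuple[float, Formula]]) -> Formula:
    """Element-wise linear combination of formulas and charges.

    Coefficients may be negative (byproduct subtraction).  The combined
    charge is ``None`` as soon as any input charge is ``None``.  Elements
    whose combined count is exactly zero are dropped.
    """
    counts: dict[str, float] = {}
    charge: float | None = 0.0
    for coeff, f in terms:
        for element, count in f.counts.items():
            counts[element] = counts.get(element, 0.0) + coeff * count
        if charge is not None:
            charge = None if f.charge is None else charge + coeff * f.charge
    counts = {e: c for e, c in counts.items() if c != 0.0}
    return Formula(counts, charge)
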