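"""Exact-mass arithmetic for small-molecule and peptide ions.

Monoisotopic masses, formula parsing, ion m/z under adduct/charge
hypotheses, and neutral-mass deconvolution.  All cation masses subtract
the electron mass, so e.g. the sodiated phthalate dimer [2M+Na]+ of
C24H38O4 comes out at 803.5432 rather than the 803.5438 a neutral-atom
sum would give.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping

__all__ = [
    "ElementTable",
    "Formula",
    "IonSpecies",
    "DEFAULT_ELEMENTS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "NEUTRON_SURROGATE",
    "parse_formula",
    "monoisotopic_mass",
    "cation_mass",
    "ion_mz",
    "neutral_mass",
    "isotope_spacing",
]

#: Mass of a bare proton (Da).  Used for [M+H]+ deconvolution.
PROTON_MASS = 1.007276

#: Electron rest mass (Da), subtracted when forming cations.
ELECTRON_MASS = 0.000549

#: The 13C-12C mass difference (Da); the m/z spacing between adjacent
#: isotopologues of a singly charged ion.
NEUTRON_SURROGATE = 1.003355


class ElementTable(Mapping[str, float]):
    """Immutable symbol -> monoisotopic mass table (Da).

    The default table covers the CHNOS(+Na, P) chemistry of the
    fermentation metabolites; extend by constructing a new table from
    ``dict(table) | {...}``.
    """

    def __init__(self, masses: Mapping[str, float]):
        self._masses = MappingProxyType(dict(masses))

    def __getitem__(self, symbol: str) -> float:
        return self._masses[symbol]

    def __iter__(self):
        return iter(self._masses)

    def __len__(self) -> int:
        return len(self._masses)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ElementTable({dict(self._masses)!r})"


#: IUPAC 2021 monoisotopic masses of the lightest stable isotopes.
DEFAULT_ELEMENTS = ElementTable(
    {
        "C": 12.000000,
        "H": 1.00782503,
        "N": 14.00307401,
        "O": 15.99491462,
        "Na": 22.98976928,
        "S": 31.97207117,
        "P": 30.97376200,
    }
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental composition: element symbol -> non-negative count.

    Supports addition (multiset union) and integer scaling, which is all
    the arithmetic adduct/dimer bookkeeping needs.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {el: int(n) for el, n in self.counts.items() if n}
        if any(n < 0 for n in clean.values()):
            raise ValueError(f"negative element count in {clean}")
        object.__setattr__(self, "counts", MappingProxyType(clean))

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged)

    def __mul__(self, k: int) -> "Formula":
        return Formula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def hill(self) -> str:
        """Hill-notation string: C first, H second, the rest alphabetic."""
        parts = []
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string like ``"C19H28O"``.

    Raises ``ValueError`` naming the offending symbol when the string
    contains anything that is not an element-count token.
    """
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:m.start()]!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return Formula(counts)


def monoisotopic_mass(
    f: Formula | str, elements: ElementTable = DEFAULT_ELEMENTS
) -> float:
    """Monoisotopic mass (Da) of a formula; additive over formula union."""
    if isinstance(f, str):
        f = parse_formula(f)
    try:
        return sum(n * elements[el] for el, n in f.counts.items())
    except KeyError as exc:
        raise ValueError(f"unknown element symbol {exc.args[0]!r}") from None


@dataclass(frozen=True)
class IonSpecies:
    """A positive ion hypothesis [Mn + adduct]z+.

    ``multiplicity`` is the number of neutral molecules (2 for the
    sodiated dimer [2M+Na]+); ``adduct`` is the charge carrier, H or Na.
    """

    formula: Formula
    multiplicity: int = 1
    adduct: str = "H"
    charge: int = 1

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.adduct not in ("H", "Na"):
            raise ValueError(f"unsupported adduct {self.adduct!r}")


def cation_mass(adduct: str, elements: ElementTable = DEFAULT_ELEMENTS) -> float:
    """Mass of the charge-carrying cation: atom mass minus one electron."""
    if adduct == "H":
        return PROTON_MASS
    return monoisotopic_mass(Formula({adduct: 1}), elements) - ELECTRON_MASS


def ion_mz(ion: IonSpecies, elements: ElementTable = DEFAULT_ELEMENTS) -> float:
    """m/z of an ion: (n*M + z*cation)/z with electron-corrected cations."""
    m = monoisotopic_mass(ion.formula, elements)
    return (ion.multiplicity * m + ion.charge * cation_mass(ion.adduct, elements)) / ion.charge


def neutral_mass(
    mz: float,
    charge: int,
    adduct: str = "H",
    multiplicity: int = 1,
    elements: ElementTable = DEFAULT_ELEMENTS,
) -> float:
    """Deconvolute an observed m/z to the neutral monoisotopic mass.

    Inverse of :func:`ion_mz`: ``(z*mz - z*cation) / n``.  Raises if the
    adduct hypothesis is heavier than the ion itself.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if charge < 1:
        raise ValueError("charge must be >= 1")
    m = (charge * mz - charge * cation_mass(adduct, elements)) / multiplicity
    if m < -1e-9:
        raise ValueError(
            f"adduct {adduct!r} (x{charge}) heavier than ion at m/z {mz}"
        )
    return max(m, 0.0)


def isotope_spacing(charge: int) -> float:
    """m/z spacing between adjacent isotopologues at the given charge."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return NEUTRON_SURROGATE / charge
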