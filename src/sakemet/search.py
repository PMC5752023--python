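"""Candidate generation for a neutral monoisotopic mass.

Two bounded enumerations, emulating a molecular-formula-searcher style
database query: elemental formulas over a per-element count lattice, and
amino-acid residue compositions (order-free peptide candidates, with
leucine/isoleucine collapsed to the single mass-degenerate symbol
``[L/I]``).

Masses above 1000 Da are refused with a warning: formula assignment is
too redundant up there for an exact-mass-only search to be meaningful.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import pandas as pd

from .chem import DEFAULT_ELEMENTS, ElementTable, Formula, monoisotopic_mass, parse_formula

__all__ = [
    "WATER",
    "RESIDUE_FORMULAS",
    "residue_masses",
    "SearchConfig",
    "Candidate",
    "enumerate_formulas",
    "enumerate_peptide_compositions",
    "composition_to_formula",
    "candidates_to_frame",
]

WATER = parse_formula("H2O")
WATER_MASS = monoisotopic_mass(WATER)

#: Residue (not free amino acid) formulas for the 19 mass-distinct
#: standard residues; Leu and Ile share C6H11NO and are reported as the
#: single symbol "[L/I]".  Peptide mass = sum of residues + H2O.
RESIDUE_FORMULAS: Mapping[str, Formula] = {
    "G": parse_formula("C2H3NO"),
    "A": parse_formula("C3H5NO"),
    "S": parse_formula("C3H5NO2"),
    "P": parse_formula("C5H7NO"),
    "V": parse_formula("C5H9NO"),
    "T": parse_formula("C4H7NO2"),
    "C": parse_formula("C3H5NOS"),
    "[L/I]": parse_formula("C6H11NO"),
    "N": parse_formula("C4H6N2O2"),
    "D": parse_formula("C4H5NO3"),
    "Q": parse_formula("C5H8N2O2"),
    "K": parse_formula("C6H12N2O"),
    "E": parse_formula("C5H7NO3"),
    "M": parse_formula("C5H9NOS"),
    "H": parse_formula("C6H7N3O"),
    "F": parse_formula("C9H9NO"),
    "R": parse_formula("C6H12N4O"),
    "Y": parse_formula("C9H9NO2"),
    "W": parse_formula("C11H10N2O"),
}


def residue_masses(elements: ElementTable = DEFAULT_ELEMENTS) -> dict[str, float]:
    """Monoisotopic residue masses derived from :data:`RESIDUE_FORMULAS`."""
    return {sym: monoisotopic_mass(f, elements) for sym, f in RESIDUE_FORMULAS.items()}


#: Default per-element maxima for formula enumeration; generous enough
#: for CHNO(S) metabolites below 1000 Da.
DEFAULT_ELEMENT_BOUNDS: Mapping[str, int] = {"C": 40, "H": 80, "N": 6, "O": 10}


@dataclass
class SearchConfig:
    """Tolerances and bounds for the two enumerations.

    ``tolerance_ppm`` applies unless ``tolerance_mda`` is set, in which
    case the absolute window (milli-Dalton) wins.  Defaults reflect
    orbitrap-class accuracy: 10 ppm for formulas, 5 ppm for peptides.
    """

    tolerance_ppm: float = 10.0
    tolerance_mda: float | None = None
    element_bounds: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ELEMENT_BOUNDS)
    )
    residue_alphabet: Mapping[str, float] = field(
        default_factory=residue_masses
    )
    max_residues: int = 10
    elements: ElementTable = field(default_factory=lambda: DEFAULT_ELEMENTS)

    def __post_init__(self):
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance must be positive")
        if self.tolerance_mda is not None and self.tolerance_mda <= 0:
            raise ValueError("tolerance must be positive")
        if any(b < 0 for b in self.element_bounds.values()):
            raise ValueError("element bounds must be non-negative")

    def window(self, target: float) -> float:
        """Absolute mass window (Da) around ``target``."""
        if self.tolerance_mda is not None:
            return self.tolerance_mda * 1e-3
        return self.tolerance_ppm * 1e-6 * target


@dataclass(frozen=True)
class Candidate:
    """One search hit: a formula or a residue multiset within tolerance."""

    kind: Literal["formula", "peptide-composition"]
    payload: Formula | tuple[tuple[str, int], ...]
    mass: float
    error_ppm: float
    target: float

    def label(self) -> str:
        if self.kind == "formula":
            return self.payload.hill()
        return "".join(
            sym if n == 1 else f"{sym}{n}" for sym, n in self.payload
        )


MAX_SEARCH_MASS = 1000.0


def _check_target(target: float) -> bool:
    if target <= 0:
        raise ValueError("target mass must be positive")
    if target > MAX_SEARCH_MASS:
        warnings.warn(
            f"target {target:.3f} Da exceeds {MAX_SEARCH_MASS:.0f} Da; "
            "formula assignment is too redundant above this mass",
            stacklevel=3,
        )
        return False
    return True


def enumerate_formulas(target: float, cfg: SearchConfig | None = None) -> list[Candidate]:
    """All formulas within the element bounds whose mass matches ``target``.

    Depth-first search over elements in descending mass order, pruning a
    branch as soon as the remaining mass cannot be reached with the
    remaining (lighter) elements.  Result sorted by absolute mass error,
    ties by Hill string.
    """
    cfg = cfg or SearchConfig()
    if not _check_target(target):
        return []
    tol = cfg.window(target)
    elems = sorted(
        cfg.element_bounds.items(), key=lambda kv: cfg.elements[kv[0]], reverse=True
    )
    masses = [cfg.elements[el] for el, _ in elems]
    # max mass attainable from element i onward, for pruning
    suffix_max = [0.0] * (len(elems) + 1)
    for i in range(len(elems) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + masses[i] * elems[i][1]

    hits: list[Candidate] = []
    counts: dict[str, int] = {}

    def dfs(i: int, remaining: float) -> None:
        if i == len(elems):
            if abs(remaining) <= tol:
                f = Formula(counts)
                mass = monoisotopic_mass(f, cfg.elements)
                hits.append(
                    Candidate("formula", f, mass, (mass - target) / target * 1e6, target)
                )
            return
        el, bound = elems[i]
        m = masses[i]
        hi = min(bound, int((remaining + tol) // m)) if remaining + tol >= 0 else -1
        for n in range(0, hi + 1):
            rem = remaining - n * m
            if rem < -tol or rem - tol > suffix_max[i + 1]:
                continue
            if n:
                counts[el] = n
            dfs(i + 1, rem)
            counts.pop(el, None)

    dfs(0, target)
    hits.sort(key=lambda c: (abs(c.error_ppm), c.payload.hill()))
    return hits


def enumerate_peptide_compositions(
    target: float, cfg: SearchConfig | None = None
) -> list[Candidate]:
    """All residue multisets of size <= max whose peptide mass matches.

    Peptide mass = sum of residue masses + H2O.  The composition is
    order-free; Leu/Ile appear as the single symbol ``[L/I]``.
    """
    cfg = cfg or SearchConfig(tolerance_ppm=5.0)
    if not _check_target(target):
        return []
    tol = cfg.window(target)
    residue_target = target - WATER_MASS
    if residue_target < -tol:
        return []
    symbols = sorted(cfg.residue_alphabet, key=cfg.residue_alphabet.get, reverse=True)
    masses = [cfg.residue_alphabet[s] for s in symbols]

    hits: list[Candidate] = []
    comp: dict[str, int] = {}

    def dfs(i: int, remaining: float, used: int) -> None:
        if remaining < -tol:
            return
        if i == len(symbols):
            if abs(remaining) <= tol:
                multiset = tuple(sorted(comp.items()))
                mass = WATER_MASS + sum(
                    n * cfg.residue_alphabet[s] for s, n in multiset
                )
                hits.append(
                    Candidate(
                        "peptide-composition",
                        multiset,
                        mass,
                        (mass - target) / target * 1e6,
                        target,
                    )
                )
            return
        m = masses[i]
        # residues from i on are no heavier than m: prune unreachable mass
        if remaining - tol > (cfg.max_residues - used) * m:
            return
        max_n = min(cfg.max_residues - used, int((remaining + tol) // m))
        for n in range(0, max_n + 1):
            if n:
                comp[symbols[i]] = n
            dfs(i + 1, remaining - n * m, used + n)
            comp.pop(symbols[i], None)

    dfs(0, residue_target, 0)
    hits.sort(key=lambda c: (abs(c.error_ppm), c.label()))
    return hits


def composition_to_formula(residues: Mapping[str, int] | Sequence[tuple[str, int]]) -> Formula:
    """Elemental formula of a peptide: residue formulas plus one water."""
    if not isinstance(residues, Mapping):
        residues = dict(residues)
    total = WATER
    for sym, n in residues.items():
        if sym not in RESIDUE_FORMULAS:
            raise ValueError(f"unknown residue symbol {sym!r}")
        total = total + RESIDUE_FORMULAS[sym] * n
    return total


def candidates_to_frame(candidates: Sequence[Candidate]) -> pd.DataFrame:
    """Tabulate candidates for CSV export."""
    return pd.DataFrame(
        {
            "target_da": [c.target for c in candidates],
            "kind": [c.kind for c in candidates],
            "candidate": [c.label() for c in candidates],
            "theoretical_mass_da": [c.mass for c in candidates],
            "error_ppm": [c.error_ppm for c in candidates],
        }
    )
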