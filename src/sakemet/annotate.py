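"""From selected factors to chemistry.

For each factor (grid cell) chosen by its PC1 rank: locate the
maximum-intensity centroid in the cell (the apex ion), infer the charge
from the isotopologue spacing, deconvolute to a neutral monoisotopic
mass under H+/Na+ adduct hypotheses, attach formula and
peptide-composition candidates, group factors that are isotopologues of
one molecule, and flag known instrument background (phthalate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import search as _search
from .chem import cation_mass, isotope_spacing
from .profile import Factor
from .search import Candidate, SearchConfig
from .simulate import Run

__all__ = [
    "ApexIon",
    "AnnotationConfig",
    "AnnotationRecord",
    "apex_peak",
    "infer_charge",
    "group_isotopologues",
    "annotate",
    "annotate_factors",
    "report_frame",
]


@dataclass(frozen=True)
class ApexIon:
    """The most intense centroid inside a factor's cell."""

    mz: float
    rt: float
    scan: int
    intensity: float


@dataclass(frozen=True)
class BackgroundIon:
    """A known contaminant signature: m/z window late in the gradient."""

    mz: float
    mz_tol: float = 0.01
    rt_after: float = 100.0
    note: str = "instrument background"


#: Diisooctyl phthalate, the ubiquitous LC plasticizer: [M+H]+ and
#: [2M+Na]+ eluting at the hydrophobic end of the gradient.
PHTHALATE_BACKGROUND = (
    BackgroundIon(391.2843, note="diisooctyl phthalate [M+H]+"),
    BackgroundIon(803.5432, note="diisooctyl phthalate [2M+Na]+"),
)


@dataclass
class AnnotationConfig:
    """Knobs of the annotation pipeline.

    Adduct hypotheses are (multiplicity, adduct) pairs tried for every
    factor, [M+H]+ first; the background list is configuration, not
    hard-coded chemistry.
    """

    max_z: int = 3
    tol_ppm: float = 10.0
    formula_cfg: SearchConfig = field(default_factory=SearchConfig)
    peptide_cfg: SearchConfig = field(default_factory=lambda: SearchConfig(tolerance_ppm=5.0))
    hypotheses: tuple[tuple[int, str], ...] = ((1, "H"), (1, "Na"), (2, "Na"))
    background: tuple[BackgroundIon, ...] = PHTHALATE_BACKGROUND
    search_peptides: bool = True
    search_formulas: bool = True


@dataclass
class Hypothesis:
    """One adduct interpretation of the apex with its candidates."""

    multiplicity: int
    adduct: str
    charge: int
    neutral_mass: float
    candidates: list[Candidate]
    not_assignable: bool = False  # > 1000 Da: too redundant to search

    def label(self) -> str:
        m = "M" if self.multiplicity == 1 else f"{self.multiplicity}M"
        z = "+" if self.charge == 1 else f"{self.charge}+"
        return f"[{m}+{self.adduct}]{z}"


@dataclass
class AnnotationRecord:
    """Everything learned about one factor."""

    factor: Factor
    apex: ApexIon
    charge: int
    charge_determined: bool
    hypotheses: list[Hypothesis]
    background: BackgroundIon | None = None
    group_id: str | None = None
    isotope_shift: int = 0
    error: str | None = None

    @property
    def primary(self) -> Hypothesis | None:
        return self.hypotheses[0] if self.hypotheses else None

    @property
    def protonated(self) -> Hypothesis | None:
        """The [M+H]+ reading; the conventional 'calculated exact mass'."""
        for h in self.hypotheses:
            if (h.multiplicity, h.adduct) == (1, "H"):
                return h
        return None

    def best_candidate(self, kind: str | None = None) -> tuple[Hypothesis, Candidate] | None:
        best = None
        for h in self.hypotheses:
            for c in h.candidates:
                if kind is not None and c.kind != kind:
                    continue
                if best is None or abs(c.error_ppm) < abs(best[1].error_ppm):
                    best = (h, c)
        return best


def apex_peak(run: Run, factor: Factor) -> ApexIon:
    """Maximum-intensity centroid within the factor's cell.

    The m/z is reported at full centroid precision, not bin resolution.
    Intensity ties go to the lower m/z.
    """
    mask = (
        (run.scan >= factor.scan_lo)
        & (run.scan < factor.scan_hi)
        & (run.mz >= factor.mz_lo)
        & (run.mz < factor.mz_hi)
    )
    if not mask.any():
        raise ValueError(f"factor {factor.feature_id}: cell is empty in run {run.label}")
    mzs = run.mz[mask]
    ints = run.intensity[mask]
    scans = run.scan[mask]
    top = ints.max()
    tied = np.flatnonzero(ints == top)
    i = tied[np.argmin(mzs[tied])]
    rt = run.rt[mask][i]
    return ApexIon(float(mzs[i]), float(rt), int(scans[i]), float(top))


def infer_charge(
    run: Run, apex: ApexIon, max_z: int = 3, tol_ppm: float = 10.0
) -> tuple[int, bool]:
    """Charge from the isotopologue spacing next to the apex.

    Tries charges from ``max_z`` down to 1 and accepts the first z whose
    companion centroid sits one isotope spacing above the apex (within
    tolerance, in the apex scan or its neighbours, at 1-120 % of the
    apex intensity).  High charges are tried first because a z-charged
    envelope also shows peaks at multiples of its spacing, which lower
    charges would claim.  Returns (z, determined); an isolated peak
    defaults to (1, False).
    """
    near = np.abs(run.scan - apex.scan) <= 1
    mzs = run.mz[near]
    ints = run.intensity[near]
    for z in range(max_z, 0, -1):
        target = apex.mz + isotope_spacing(z)
        tol = tol_ppm * 1e-6 * target
        hit = (
            (np.abs(mzs - target) <= tol)
            & (ints >= 0.01 * apex.intensity)
            & (ints <= 1.2 * apex.intensity)
        )
        if hit.any():
            return z, True
    return 1, False


def group_isotopologues(
    records: Sequence[AnnotationRecord], tol_ppm: float = 10.0, max_shift: int = 5
) -> None:
    """Group factors that are isotopologues of one molecule (in place).

    Record B joins record A's group when their scan bins overlap and
    apex(B) sits an integer number of isotope spacings (at A's charge)
    above apex(A).  The monoisotopic (lowest-m/z) member represents the
    group; members carry their integer shift.
    """
    recs = [r for r in records if r.error is None]
    parent = list(range(len(recs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(recs):
        for j, b in enumerate(recs):
            if i == j:
                continue
            if not (a.factor.scan_lo < b.factor.scan_hi and b.factor.scan_lo < a.factor.scan_hi):
                continue
            delta = b.apex.mz - a.apex.mz
            spacing = isotope_spacing(a.charge)
            k = round(delta / spacing)
            if k >= 1 and abs(delta - k * spacing) <= tol_ppm * 1e-6 * b.apex.mz:
                parent[find(j)] = find(i)

    groups: dict[int, list[AnnotationRecord]] = {}
    for i, r in enumerate(recs):
        groups.setdefault(find(i), []).append(r)
    for members in groups.values():
        rep = min(members, key=lambda r: r.apex.mz)
        if len(members) == 1:
            continue
        spacing = isotope_spacing(rep.charge)
        for r in members:
            r.group_id = rep.factor.feature_id
            r.isotope_shift = round((r.apex.mz - rep.apex.mz) / spacing)


def _match_background(
    apex: ApexIon, background: Sequence[BackgroundIon]
) -> BackgroundIon | None:
    for bg in background:
        if abs(apex.mz - bg.mz) <= bg.mz_tol and apex.rt > bg.rt_after:
            return bg
    return None


def annotate(factor: Factor, run: Run, cfg: AnnotationConfig | None = None) -> AnnotationRecord:
    """Full annotation of one factor: apex -> charge -> mass -> candidates.

    Neutral masses above 1000 Da are reported but not searched (formula
    assignment is too redundant); candidate lists stay empty and the
    hypothesis is marked not assignable.
    """
    cfg = cfg or AnnotationConfig()
    apex = apex_peak(run, factor)
    z, determined = infer_charge(run, apex, cfg.max_z, cfg.tol_ppm)
    hypotheses = []
    for mult, adduct in cfg.hypotheses:
        m = (z * apex.mz - z * cation_mass(adduct)) / mult
        if m <= 0:
            continue
        cands: list[Candidate] = []
        na = m > _search.MAX_SEARCH_MASS
        if not na:
            if cfg.search_formulas:
                cands += _search.enumerate_formulas(m, cfg.formula_cfg)
            if cfg.search_peptides:
                cands += _search.enumerate_peptide_compositions(m, cfg.peptide_cfg)
            cands.sort(key=lambda c: abs(c.error_ppm))
        hypotheses.append(Hypothesis(mult, adduct, z, m, cands, not_assignable=na))
    # rank hypotheses by their best candidate's |ppm|, [M+H]+ winning ties
    hypotheses.sort(
        key=lambda h: min((abs(c.error_ppm) for c in h.candidates), default=np.inf)
    )
    return AnnotationRecord(
        factor=factor,
        apex=apex,
        charge=z,
        charge_determined=determined,
        hypotheses=hypotheses,
        background=_match_background(apex, cfg.background),
    )


def annotate_factors(
    factors: Sequence[Factor], run: Run, cfg: AnnotationConfig | None = None
) -> list[AnnotationRecord]:
    """Annotate a factor list; per-factor failures are recorded, not raised."""
    cfg = cfg or AnnotationConfig()
    records = []
    for f in factors:
        try:
            records.append(annotate(f, run, cfg))
        except ValueError as exc:
            records.append(
                AnnotationRecord(
                    factor=f,
                    apex=ApexIon(np.nan, np.nan, -1, np.nan),
                    charge=0,
                    charge_determined=False,
                    hypotheses=[],
                    error=str(exc),
                )
            )
    group_isotopologues(records, tol_ppm=cfg.tol_ppm)
    return records


def report_frame(records: Sequence[AnnotationRecord]) -> pd.DataFrame:
    """Annotation report table (one row per factor)."""
    rows = []
    for r in records:
        if r.error is not None:
            rows.append({"factor": r.factor.feature_id, "error": r.error})
            continue
        prim = r.protonated or r.primary
        best = r.best_candidate()
        rows.append(
            {
                "factor": r.factor.feature_id,
                "mz_bin": f"{r.factor.mz_lo:g}-{r.factor.mz_hi:g}",
                "scan_bin": f"{r.factor.scan_lo}-{r.factor.scan_hi}",
                "rt_min": round(r.apex.rt, 2),
                "exact_mz": round(r.apex.mz, 4),
                "charge": r.charge if r.charge_determined else f"{r.charge}?",
                "neutral_mass_da": round(prim.neutral_mass, 4) if prim else np.nan,
                "hypothesis": best[0].label() if best else (prim.label() if prim else ""),
                "candidate": best[1].label() if best else "N.A.",
                "candidate_ppm": round(best[1].error_ppm, 2) if best else np.nan,
                "peptide_candidate": (
                    pep[1].label() if (pep := r.best_candidate("peptide-composition")) else ""
                ),
                "n_candidates": sum(len(h.candidates) for h in r.hypotheses),
                "background": r.background.note if r.background else "",
                "isotope_group": r.group_id or "",
                "isotope_shift": r.isotope_shift,
                "error": "",
            }
        )
    return pd.DataFrame(rows)
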