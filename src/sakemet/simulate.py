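"""Synthetic multi-batch, multi-day LC-MS runs with known ground truth.

Emulates the fermentation-monitoring study design: 2 brewing batches x
6 sampling days x 2 technical replicates, each run a 30-115 min
acquisition of 3,000 centroided scans over m/z 200-1000.  Compounds
elute as Gaussian peaks, carry +1/+2 charge states with H+/Na+ adducts
and aggregated isotope envelopes, and follow day-dependent abundance
trajectories; a constant phthalate background (instrument-derived, so
exempt from the per-sample loading factor) and seeded decoy compounds
complete the scene.

The default scenario is the study condition every downstream test runs
against; its parameters are fixed here, not tuned per test.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import (
    DEFAULT_ELEMENTS,
    NEUTRON_SURROGATE,
    Formula,
    cation_mass,
    monoisotopic_mass,
    parse_formula,
)
from .search import composition_to_formula

__all__ = [
    "N_SCANS",
    "RT_MIN",
    "RT_MAX",
    "MZ_MIN",
    "MZ_MAX",
    "scan_times",
    "isotope_envelope",
    "averagine_formula",
    "GroundTruthCompound",
    "NoiseModel",
    "Run",
    "simulate_run",
    "Scenario",
    "default_scenario",
    "ground_truth_table",
    "write_run",
    "read_run",
]

# Acquisition geometry: 3,000 scans spanning the 30-115 min window,
# full-scan m/z range 200-1000 (peaks at exactly 1000 are out of range).
N_SCANS = 3000
RT_MIN = 30.0
RT_MAX = 115.0
MZ_MIN = 200.0
MZ_MAX = 1000.0

#: Relative peak height below which a compound's elution tail is not
#: written out (0.1 % of the line apex).
INTENSITY_FLOOR = 1e-3

#: Heavy-isotope abundances per element: nominal mass shift -> fraction.
ISOTOPE_ABUNDANCES: Mapping[str, Sequence[tuple[int, float]]] = {
    "C": ((0, 0.9893), (1, 0.0107)),
    "H": ((0, 0.999885), (1, 0.000115)),
    "N": ((0, 0.99632), (1, 0.00368)),
    "O": ((0, 0.99757), (1, 0.00038), (2, 0.00205)),
    "S": ((0, 0.9499), (1, 0.0075), (2, 0.0425)),
    "Na": ((0, 1.0),),
    "P": ((0, 1.0),),
}


def scan_times(n_scans: int = N_SCANS) -> np.ndarray:
    """Retention time (min) of each scan: linear over [30, 115)."""
    return RT_MIN + (RT_MAX - RT_MIN) * np.arange(n_scans) / n_scans


def isotope_envelope(f: Formula | str, depth: int = 3) -> np.ndarray:
    """Relative intensities of M, M+1, ... M+(depth-1).

    Element-wise convolution of heavy-isotope abundance polynomials,
    aggregated by nominal mass shift and normalized so M = 1.  Coarse by
    construction (no fine structure), which is all 1-Th binning and
    spacing-based charge inference can see.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if isinstance(f, str):
        f = parse_formula(f)
    total = np.zeros(depth)
    total[0] = 1.0
    for el, n in f.counts.items():
        try:
            iso = ISOTOPE_ABUNDANCES[el]
        except KeyError:
            raise ValueError(f"no isotope data for element {el!r}") from None
        poly = np.zeros(depth)
        for shift, frac in iso:
            if shift < depth:
                poly[shift] = frac
        elem = np.zeros(depth)
        elem[0] = 1.0
        for _ in range(n):
            elem = np.convolve(elem, poly)[:depth]
        total = np.convolve(total, elem)[:depth]
    return total / total[0]


def averagine_formula(mass: float) -> Formula:
    """Integer-rounded averagine composition for a peptide-like mass.

    Used to give compounds specified only by neutral mass a plausible
    isotope envelope.
    """
    scale = mass / 111.1254
    counts = {
        "C": round(4.9384 * scale),
        "H": round(7.7583 * scale),
        "N": round(1.3577 * scale),
        "O": round(1.4773 * scale),
        "S": round(0.0417 * scale),
    }
    return Formula({el: n for el, n in counts.items() if n > 0})


@dataclass(frozen=True)
class IonState:
    """One charge-state hypothesis a compound is generated under."""

    multiplicity: int = 1
    adduct: str = "H"
    charge: int = 1
    weight: float = 1.0


@dataclass
class GroundTruthCompound:
    """A spiked compound: chemistry, elution, ionization and trajectory.

    Exactly one of ``formula`` / ``composition`` / ``neutral`` defines
    the chemistry (a composition is a residue multiset and implies its
    formula; a bare neutral mass gets an averagine envelope).
    ``abundance`` is either a constant or a per-(batch, day) mapping in
    arbitrary ion-count units; it sets the apex height of the Gaussian
    elution profile.  ``is_background`` marks instrument-derived signal
    that does not scale with the amount of sample loaded.
    """

    cid: str
    rt_apex: float
    rt_sigma: float
    abundance: float | Mapping[tuple[str, int], float]
    formula: str | Formula | None = None
    composition: Mapping[str, int] | None = None
    neutral: float | None = None
    ions: tuple[IonState, ...] = (IonState(),)
    envelope_depth: int = 3
    is_background: bool = False

    def __post_init__(self):
        if self.rt_sigma <= 0:
            raise ValueError(f"{self.cid}: rt_sigma must be positive")
        if self.composition is not None:
            self.formula = composition_to_formula(self.composition)
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.formula is not None:
            self.neutral = monoisotopic_mass(self.formula)
        if self.neutral is None:
            raise ValueError(f"{self.cid}: needs a formula, composition or neutral mass")

    def envelope(self) -> np.ndarray:
        f = self.formula if self.formula is not None else averagine_formula(self.neutral)
        return isotope_envelope(f, self.envelope_depth)

    def abundance_on(self, batch: str, day: int) -> float:
        if isinstance(self.abundance, Mapping):
            return self.abundance[(batch, day)]
        return float(self.abundance)


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic imperfections of a run; identical seed -> identical run.

    baseline_density: chemical-noise peaks per scan (uniform in m/z,
    exponential in intensity, scaled by the sample loading); intensity_cv
    is the multiplicative log-normal CV on every signal peak;
    mz_jitter_ppm is the 1-sigma mass-accuracy jitter.
    """

    baseline_density: float = 60.0
    baseline_scale: float = 1000.0
    intensity_cv: float = 0.05
    mz_jitter_ppm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("baseline_density", "baseline_scale", "intensity_cv", "mz_jitter_ppm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


NOISELESS = NoiseModel(baseline_density=0.0, baseline_scale=0.0, intensity_cv=0.0, mz_jitter_ppm=0.0)


@dataclass
class Run:
    """One LC-MS acquisition: centroided peaks over 3,000 scans.

    Peaks are stored as flat, (scan, m/z)-sorted arrays; retention times
    follow the linear scan->time map.
    """

    batch: str
    day: int
    replicate: int
    scan: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray
    n_scans: int = N_SCANS

    def __post_init__(self):
        self.scan = np.asarray(self.scan, dtype=np.int64)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.scan) == len(self.mz) == len(self.intensity)):
            raise ValueError("scan/mz/intensity arrays must have equal length")
        if self.n_scans != N_SCANS:
            raise ValueError(f"a run has exactly {N_SCANS} scans, got {self.n_scans}")
        if len(self.scan) and (self.scan.min() < 0 or self.scan.max() >= self.n_scans):
            raise ValueError("scan index out of range")
        if len(self.mz) and (self.mz.min() < MZ_MIN or self.mz.max() >= MZ_MAX):
            raise ValueError(f"peak m/z outside [{MZ_MIN}, {MZ_MAX})")
        order = np.lexsort((self.mz, self.scan))
        self.scan = self.scan[order]
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def rt(self) -> np.ndarray:
        """Retention time (min) of each peak."""
        return RT_MIN + (RT_MAX - RT_MIN) * self.scan / self.n_scans

    @property
    def label(self) -> str:
        return f"{self.batch}_d{self.day:02d}_r{self.replicate}"

    def __len__(self) -> int:
        return len(self.scan)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Run):
            return NotImplemented
        return (
            (self.batch, self.day, self.replicate) == (other.batch, other.day, other.replicate)
            and np.array_equal(self.scan, other.scan)
            and np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
        )


def _run_seed(seed: int, batch: str, day: int, replicate: int) -> list[int]:
    return [seed % (2**31), zlib.crc32(str(batch).encode()) % (2**31), day, replicate]


def simulate_run(
    compounds: Sequence[GroundTruthCompound],
    noise: NoiseModel,
    batch: str,
    day: int,
    replicate: int,
    sample_loading: float = 1.0,
) -> Run:
    """Generate one run: Gaussian elution x isotope envelope x ionization.

    For every compound, charge state and isotopologue k the generator
    places centroids at ``ion m/z + k * 1.003355/z`` (plus jitter), with
    per-scan height ``abundance x state weight x envelope[k] x
    Gaussian(rt)``, truncated below 0.1 % of the line apex.  Sample-
    derived signal (and the chemical baseline) scales with
    ``sample_loading``; background compounds do not.  Deterministic for
    a given noise seed and run coordinates.
    """
    rng = np.random.default_rng(_run_seed(noise.seed, batch, day, replicate))
    rts = scan_times()
    dt = (RT_MAX - RT_MIN) / N_SCANS
    half_width = np.sqrt(-2.0 * np.log(INTENSITY_FLOOR))  # in units of sigma

    scans_out: list[np.ndarray] = []
    mz_out: list[np.ndarray] = []
    int_out: list[np.ndarray] = []

    for comp in compounds:
        if not (RT_MIN <= comp.rt_apex <= RT_MAX):
            warnings.warn(f"compound {comp.cid} elutes outside the acquisition window; skipped")
            continue
        abund = comp.abundance_on(batch, day)
        if not comp.is_background:
            abund *= sample_loading
        if abund <= 0:
            continue
        env = comp.envelope()
        s0 = max(0, int(np.ceil((comp.rt_apex - half_width * comp.rt_sigma - RT_MIN) / dt)))
        s1 = min(N_SCANS - 1, int(np.floor((comp.rt_apex + half_width * comp.rt_sigma - RT_MIN) / dt)))
        if s1 < s0:
            continue
        scans = np.arange(s0, s1 + 1)
        gauss = np.exp(-0.5 * ((rts[scans] - comp.rt_apex) / comp.rt_sigma) ** 2)
        keep = gauss >= INTENSITY_FLOOR
        scans, gauss = scans[keep], gauss[keep]
        any_in_window = False
        for state in comp.ions:
            base_mz = (
                state.multiplicity * comp.neutral + state.charge * cation_mass(state.adduct)
            ) / state.charge
            for k in range(comp.envelope_depth):
                mzk = base_mz + k * NEUTRON_SURROGATE / state.charge
                if not (MZ_MIN <= mzk < MZ_MAX):
                    continue
                any_in_window = True
                height = abund * state.weight * env[k]
                scans_out.append(scans)
                mz_out.append(np.full(len(scans), mzk))
                int_out.append(height * gauss)
        if not any_in_window:
            warnings.warn(f"compound {comp.cid} has no ion inside the m/z window; skipped")

    if scans_out:
        scan = np.concatenate(scans_out)
        mz = np.concatenate(mz_out)
        inten = np.concatenate(int_out)
    else:
        scan = np.zeros(0, dtype=np.int64)
        mz = np.zeros(0)
        inten = np.zeros(0)

    if noise.intensity_cv > 0 and len(inten):
        s = np.sqrt(np.log1p(noise.intensity_cv**2))
        inten = inten * rng.lognormal(-0.5 * s * s, s, len(inten))
    if noise.mz_jitter_ppm > 0 and len(mz):
        mz = mz * (1.0 + noise.mz_jitter_ppm * 1e-6 * rng.standard_normal(len(mz)))

    if noise.baseline_density > 0:
        nb = rng.poisson(noise.baseline_density * N_SCANS)
        b_scan = rng.integers(0, N_SCANS, nb)
        b_mz = rng.uniform(MZ_MIN, MZ_MAX, nb)
        b_int = rng.exponential(noise.baseline_scale * sample_loading, nb)
        scan = np.concatenate([scan, b_scan])
        mz = np.concatenate([mz, b_mz])
        inten = np.concatenate([inten, b_int])

    ok = (mz >= MZ_MIN) & (mz < MZ_MAX)
    return Run(batch, day, replicate, scan[ok], mz[ok], inten[ok])


# ---------------------------------------------------------------------------
# The default fermentation scenario
# ---------------------------------------------------------------------------

#: Sampling days after the commencement of the main fermentation.
DAY_GRID: Mapping[str, tuple[int, ...]] = {
    "sake_1": (6, 11, 16, 21, 26, 34),
    "sake_2": (1, 5, 11, 19, 26, 34),
}


def _rising_trajectory(day: int, peak: float) -> float:
    """Early-rising saturating trajectory (Hill form, K = 8 days).

    Near-zero at day 1, half-maximal around day 8, saturated by the end
    of the month; the day-34/day-1 ratio is ~37.
    """
    hill = day**2 / (day**2 + 8.0**2)
    return peak * (0.01 + 0.99 * hill)


def sample_loading_factor(day: int) -> float:
    """Per-sample loading of sample-derived material, declining with day.

    Emulates the thinning of the mash matrix as fermentation proceeds;
    global median normalization divides this factor out of sample-derived
    features and thereby imprints its inverse on constant instrument
    background.
    """
    return 1.25 - 0.015 * day


@dataclass
class Scenario:
    """A complete study design: compounds, day grids, replication."""

    compounds: list[GroundTruthCompound]
    day_grid: Mapping[str, tuple[int, ...]] = field(default_factory=lambda: dict(DAY_GRID))
    n_replicates: int = 2
    loading: Callable[[int], float] = sample_loading_factor

    @property
    def batches(self) -> list[str]:
        return list(self.day_grid)

    def runs(self, noise: NoiseModel) -> list[Run]:
        """Simulate every (batch, day, replicate) run of the design."""
        out = []
        for batch, days in self.day_grid.items():
            for day in days:
                for rep in range(1, self.n_replicates + 1):
                    out.append(
                        simulate_run(
                            self.compounds, noise, batch, day, rep,
                            sample_loading=self.loading(day),
                        )
                    )
        return out


def _trajectory_map(peak: float) -> dict[tuple[str, int], float]:
    return {
        (batch, day): _rising_trajectory(day, peak)
        for batch, days in DAY_GRID.items()
        for day in days
    }


def default_scenario(n_decoys: int = 50, seed: int = 101) -> Scenario:
    """The fermentation study condition.

    Six early-rising compounds (four Leu/Ile-rich peptides and two small
    molecules, at their reported retention apexes), a constant diisooctyl
    phthalate background producing [M+H]+ 391.2843 and [2M+Na]+ 803.5432
    late in the gradient, and ``n_decoys`` flat-trajectory decoys.
    """
    rising = [
        GroundTruthCompound("LLL", 64.9, 0.20, _trajectory_map(1.2e6),
                            composition={"[L/I]": 3}),
        GroundTruthCompound("FPL", 64.2, 0.20, _trajectory_map(9.0e5),
                            composition={"[L/I]": 1, "F": 1, "P": 1}),
        GroundTruthCompound("LLLP", 65.9, 0.20, _trajectory_map(1.1e6),
                            composition={"[L/I]": 3, "P": 1}),
        GroundTruthCompound("LLLLP", 70.1, 0.20, _trajectory_map(8.0e5),
                            composition={"[L/I]": 4, "P": 1}),
        GroundTruthCompound("C19H28O", 68.8, 0.22, _trajectory_map(7.0e5),
                            formula="C19H28O"),
        GroundTruthCompound("C17H26N2O3", 70.0, 0.22, _trajectory_map(6.0e5),
                            formula="C17H26N2O3"),
    ]
    phthalate = GroundTruthCompound(
        "DHEP", 103.8, 0.50, 4.0e5, formula="C24H38O4",
        ions=(IonState(1, "H", 1, 1.0), IonState(2, "Na", 1, 0.4)),
        is_background=True,
    )
    rng = np.random.default_rng(seed)
    decoys = []
    while len(decoys) < n_decoys:
        c = int(rng.integers(10, 31))
        h = int(rng.integers(int(1.2 * c), int(2.2 * c) + 1))
        n = int(rng.integers(0, 5))
        o = int(rng.integers(1, 9))
        f = Formula({"C": c, "H": h, "N": n, "O": o})
        mass = monoisotopic_mass(f)
        if not (220.0 <= mass <= 950.0):
            continue
        decoys.append(
            GroundTruthCompound(
                f"decoy{len(decoys):02d}",
                float(rng.uniform(35.0, 100.0)),
                float(rng.uniform(0.15, 0.30)),
                float(rng.lognormal(np.log(1.5e5), 0.5)),
                formula=f,
            )
        )
    return Scenario(compounds=rising + [phthalate] + decoys)


def ground_truth_table(scenario: Scenario) -> pd.DataFrame:
    """Per-(compound, batch, day) true abundances, for recovery checks."""
    rows = []
    for comp in scenario.compounds:
        for batch, days in scenario.day_grid.items():
            for day in days:
                rows.append(
                    {
                        "compound": comp.cid,
                        "formula": comp.formula.hill() if comp.formula is not None else "",
                        "neutral_mass_da": comp.neutral,
                        "rt_apex_min": comp.rt_apex,
                        "batch": batch,
                        "day": day,
                        "abundance": comp.abundance_on(batch, day),
                        "is_background": comp.is_background,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run CSV dialect
# ---------------------------------------------------------------------------

_HEADER = "scan,rt_min,mz,intensity"


def write_run(run: Run, path) -> None:
    """Write the documented CSV dialect: one row per centroid peak."""
    with open(path, "w") as fh:
        fh.write("# sakemet run v1\n")
        fh.write(
            f"# batch={run.batch} day={run.day} replicate={run.replicate} "
            f"n_scans={run.n_scans}\n"
        )
        # full-precision floats so a written run reads back bit-identical
        pd.DataFrame(
            {
                "scan": run.scan,
                "rt_min": run.rt,
                "mz": run.mz,
                "intensity": run.intensity,
            }
        ).to_csv(fh, index=False, float_format="%.17g")


def read_run(path) -> Run:
    """Read a run CSV; validates the declared scan count and every row."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            for token in line[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
        elif line.strip() == _HEADER:
            data_start = i + 1
            break
        elif line.strip():
            raise ValueError(f"{path}: unexpected content at line {i + 1}: {line.strip()!r}")
    else:
        raise ValueError(f"{path}: missing column header {_HEADER!r}")

    n_scans = int(meta.get("n_scans", N_SCANS))
    if n_scans != N_SCANS:
        raise ValueError(f"{path}: declares {n_scans} scans, expected {N_SCANS}")

    import io

    body = "".join(lines[data_start:])
    try:
        df = pd.read_csv(
            io.StringIO(_HEADER + "\n" + body),
            dtype={"scan": np.int64, "rt_min": float, "mz": float, "intensity": float},
            float_precision="round_trip",
        )
    except (ValueError, pd.errors.ParserError):
        # slow path only to point at the offending line
        for ln, line in enumerate(lines[data_start:], start=data_start + 1):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}: malformed row at line {ln}: {line.strip()!r}"
                ) from None
            try:
                int(parts[0]), float(parts[2]), float(parts[3])
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value at line {ln}: {line.strip()!r}"
                ) from None
        raise
    return Run(
        meta.get("batch", "?"),
        int(meta.get("day", 0)),
        int(meta.get("replicate", 0)),
        df["scan"].to_numpy(),
        df["mz"].to_numpy(),
        df["intensity"].to_numpy(),
    )
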