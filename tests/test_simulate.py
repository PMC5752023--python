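"""Synthetic LC-MS generator: envelopes, determinism, conservation, IO."""

import itertools
import math

import numpy as np
import pytest

from sakemet.chem import parse_formula
from sakemet.simulate import (
    DAY_GRID,
    INTENSITY_FLOOR,
    ISOTOPE_ABUNDANCES,
    MZ_MAX,
    MZ_MIN,
    N_SCANS,
    NOISELESS,
    GroundTruthCompound,
    IonState,
    NoiseModel,
    Run,
    default_scenario,
    ground_truth_table,
    isotope_envelope,
    read_run,
    scan_times,
    simulate_run,
    write_run,
)


def envelope_oracle(formula, depth):
    """Full multinomial expansion per element, aggregated by mass shift."""
    f = parse_formula(formula) if isinstance(formula, str) else formula
    dist = {0: 1.0}
    for el, n in f.counts.items():
        isotopes = ISOTOPE_ABUNDANCES[el]
        elem_dist = {}
        shifts = [s for s, _ in isotopes]
        fracs = [p for _, p in isotopes]
        for counts in itertools.product(range(n + 1), repeat=len(isotopes)):
            if sum(counts) != n:
                continue
            coeff = math.factorial(n)
            prob = 1.0
            for k, p in zip(counts, fracs):
                coeff //= math.factorial(k)
                prob *= p**k
            shift = sum(k * s for k, s in zip(counts, shifts))
            elem_dist[shift] = elem_dist.get(shift, 0.0) + coeff * prob
        dist = {
            s1 + s2: sum(
                v1 * v2
                for (s1b, v1) in dist.items()
                for (s2b, v2) in elem_dist.items()
                if s1b + s2b == s1 + s2
            )
            for s1 in dist
            for s2 in elem_dist
        }
    top = max(dist) + 1
    arr = np.zeros(top)
    for s, v in dist.items():
        arr[s] = v
    return (arr / arr[0])[:depth]


class TestIsotopeEnvelope:
    @pytest.mark.parametrize("formula", ["C", "H2O", "C18H35N3O4", "C3H5NOS"])
    def test_matches_multinomial_oracle(self, formula):
        depth = 3
        got = isotope_envelope(formula, depth)
        want = envelope_oracle(formula, depth)
        n = min(len(got), len(want))
        np.testing.assert_allclose(got[:n], want[:n], rtol=1e-10)
        assert np.all(got[n:] == 0)

    def test_single_carbon(self):
        env = isotope_envelope("C", 2)
        assert env[1] / env[0] == pytest.approx(0.0107 / 0.9893, rel=1e-9)

    def test_water_m1_tiny(self):
        env = isotope_envelope("H2O", 2)
        assert env[1] < 1e-3

    def test_normalized_to_monoisotopic(self):
        assert isotope_envelope("C29H53N5O6", 4)[0] == 1.0

    def test_bad_depth(self):
        with pytest.raises(ValueError):
            isotope_envelope("C", 0)


class TestSimulateRun:
    def test_deterministic_under_seed(self):
        sc = default_scenario(n_decoys=5)
        noise = NoiseModel(seed=7)
        r1 = simulate_run(sc.compounds, noise, "sake_1", 6, 1)
        r2 = simulate_run(sc.compounds, noise, "sake_1", 6, 1)
        assert r1 == r2

    def test_different_seeds_differ(self):
        sc = default_scenario(n_decoys=5)
        r1 = simulate_run(sc.compounds, NoiseModel(seed=7), "sake_1", 6, 1)
        r2 = simulate_run(sc.compounds, NoiseModel(seed=8), "sake_1", 6, 1)
        assert r1 != r2

    def test_replicates_differ_only_by_noise(self):
        sc = default_scenario(n_decoys=5)
        noise = NoiseModel(seed=7)
        r1 = simulate_run(sc.compounds, noise, "sake_1", 6, 1)
        r2 = simulate_run(sc.compounds, noise, "sake_1", 6, 2)
        assert r1 != r2
        assert abs(r1.intensity.sum() - r2.intensity.sum()) / r1.intensity.sum() < 0.05

    def test_noiseless_tic_matches_analytic(self, single_compound_run):
        comp, run = single_compound_run
        rts = scan_times()
        gauss = np.exp(-0.5 * ((rts - comp.rt_apex) / comp.rt_sigma) ** 2)
        gauss = gauss[gauss >= INTENSITY_FLOOR]
        expected = 1e6 * gauss.sum() * isotope_envelope(comp.formula, 3).sum()
        assert run.intensity.sum() == pytest.approx(expected, rel=1e-6)

    def test_peaks_within_acquisition_window(self):
        sc = default_scenario(n_decoys=10)
        run = simulate_run(sc.compounds, NoiseModel(seed=3), "sake_2", 34, 1)
        assert run.scan.min() >= 0 and run.scan.max() < N_SCANS
        assert run.mz.min() >= MZ_MIN and run.mz.max() < MZ_MAX

    def test_compound_outside_rt_window_skipped(self):
        comp = GroundTruthCompound("late", 120.0, 0.2, 1e5, formula="C19H28O")
        with pytest.warns(UserWarning, match="outside the acquisition window"):
            run = simulate_run([comp], NOISELESS, "b", 1, 1)
        assert len(run) == 0

    def test_compound_outside_mz_window_skipped(self):
        comp = GroundTruthCompound("heavy", 60.0, 0.2, 1e5, neutral=1500.0)
        with pytest.warns(UserWarning, match="m/z window"):
            run = simulate_run([comp], NOISELESS, "b", 1, 1)
        assert len(run) == 0

    def test_charge2_ion_at_half_spacing(self):
        comp = GroundTruthCompound(
            "pep", 60.0, 0.2, 1e5, neutral=1322.6034,
            ions=(IonState(1, "H", 2, 1.0),), envelope_depth=2,
        )
        run = simulate_run([comp], NOISELESS, "b", 1, 1)
        mzs = np.unique(run.mz.round(4))
        assert len(mzs) == 2
        assert mzs[1] - mzs[0] == pytest.approx(1.003355 / 2, abs=1e-4)


class TestDefaultScenario:
    def test_scenario_size_and_design(self):
        sc = default_scenario()
        assert len(sc.compounds) >= 56
        assert sc.n_replicates == 2
        assert set(sc.day_grid) == {"sake_1", "sake_2"}
        assert sc.day_grid["sake_1"] == (6, 11, 16, 21, 26, 34)
        assert sc.day_grid["sake_2"] == (1, 5, 11, 19, 26, 34)

    def test_phthalate_constant_across_days(self):
        truth = ground_truth_table(default_scenario())
        dhep = truth[truth.compound == "DHEP"]
        assert dhep.is_background.all()
        assert dhep.abundance.nunique() == 1

    def test_rising_compounds_rise_tenfold(self):
        truth = ground_truth_table(default_scenario())
        for cid in ["LLL", "FPL", "LLLP", "LLLLP", "C19H28O", "C17H26N2O3"]:
            series = truth[(truth.compound == cid) & (truth.batch == "sake_2")]
            by_day = series.set_index("day")["abundance"]
            assert by_day[34] / by_day[1] > 10

    def test_decoys_flat(self):
        truth = ground_truth_table(default_scenario(n_decoys=10))
        decoys = truth[truth.compound.str.startswith("decoy")]
        assert (decoys.groupby("compound")["abundance"].nunique() == 1).all()


class TestRunIO:
    def test_roundtrip_equal(self, tmp_path, single_compound_run):
        _, run = single_compound_run
        path = tmp_path / "run.csv"
        write_run(run, path)
        assert read_run(path) == run

    def test_noisy_roundtrip_equal(self, tmp_path):
        sc = default_scenario(n_decoys=3)
        run = simulate_run(sc.compounds, NoiseModel(seed=5), "sake_1", 11, 2)
        path = tmp_path / "run.csv"
        write_run(run, path)
        assert read_run(path) == run

    def test_empty_run_roundtrips(self, tmp_path):
        empty = Run("b", 1, 1, np.array([], dtype=int), np.array([]), np.array([]))
        path = tmp_path / "empty.csv"
        write_run(empty, path)
        assert read_run(path) == empty

    def test_wrong_scan_count_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# sakemet run v1\n# batch=b day=1 replicate=1 n_scans=100\nscan,rt_min,mz,intensity\n")
        with pytest.raises(ValueError, match="100 scans"):
            read_run(path)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "# batch=b day=1 replicate=1 n_scans=3000\n"
            "scan,rt_min,mz,intensity\n"
            "5,30.1,250.5,100\n"
            "7,30.2,oops,1\n"
        )
        with pytest.raises(ValueError, match="line 4"):
            read_run(path)


def test_run_validates_geometry():
    with pytest.raises(ValueError, match="m/z"):
        Run("b", 1, 1, np.array([0]), np.array([1500.0]), np.array([1.0]))
    with pytest.raises(ValueError, match="scan"):
        Run("b", 1, 1, np.array([3000]), np.array([500.0]), np.array([1.0]))
    with pytest.raises(ValueError, match="3000"):
        Run("b", 1, 1, np.array([0]), np.array([500.0]), np.array([1.0]), n_scans=200)
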