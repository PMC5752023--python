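import numpy as np
import pytest

from sakemet.pipeline import PipelineConfig, run_pipeline
from sakemet.simulate import GroundTruthCompound, IonState, NOISELESS, simulate_run


RISING = ["LLL", "FPL", "LLLP", "LLLLP", "C19H28O", "C17H26N2O3"]


@pytest.fixture(scope="session")
def pipeline_result():
    """One full pipeline run on the default scenario (fixed seed)."""
    return run_pipeline(PipelineConfig(seed=1))


@pytest.fixture()
def single_compound_run():
    """Noiseless run of one protonated peptide (Leu/Ile tripeptide)."""
    comp = GroundTruthCompound(
        "LLL", 64.9, 0.2, 1e6, composition={"[L/I]": 3}, envelope_depth=3
    )
    return comp, simulate_run([comp], NOISELESS, "b", 1, 1)


def home_cell(compound, grid, charge=1, adduct="H", multiplicity=1):
    """Ground-truth grid cell of a compound's monoisotopic ion."""
    from sakemet.chem import cation_mass
    from sakemet.simulate import RT_MIN, RT_MAX, N_SCANS

    mz = (multiplicity * compound.neutral + charge * cation_mass(adduct)) / charge
    scan = int((compound.rt_apex - RT_MIN) / (RT_MAX - RT_MIN) * N_SCANS)
    idx = grid.cell_index(np.array([mz]), np.array([scan]))[0]
    return grid.feature_ids()[idx]
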