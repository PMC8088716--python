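import numpy as np
import pandas as pd
import pytest

from exosig import synthio


@pytest.fixture
def tiny_peptides():
    """Hand-built two-group peptide table with known fold changes.

    PA has one peptide with A=[2,8], B=[1,4] -> peptide ratio 2.0 -> FC 2.0.
    PB has two peptides with group ratios 2 and 8 -> FC 4.0.
    PC is constant across all samples -> FC 1.0.
    """
    cols = ["A_r1", "A_r2", "B_r1", "B_r2"]
    data = {
        "PA_pep1": [2.0, 8.0, 1.0, 4.0],
        "PB_pep1": [2.0, 2.0, 1.0, 1.0],   # ratios all 2 -> group ratio 2
        "PB_pep2": [8.0, 8.0, 1.0, 1.0],   # ratios all 8 -> group ratio 8
        "PC_pep1": [5.0, 5.0, 5.0, 5.0],
    }
    tbl = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    tbl.insert(0, "protein_id", [k.split("_")[0] for k in data])
    tbl.index.name = "peptide_id"
    sheet = pd.DataFrame(
        {
            "sample_id": cols,
            "group": ["A", "A", "B", "B"],
            "cohort": pd.NA,
            "replicate": [1, 2, 1, 2],
            "dfi_days": pd.NA,
        }
    )
    return tbl, sheet


@pytest.fixture
def serum_strong():
    """Strong-separation serum cohorts (the headline-classification regime)."""
    cfg = synthio.serum_config(seed=11)
    return synthio.simulate_serum_cohorts(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
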