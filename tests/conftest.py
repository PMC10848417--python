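import numpy as np
import pandas as pd
import pytest

from raresub.io_model import RoiPanel
from raresub.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort shared across integration tests."""
    config = SimConfig(n_patients=6, seed=7, n_untreated_replicates=3)
    return simulate_cohort(config)


@pytest.fixture()
def tiny_panel():
    """A hand-built 12-site panel with known contexts."""
    rows = []
    seq = "ACGTACGTACGTAC"  # positions 101..112 use 1-bp flanks from this
    for i in range(12):
        rows.append(("chr1", 101 + i, seq[i + 1], seq[i:i + 3]))
    return RoiPanel(sites=pd.DataFrame(rows, columns=["chrom", "pos", "ref_base", "triplet"]))


@pytest.fixture()
def variant_frame():
    """Minimal valid three-row variant table."""
    return pd.DataFrame({
        "patient_id": ["P01"] * 3,
        "sample_id": ["P01_P"] * 3,
        "chrom": ["chr1", "chr1", "chr2"],
        "pos": [101, 105, 200],
        "ref": ["C", "A", "G"],
        "alt": ["T", "G", "A"],
        "mt_alt": [12, 0, 40],
        "mt_total": [1160, 800, 500],
        "called": [True, False, True],
    })


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240206)
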