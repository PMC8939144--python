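import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

from methfield import SimulationConfig, simulate_dataset
from methfield.io import SampleRecord


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic trio dataset shared across tests."""
    cfg = SimulationConfig(
        n_blocks=60, n_patients=8, seed=42,
        n_tumor_hyper=10, n_tumor_hypo=3, n_fc_up=8, n_fc_down=3,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def trio_manifest():
    """Three complete patient trios."""
    return [
        SampleRecord(patient_id=f"P{i}", tissue=t)
        for i in (1, 2, 3)
        for t in ("TUM", "ADJ", "DIS")
    ]


def make_site_table(rows):
    """rows: (chrom, pos, strand, context, meth, unmeth[, sample])"""
    cols = ["chrom", "pos", "strand", "context", "meth_count", "unmeth_count"]
    if rows and len(rows[0]) == 7:
        cols.append("sample_id")
    return pd.DataFrame(rows, columns=cols)
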