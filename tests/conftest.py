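import numpy as np
import pandas as pd
import pytest

from tonegenes.synthetic import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def study_like_dataset():
    """One synthetic dataset at the study's default conditions (~35 families)."""
    return generate_dataset(SimulationConfig(), seed=20240101).table


@pytest.fixture(scope="session")
def large_dataset():
    """A larger synthetic dataset for asymptotic checks (200 families)."""
    cfg = SimulationConfig(n_families=200)
    return generate_dataset(cfg, seed=20240102).table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_locus_table():
    """Hand-built locus-level observations for two samples."""
    return pd.DataFrame([
        # the worked example: two ASPM sources pooled for one sample
        ("SA001509P", "PO000017I", "ASPM", "A44871G", 0.40, 30, "orig"),
        ("SA001509P", "PO000017I", "ASPM", "rs3762271", 0.41, 34, "ALFRED"),
        ("SA001509P", "PO000017I", "MCPH1", "rs930557", 0.70, 30, "orig"),
        ("S2", "P2", "ASPM", "rs41310927", 0.25, 50, "gnomAD"),
    ], columns=["sample_id", "population_id", "gene", "locus_id", "f", "n_alleles", "source"])
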