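import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from panprog.datatypes import ClinicalTable, MultiOmicsDataset, OmicsLayer
from panprog.synthetic import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """A modest harmonized cohort with two planted drivers (g0001, g0002)."""
    from panprog.harmonize import harmonize_dataset

    cfg = SimConfig(
        n_genes=80,
        n_samples=160,
        n_drivers=2,
        driver_layers=[("GE", "DM"), ("GE", "SCNA")],
        effect_size=1.2,
        seed=11,
    )
    dataset, truth = generate_dataset(cfg)
    return harmonize_dataset(dict(dataset.layers), dataset.clinical), truth


@pytest.fixture
def toy_layers():
    """Four hand-written 3-gene x 4-sample layers plus clinical rows."""
    samples = ["s1", "s2", "s3", "s4"]
    genes = ["gA", "gB", "gC"]
    rng = np.random.default_rng(3)
    layers = {
        kind: OmicsLayer(
            kind, pd.DataFrame(rng.normal(size=(3, 4)), index=genes, columns=samples)
        )
        for kind in ("GE", "SCNA", "DM", "ME")
    }
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "time_days": [100.0, 200.0, 300.0, 400.0],
                "event": [1, 0, 1, 1],
                "sample_type_code": ["01"] * 4,
            }
        )
    )
    return layers, clinical


@pytest.fixture
def toy_dataset(toy_layers):
    layers, clinical = toy_layers
    return MultiOmicsDataset(layers=layers, clinical=clinical)
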