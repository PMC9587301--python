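import numpy as np
import pandas as pd
import pytest

import methlink as ml


@pytest.fixture(scope="session")
def small_dataset() -> ml.SyntheticDataset:
    """Default-structure dataset at reduced scale, shared across tests."""
    cfg = ml.SynthConfig(n_genes=120, background_probes=120)
    return ml.generate_dataset(cfg, seed=42)


@pytest.fixture(scope="session")
def ko_contrasts(small_dataset):
    """All five expression contrasts of the knockout/rescue design."""
    ds = small_dataset
    model = ml.NBDifferentialExpression(ds.counts, ds.design)
    names = {"ko": ("WT", "KO"), "r1_wt": ("WT", "R1"), "r2_wt": ("WT", "R2"),
             "r1_ko": ("KO", "R1"), "r2_ko": ("KO", "R2")}
    return {k: model.fit(c) for k, c in names.items()}


def toy_design(conditions, replicates=4):
    rows = [(f"{c}_{r}", c, r, "human")
            for c in conditions for r in range(1, replicates + 1)]
    return pd.DataFrame(rows, columns=["sample_id", "condition", "replicate",
                                       "species"])


@pytest.fixture
def two_group_design():
    return toy_design(["A", "B"])
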