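import numpy as np
import pandas as pd
import pytest

from txprot.core import Contrast, ExpressionMatrix, SampleDesign
from txprot.simdata import SimConfig, simulate_design, simulate_multiomics


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_genes=400, seed=11)


@pytest.fixture(scope="session")
def small_design():
    return simulate_design(5, 3)


@pytest.fixture(scope="session")
def small_sim(small_cfg, small_design):
    """A small but fully structured simulated bundle, shared read-only."""
    rna, protein, lengths, truth = simulate_multiomics(small_cfg, small_design)
    return {
        "cfg": small_cfg,
        "design": small_design,
        "rna": rna,
        "protein": protein,
        "lengths": lengths,
        "truth": truth,
    }


@pytest.fixture()
def toy_protein_design():
    """Two conditions x one timepoint x 2-3 protein replicates."""
    rows = []
    for cond, n in (("vehicle", 3), ("agonist", 3)):
        for r in range(1, n + 1):
            rows.append(
                {
                    "sample_id": f"p_{cond}_r{r}",
                    "condition": cond,
                    "timepoint": "early",
                    "replicate": r,
                    "assay": "protein",
                }
            )
    return SampleDesign(pd.DataFrame(rows))


def protein_matrix(values, sample_ids, feature_ids=None):
    values = np.asarray(values, dtype=float)
    if feature_ids is None:
        feature_ids = [f"p{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=sample_ids),
        layer="log2_intensity",
    )
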