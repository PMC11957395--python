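import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from neurgi.config import RunConfig
from neurgi.synthetic import SyntheticSpec, generate_feature_table

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bench600():
    """The 600-gene benchmark cohort: 300 positives vs 300 latent negatives,
    28 features of which 7 are pure noise, effect size 2 SD."""
    return generate_feature_table(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def trained_small(bench600):
    """A small but non-trivial ensemble on the benchmark cohort."""
    from neurgi.model import train_ensemble

    cfg = RunConfig(seed=7, k_folds=5, n_trees=40)
    return train_ensemble(bench600.table, bench600.truth, cfg)


@pytest.fixture()
def tiny_table():
    """Hand-built 4-gene, 3-feature table with one NaN."""
    from neurgi.types import GeneFeatureTable

    idx = pd.Index(["g1", "g2", "g3", "g4"], name="gene_id")
    features = pd.DataFrame(
        {
            "expr_a": [1.0, 2.0, np.nan, 4.0],
            "phys_a": [0.0, 1.0, 2.0, 0.0],
            "cons_a": [0.5, 0.9, 0.1, 0.7],
        },
        index=idx,
    )
    return GeneFeatureTable(
        features=features,
        gene_type=pd.Series(["tf", "enzyme", "other", "rbp"], index=idx),
        categories={"expr_a": "expression", "phys_a": "physiological", "cons_a": "conservation"},
    )
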