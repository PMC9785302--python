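import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import enosekit as ek

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort():
    """Two-region cohort at study-design defaults (36 Coa / 31 Douro)."""
    cfg = ek.GeneratorConfig(seed=1)
    curves, profiles, labels = ek.generate_cohort(cfg)
    return cfg, curves, profiles, labels


@pytest.fixture(scope="session")
def full_table(default_cohort):
    _, curves, _, _ = default_cohort
    return ek.extract_features(curves)


@pytest.fixture(scope="session")
def mean_view(full_table):
    return ek.select_method_view(full_table, "MEAN")


def make_table(X, labels, prefix="F"):
    """Wrap a numeric matrix and label vector into a FeatureTable."""
    X = np.asarray(X, dtype=float)
    index = pd.Index([f"s{i}" for i in range(len(X))], name="sample_id")
    features = pd.DataFrame(
        X, index=index, columns=[f"{prefix}{j}" for j in range(X.shape[1])]
    )
    return ek.FeatureTable(
        features=features, labels=pd.Series(list(labels), index=index, name="region")
    )
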