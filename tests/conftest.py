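import warnings

import numpy as np
import pytest

from pathpairs import (
    FeatureMatrix,
    PathwayCatalog,
    SynthConfig,
    build_feature_sets,
    cross_join,
    generate,
)

# MLP fits in tests deliberately run few epochs; convergence chatter is noise.
warnings.filterwarnings("ignore", message=".*Maximum iterations.*")


@pytest.fixture
def tiny_matrix() -> FeatureMatrix:
    """Two metabolites, two elemental features."""
    return FeatureMatrix(
        ["m1", "m2"], ["f1", "f2"], np.array([[1.0, 2.0], [3.0, 4.0]]),
        np.array([0, 0]),
    )


@pytest.fixture
def tiny_catalog() -> PathwayCatalog:
    return PathwayCatalog.from_dict({"P1": ["m1", "m2"]})


@pytest.fixture(scope="session")
def small_pair_dataset():
    """A modest learnable fixture shared by evaluation tests."""
    cfg = SynthConfig(
        n_metabolites=200, n_pathways=4, n_features=60, signature_size=8,
        signal_strength=5.0, seed=11,
    )
    matrix, catalog = generate(cfg)
    sets = build_feature_sets(matrix, catalog)
    return cross_join(sets.metabolite, sets.pathway, catalog)
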