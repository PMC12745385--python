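import numpy as np
import pytest

import spinefuse as sf


@pytest.fixture(scope="session")
def strong_cohort_features():
    """90-case, 3-class strong-separation phantom cohort, featurized once
    per session with the stub backbone (fused 4608-d vectors)."""
    profiles = sf.strong_separation_profiles()
    counts = {name: 30 for name in profiles}
    cohort = sf.generate_cohort(profiles, counts, base_seed=0,
                                noise_sigma=0.01)
    X, y = sf.featurize_cohort(cohort)
    return X, y


@pytest.fixture(scope="session")
def d8_fixture():
    """D=8 tabular fixture (3 informative, 5 noise columns, effect size 4,
    n=60) used for selector-vs-oracle comparisons."""
    return sf.make_feature_fixture(n_per_class=20, n_classes=3,
                                   d_informative=3, d_noise=5,
                                   effect_size=4.0, seed=11)


@pytest.fixture(scope="session")
def small_rf():
    """Reduced forest for wrapper-search tests: the search dynamics do not
    depend on forest size, only the fitness landscape does."""
    return sf.RFConfig(n_trees=15, max_depth=8, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
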