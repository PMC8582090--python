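import numpy as np
import pytest

import fallrisk as fr


@pytest.fixture(scope="session")
def anchors():
    return fr.default_anchors()


@pytest.fixture(scope="session")
def model():
    return fr.published_model()


@pytest.fixture(scope="session")
def cutoff_table(model, anchors):
    return fr.derive_cutoffs(model, anchors)


@pytest.fixture(scope="session")
def cohort500():
    """One seeded synthetic cohort at the study's sample size."""
    return fr.generate_cohort(n=500, seed=11)


@pytest.fixture(scope="session")
def cohort_large():
    """A large cohort for quantile/correlation recovery checks."""
    return fr.generate_cohort(n=20000, seed=3)


def random_labelled_scores(rng, n_max=200):
    """Random scores/labels with both classes present and ties likely."""
    n = int(rng.integers(10, n_max))
    scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
    labels = (rng.random(n) < 0.4).astype(int)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return scores, labels
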