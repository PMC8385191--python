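import logging

import numpy as np
import pandas as pd
import pytest

import ssp50 as s

# cohort-level warnings (uncentered matrices etc.) are expected noise in tests
logging.getLogger("ssp50").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def centroids():
    """Well-separated 50-gene, 5-subtype synthetic centroid set."""
    return s.make_centroids(n_genes=50, n_subtypes=5, separation=1.0, seed=11)


@pytest.fixture(scope="session")
def default_cohort(centroids):
    """Default-condition synthetic tumor cohort (143 samples, both platforms)."""
    spec = s.SyntheticCohortSpec(seed=11)
    return s.generate_cohort(spec, centroids)


def accuracy(calls, truth: pd.Series) -> float:
    return float(np.mean([c.label == truth[c.sample_id] for c in calls]))
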