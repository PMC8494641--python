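import numpy as np
import pytest

from methylatlas.simulate import default_cohort_spec, generate_methylome_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """300 cells, 3 planted clusters, two contexts — shared read-only fixture."""
    spec = default_cohort_spec(
        n_cells=300, n_clusters=3, n_features=300, n_markers=30, seed=42
    )
    counts, truth = generate_methylome_cohort(spec)
    return counts, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
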