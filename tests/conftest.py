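import numpy as np
import pytest

import parcelstim as ps


@pytest.fixture(scope="session")
def spec60():
    """Study-condition cohort spec at test scale: 200 reference subjects,
    60 parcels, 128 volumes at TR 2.8 s."""
    return ps.CohortSpec(seed=0)


@pytest.fixture(scope="session")
def reference(spec60):
    """Fitted reference: Frechet mean + normative model over the full
    200-subject synthetic cohort."""
    cohort = ps.generate_reference_cohort(spec60)
    return ps.fit_reference(cohort)


@pytest.fixture(scope="session")
def atlas60(spec60):
    atlas = ps.synthetic_atlas(spec60.n_parcels, seed=0)
    assert tuple(atlas.networks) == spec60.network_partition
    return atlas


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_spd(rng, p, scale=1.0):
    """Random symmetric positive definite matrix."""
    a = rng.standard_normal((p, 2 * p))
    return scale * (a @ a.T) / (2 * p) + 0.1 * np.eye(p)
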