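import warnings

import numpy as np
import pytest

import dlradiomics as dlr


@pytest.fixture(scope="session")
def phantom_pair():
    """Textured ellipsoidal phantom with mask (anisotropic semi-axes)."""
    return dlr.make_phantom(dlr.PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def sphere_phantom():
    """Spherical phantom, radius 10 mm, for shape-feature identities."""
    return dlr.make_phantom(dlr.PhantomSpec(semi_axes_mm=(10.0, 10.0, 10.0), seed=5))


@pytest.fixture(scope="session")
def cohort_informative():
    """n=200 cohort, one informative feature (delta=2) among 50 noise features."""
    fm, y, truth = dlr.make_feature_cohort(
        dlr.CohortSpec(n_samples=200, n_features=51, n_informative=1,
                       effect_size=2.0, seed=11)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fmz = dlr.zscore_normalize(fm)
    return fmz, y, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
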