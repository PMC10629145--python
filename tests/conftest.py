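import numpy as np
import pytest

import misspipe as mp


@pytest.fixture(scope="session")
def mixed_masked():
    """60 x 6 mixed continuous/binary cohort with ~15% MCAR."""
    schema = mp.FeatureSchema(
        names=tuple(f"f{j}" for j in range(6)),
        kinds=("continuous", "binary", "continuous", "continuous", "binary",
               "continuous"),
    )
    spec = mp.SyntheticSpec(
        n=60, schema=schema, beta_true=np.array([1.0, 0, 0.5, 0, 0, -0.8]),
        intercept=0.0, support_size=3, corr=0.4, seed=7,
    )
    cohort = mp.generate_cohort(spec)
    mspec = mp.MissingnessSpec(
        mechanism="mcar", per_feature_rate=np.full(6, 0.15), seed=8)
    return cohort, mp.inject_missingness(cohort, mspec)


def random_masked_cohort(rng, n=None, d=None, binary_fraction=0.3,
                         rate=0.2, corr=0.5):
    """Randomized small masked cohort for property tests."""
    n = n or int(rng.integers(40, 200))
    d = d or int(rng.integers(4, 9))
    spec = mp.SyntheticSpec.default(
        n=n, d=d, support_size=min(3, d), binary_fraction=binary_fraction,
        corr=corr, seed=int(rng.integers(0, 2**31)),
    )
    cohort = mp.generate_cohort(spec)
    rates = rng.uniform(0.05, rate, size=d)
    mspec = mp.MissingnessSpec(mechanism="mcar", per_feature_rate=rates,
                               seed=int(rng.integers(0, 2**31)))
    return cohort, mp.inject_missingness(cohort, mspec)
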