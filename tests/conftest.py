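import numpy as np
import pytest

from t2ebm.synthetic import CohortSpec, generate_cohort


def small_spec(K=5, n_pat=60, n_ctl=40, seed=0, **kw):
    names = tuple(f"B{i}" for i in range(K))
    defaults = dict(
        n_patients=n_pat,
        n_controls=n_ctl,
        biomarkers=names,
        directions={m: True for m in names},
        batteries=[],
        include_gmv=False,
        seed=seed,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized cohort with the full battery structure."""
    spec = CohortSpec(seed=7)
    return generate_cohort(spec) + (spec,)
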