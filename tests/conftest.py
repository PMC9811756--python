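import numpy as np
import pytest

from gliovasc.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A tiny rendered cohort (2 hypertension + 2 control), reused read-only."""
    out = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(n_hypertension=2, n_control=2, seed=42)
    result = generate_cohort(spec, out)
    result["spec"] = spec
    return result
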