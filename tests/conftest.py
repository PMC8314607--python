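import numpy as np
import pytest

import fpecea


@pytest.fixture(scope="session")
def base():
    """Bundled base-case parameter set (never mutate; copy first)."""
    return fpecea.base_case()


@pytest.fixture(scope="session")
def traces(base):
    """Deterministic cohort traces for both sexes and arms."""
    out = {}
    for sex in ("women", "men"):
        for arm in ("fpe", "no-fpe"):
            out[(sex, arm)] = fpecea.run_cohort(base, arm, sex=sex)
    return out


@pytest.fixture(scope="session")
def cea_results(traces):
    return {
        sex: fpecea.compare(traces[(sex, "fpe")], traces[(sex, "no-fpe")])
        for sex in ("women", "men")
    }


def assert_row_stochastic(matrix: np.ndarray, atol: float = 1e-12):
    assert np.all(matrix >= -atol)
    assert np.all(matrix <= 1 + atol)
    np.testing.assert_allclose(matrix.sum(axis=-1), 1.0, atol=atol)
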