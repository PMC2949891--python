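import numpy as np
import pytest

import grncompare as g


@pytest.fixture(scope="session")
def case_models():
    """All nine printed reference models, keyed by (case, method)."""
    return {
        (c, m): g.build_case(c, m)
        for c in ("A", "B", "C")
        for m in ("ANN", "SS", "GRLOT")
    }


@pytest.fixture(scope="session")
def quick_settings():
    """Coarser integration grid for fast structural tests."""
    return g.IntegrationSettings(t_end=20.0, n_points=50)


@pytest.fixture(scope="session")
def sparse_case_a_ann(case_models):
    return g.generate_sparse(case_models[("A", "ANN")])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
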