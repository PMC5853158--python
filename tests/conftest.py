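import numpy as np
import pytest

import gliomamr as g


@pytest.fixture(scope="session")
def fixture_sets():
    """All four packaged trait fixtures as (exposure, outcome) pairs."""
    return {t: g.load_fixture(t) for t in g.FIXTURE_TRAITS}


@pytest.fixture(scope="session")
def harmonised(fixture_sets):
    """Harmonised instruments per trait (labels trusted: tables pre-aligned)."""
    return {
        t: g.harmonise_sets(e, o, trust_labels=True)
        for t, (e, o) in fixture_sets.items()
    }


@pytest.fixture(scope="session")
def ad_all(harmonised):
    """All 18 atopic dermatitis instruments, including rs909341."""
    return harmonised["atopic_dermatitis"]


@pytest.fixture(scope="session")
def ad17(ad_all):
    """The 17 atopic dermatitis instruments after excluding rs909341."""
    return [i for i in ad_all if i.snp_id != "rs909341"]


def make_instruments(
    rng,
    k=12,
    beta=0.3,
    intercept=0.0,
    sigma_x=0.02,
    sigma_y=0.05,
    x_range=(0.1, 0.5),
):
    """Synthetic harmonised instruments: Y = intercept + beta * X + noise."""
    xi = rng.uniform(*x_range, size=k)
    x = xi + rng.normal(0, sigma_x, k)
    y = intercept + beta * xi + rng.normal(0, sigma_y, k)
    return [
        g.HarmonisedInstrument(f"s{i}", x[i], sigma_x, y[i], sigma_y)
        for i in range(k)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def synth(rng):
    return make_instruments(rng)
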