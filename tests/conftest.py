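import warnings
from dataclasses import replace

import pytest

import graincast as gc

# statsmodels emits convergence chatter on tiny ARMA fits; it is inspected
# through the results flags instead
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def rice_noiseless():
    """Exactly quadratic rice-like average series, 1961-2019."""
    spec = replace(gc.default_spec("rice", seed=0), noise_sd=0.0, ar_rho=0.0,
                   span=(1961, 2019))
    avg, top = gc.generate_yields(spec)
    return avg


@pytest.fixture(scope="session")
def rice_pair():
    """Noisy rice-like (average, top) pair, 1961-2021."""
    return gc.generate_yields(gc.default_spec("rice", seed=11))


@pytest.fixture(scope="session")
def reference_fixture():
    """Four-crop fixture with the documented top-country labels."""
    return gc.make_reference_fixture(seed=0)


@pytest.fixture()
def yield_csv(tmp_path, rice_pair):
    path = tmp_path / "yields.csv"
    gc.write_yield_table(list(rice_pair), path)
    return path
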