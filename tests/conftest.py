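import warnings

import pytest

from vocompare.synthetic_data import (
    default_method_specs,
    generate_dataset,
    noiseless,
)

# MixedLM emits boundary/convergence chatter that is asserted on explicitly
# via the result's converged flag instead.
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic dataset (5 methods, 60-compound panel, seed 1)."""
    return generate_dataset(seed=1)


@pytest.fixture(scope="session")
def metadata_map(dataset):
    """In-memory metadata lookup equivalent to reading the metadata CSV."""
    return {
        name.casefold(): (bp, origin)
        for _, name, _, bp, origin in dataset.metadata_rows
    }


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Certain detection, zero RT jitter, zero area/spectrum noise, no blank noise."""
    specs = [noiseless(s) for s in default_method_specs()]
    return generate_dataset(
        method_specs=specs, seed=7, spectrum_noise_sd=0.0, n_blank_noise_peaks=0.0
    )
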