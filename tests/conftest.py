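import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from muvi.spectra_io import Spectrum, canonical_grid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def grid():
    return canonical_grid()


@pytest.fixture
def exp_spectrum(grid):
    """Factory for noiseless exponential-decay spectra on the canonical grid."""

    def make(a0=0.8, s=0.018, k=0.0, sample_id="synthetic-exp", normalized=False):
        y = a0 * np.exp(-s * (grid - 200.0)) + k
        spec = Spectrum(grid, y, sample_id=sample_id, replicate_id="r1")
        if normalized:
            from muvi.indices import normalize

            spec = normalize(spec)
        return spec

    return make
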