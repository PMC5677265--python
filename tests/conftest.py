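import numpy as np
import pytest

import gaitproxy as gp


@pytest.fixture(scope="session")
def default_params():
    return gp.GaitTemplateParams()


@pytest.fixture(scope="session")
def clean_recording():
    """Noiseless, jitter-free 30-cycle biomechanical recording."""
    return gp.generate_biomech_recording(gp.GaitTemplateParams(), 30, seed=2)


@pytest.fixture(scope="session")
def fitted_pipeline(clean_recording):
    """A proxy model fitted on the first half of the clean recording.

    Shared across tests: (estimator, training half, test half).
    """
    train, test = gp.split_half(clean_recording)
    est = gp.VGRFProxyRegressor(n_terms=12, iofr_iterations=0)
    est.fit(train)
    return est, train, test
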