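import numpy as np
import pytest

import specmed as sp


@pytest.fixture(scope="session")
def study_frame():
    """The packaged 35-regenerant study table as a DataFrame."""
    return sp.load_fixture().to_frame()


@pytest.fixture(scope="session")
def modmed_fit(study_frame):
    """Moderated mediation fit (combined absorbance, CHG demethylation, SV, time)."""
    return sp.ModeratedMediation.from_dataframe(
        study_frame, "f_combined", "chg_dmv", "sv", "time_days"
    ).fit()


@pytest.fixture
def small_boot():
    return sp.BootConfig(n_boot=200, seed=42)


@pytest.fixture
def flat_spectrum():
    wn = np.arange(4000.0, 399.0, -4.0)
    return sp.Spectrum(wn, np.full_like(wn, 5.0))
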