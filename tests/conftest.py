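import numpy as np
import pytest

import cumdep as cd


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-person CES-D-8 cohort with a true per-unit CumDS effect."""
    cfg = cd.cohort_preset(
        "cesd8", n_participants=400, seed=11,
        true_loghr={"cumds": np.log(1.06)},
    )
    return cd.simulate_cognition_adl(cd.simulate_cohort(cfg))


@pytest.fixture(scope="session")
def analytic_df(small_cohort):
    """Participant-level table with derived exposures merged on."""
    cfg = small_cohort.config
    ex = cd.derive_exposures(small_cohort.panel, cfg.scale.high_threshold)
    return small_cohort.participants.merge(ex, on="id")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
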