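import pytest

import ovlsim as ov

# The eight population contrasts of the factorial design: (delta, sigma, alpha).
SCENARIO_CELLS = [
    (0.0, 1.0, 0.0),
    (0.0, 1.0, 10.0),
    (0.0, 5.0, 0.0),
    (0.0, 5.0, 10.0),
    (2.0, 1.0, 0.0),
    (2.0, 1.0, 10.0),
    (2.0, 5.0, 0.0),
    (2.0, 5.0, 10.0),
]


@pytest.fixture(scope="session")
def grid_200():
    """Full 48-condition grid at 200 replicates/condition, intervals disabled.

    This is the desk-scale rerun of the study's descriptive surface: enough
    replicates for pooled correlations and per-condition bias, no interval
    machinery (which those summaries never read). Shared session-wide because
    it is the single most expensive computation in the suite.
    """
    cfg = ov.RunConfig(n_reps=200, master_seed=1, compute_intervals=False, boot=None)
    return ov.run_grid(cfg)
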