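import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rare_params():
    """Rare-outcome generative truth (negligible mediator clipping)."""
    from frailmed import rare_outcome_params

    return rare_outcome_params(n=5000)


@pytest.fixture(scope="session")
def fitted_mediation(rare_params):
    """One fitted mediation analysis on a simulated rare-outcome cohort."""
    import frailmed as fm

    design = fm.simulate_design(rare_params, seed=42)
    est = fm.NaturalEffectsMediator().fit(design)
    return design, est


@pytest.fixture(scope="session")
def demo_records():
    """Small validated record list in deficit-level mode."""
    import dataclasses

    import frailmed as fm

    params = dataclasses.replace(
        fm.composite_demo_params(n=120), mediator_mode="deficit_level"
    )
    return fm.simulate_records(params, seed=7)
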