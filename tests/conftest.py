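import numpy as np
import pytest

from nlhvdm import GeneKinetics, TFActivityProfile, make_activity, simulate_panel

MEASUREMENT_TIMES = np.arange(0.0, 13.0, 2.0)


@pytest.fixture(scope="session")
def pulse_profile() -> TFActivityProfile:
    return make_activity("pulse", knots=MEASUREMENT_TIMES)


@pytest.fixture(scope="session")
def constant_profile() -> TFActivityProfile:
    """Activity pinned at 1 at every post-zero knot (baseline 1 too)."""
    return TFActivityProfile(MEASUREMENT_TIMES, np.ones(7), baseline_value=1.0)


@pytest.fixture(scope="session")
def training_truth():
    """Noise-free well-conditioned 5-gene panel with zero delay (fixed seed)."""
    profile = make_activity("pulse", knots=MEASUREMENT_TIMES)
    return simulate_panel(profile, 5, noise_sd=0.0, delay_choices=(0.0,),
                          well_conditioned=True, seed=3)


def random_kinetics(rng: np.random.Generator, **overrides) -> GeneKinetics:
    params = dict(
        c=rng.uniform(0.1, 5.0), k=rng.uniform(0.5, 5.0),
        K=rng.uniform(0.1, 2.0), d=rng.uniform(0.2, 2.0),
        tau=0.0, delta=int(rng.integers(0, 2)),
    )
    params.update(overrides)
    return GeneKinetics(**params)
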