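import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared by read-only tests."""
    from cortistri import CohortConfig, gen_cohort

    return gen_cohort(CohortConfig(seed=1))


@pytest.fixture()
def make_train():
    """Factory for spike trains with sensible metadata defaults."""
    from cortistri import SpikeTrain

    def _make(times, duration=180.0, **kw):
        tags = dict(
            unit_id="u0", animal_id="a0", group="saline",
            structure="mPFC", trial="pre_exposure",
        )
        tags.update(kw)
        return SpikeTrain(times=np.asarray(times, float), duration=duration, **tags)

    return _make
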