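import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from eggscreen import load_panel
from eggscreen.io import RESPONSE_COLUMNS

settings.register_profile(
    "repro", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def panel():
    return load_panel()


def make_records(rows):
    """Build a response-table frame from dicts with sensible defaults."""
    defaults = dict(
        sample_id="s1",
        day=1,
        replicate=1,
        analyte="lincomycin",
        transition_rank="major",
        response=0.0,
        noise=1.0,
        observed_rt=4.3,
        sample_kind="study",
    )
    return pd.DataFrame([{**defaults, **r} for r in rows], columns=RESPONSE_COLUMNS)


@pytest.fixture
def records_factory():
    return make_records
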