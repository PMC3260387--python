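import dataclasses

import pytest
from hypothesis import settings

from cprsim.engine import GuidelineConfig
from cprsim.teams import TeamProfile

settings.register_profile("deterministic", derandomize=True, max_examples=60)
settings.load_profile("deterministic")


@pytest.fixture
def cfg() -> GuidelineConfig:
    return GuidelineConfig()


@pytest.fixture
def deterministic_profile() -> TeamProfile:
    """All spreads zero: schedules are exactly predictable."""
    return TeamProfile(
        t_first_defib_mean=100, t_first_defib_sd=0,
        shock_interval_mean=120, shock_interval_sd=0,
        peri_shock_pause=5,
        cc_segment_mean=90, cc_segment_sd=0,
        cc_pause_mean=10, cc_pause_sd=0,
        vent_rate=6.0,
        t_iv=150, t_intubation=300, t_epi1=200, t_epi2=None,
        t_amiodarone=None, t_atropine=None,
        cc_output=1.5, seed=0)


def make_profile(**overrides) -> TeamProfile:
    base = TeamProfile(
        t_first_defib_mean=100, t_first_defib_sd=0,
        shock_interval_mean=150, shock_interval_sd=0,
        peri_shock_pause=10,
        cc_segment_mean=60, cc_segment_sd=0,
        cc_pause_mean=10, cc_pause_sd=0,
        vent_rate=1.0,
        t_iv=150, t_intubation=300, t_epi1=200, t_epi2=340,
        t_amiodarone=None, t_atropine=None,
        cc_output=1.5, seed=0)
    return dataclasses.replace(base, **overrides)
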