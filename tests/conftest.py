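from __future__ import annotations

import pytest

from eolcare.costs import CostParameters, InflationSchedule
from eolcare.generate import GeneratorConfig, PLANTED_SCENARIOS, generate_linked_data


@pytest.fixture(scope="session")
def schedule() -> InflationSchedule:
    return InflationSchedule.default()


@pytest.fixture(scope="session")
def params() -> CostParameters:
    return CostParameters.default()


@pytest.fixture(scope="session")
def small_bundle():
    """30 decedents plus all 14 planted scenarios, seed fixed."""
    cfg = GeneratorConfig(n_decedents=30, seed=11, planted_cases=PLANTED_SCENARIOS)
    return generate_linked_data(cfg)


@pytest.fixture(scope="session")
def small_cohorts(small_bundle):
    from eolcare.cohort import build_cohorts

    return build_cohorts(small_bundle)
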