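import logging
from dataclasses import replace

import pytest

from asimed import synthetic_cohort as sc


@pytest.fixture(autouse=True)
def _quiet_logging():
    logging.getLogger("asimed").setLevel(logging.ERROR)


def no_missingness(config: sc.CohortConfig) -> sc.CohortConfig:
    return replace(config, missingness=replace(config.missingness, enabled=False))


@pytest.fixture(scope="session")
def complete_cohort():
    """Default-size pooled cohort, every follow-up observed."""
    return sc.simulate_cohort(no_missingness(sc.CohortConfig(seed=42)))


@pytest.fixture(scope="session")
def small_cohort():
    """~120-participant cohort with the default MAR attrition applied."""
    cfg = sc.with_total_n(sc.CohortConfig(seed=7), 120)
    return sc.simulate_cohort(cfg)
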