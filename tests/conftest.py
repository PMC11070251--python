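"""Shared fixtures: sites, schedules and small synthetic datasets."""

from datetime import date

import numpy as np
import pytest

from moonchorus import SiteConfig, generate_schedule


@pytest.fixture
def bci_site():
    """A tropical-forest recording site (UTC-5) running for one week."""
    return SiteConfig(
        site_id="S1",
        latitude=9.1547,
        longitude=-79.8461,
        elevation=150.0,
        utc_offset=-5.0,
        operation_intervals=((date(2019, 2, 1), date(2019, 2, 7)),),
    )


@pytest.fixture
def four_sites():
    """Four nearby sites operating for 30 nights."""
    return {
        f"S{i}": SiteConfig(
            site_id=f"S{i}",
            latitude=9.15 + 0.01 * i,
            longitude=-79.85 + 0.01 * i,
            utc_offset=-5.0,
            operation_intervals=((date(2019, 2, 1), date(2019, 3, 2)),),
        )
        for i in range(4)
    }


@pytest.fixture
def four_site_schedule(four_sites):
    windows = []
    for site in four_sites.values():
        windows += generate_schedule(site)
    return windows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
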