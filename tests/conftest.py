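import logging

import pytest

from miromics import generate_cohort

logging.getLogger("miromics").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by read-only tests."""
    return generate_cohort(n_samples=60, n_mirnas=40, seed=11)
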