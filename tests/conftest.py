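"""Shared fixtures: multi-trial study protocols reused across tests.

The two calibrated PD comparison protocols are expensive (20 one-second
simulations each), so they are computed once per session.
"""

import pytest

from stnsim.experiments import (animal_pd_condition, human_pd_condition,
                                run_condition_comparison)


@pytest.fixture(scope="session")
def human_comparison():
    """10-trial paired STDP contrast, human-calibrated PD condition."""
    return run_condition_comparison(human_pd_condition(base_seed=0))


@pytest.fixture(scope="session")
def animal_comparison():
    """10-trial paired STDP contrast, animal-calibrated PD condition."""
    return run_condition_comparison(animal_pd_condition(base_seed=0))
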