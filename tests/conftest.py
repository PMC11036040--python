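import numpy as np
import pytest

import milenorm as m
from milenorm.pipeline import _start_norms_from_params

SEED = 0  # package-wide test seed


@pytest.fixture(scope="session")
def bank():
    return m.default_bank()


class RecoveryRun:
    """Full simulate -> administer -> calibrate run at the study scale."""

    def __init__(self, bank, seed=SEED, n=948):
        self.bank = bank
        self.params = m.generate_true_params(bank, seed=seed)
        self.cohort = m.sample_cohort(n, seed=seed)
        self.oracle = m.simulate_full_responses(self.params, self.cohort, seed=seed)
        norms = _start_norms_from_params(self.params, bank, 0.9)
        self.scored, self.provenance = m.administer_cohort(
            self.oracle, self.cohort, norms, bank
        )
        self.ages = (
            self.cohort.set_index("child_id")["age_days"].reindex(self.scored.index)
        )
        self.calibrations = m.calibrate_all(self.scored, self.ages, bank)


@pytest.fixture(scope="session")
def recovery_run(bank):
    return RecoveryRun(bank)
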