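"""Shared fixtures: a fixed cohort and a session-wide simulated-trial cache.

Simulations run at the minimum allowed integrator rate (1 kHz) to keep the
suite fast; physics tolerances are unchanged.
"""

from __future__ import annotations

import pytest

from jumpwork import generate_cohort, simulate_trial

SIM_RATE = 1000.0


class TrialFactory:
    """Memoizing wrapper around :func:`simulate_trial` for one subject."""

    def __init__(self, subject):
        self.subject = subject
        self._cache = {}

    def __call__(self, jump_type: str, seed: int = 0):
        key = (jump_type, seed)
        if key not in self._cache:
            self._cache[key] = simulate_trial(
                self.subject, jump_type, seed=seed, sim_rate=SIM_RATE
            )
        return self._cache[key]


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(9, 12, seed=1)


@pytest.fixture(scope="session")
def subject(cohort):
    return cohort.subjects[0]


@pytest.fixture(scope="session")
def trials(subject):
    return TrialFactory(subject)
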