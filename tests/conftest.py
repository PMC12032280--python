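"""Shared fixtures.

Heavy simulations (the benchmark trial set and the analysed EEG cohorts)
are session-scoped so the acceptance tests can share them.  Cohort sizes
follow the study (20 participants) with a desk-scale trial count per
participant for the EEG battery; generator defaults themselves are not
reduced.
"""

from __future__ import annotations

import numpy as np
import pytest

import volatok as v


@pytest.fixture(scope="session")
def benchmark_trials() -> v.TrialSet:
    """3x10^5 trials at the generative settings (strategy benchmarks)."""
    return v.generate_trials(v.TaskConfig(n_trials=300_000, seed=101))


@pytest.fixture(scope="session")
def small_trialset() -> v.TrialSet:
    return v.generate_trials(v.TaskConfig(n_trials=2000, seed=11))


@pytest.fixture(scope="session")
def small_traces(small_trialset) -> v.BeliefTraceSet:
    return v.run_observer_set(small_trialset, v.ObserverParams())


_COHORT_TRIALS = 320  # per participant, desk scale for the EEG battery
_COHORT_N = 20


@pytest.fixture(scope="session")
def eeg_cohort_results() -> list[dict]:
    """Analysed 20-participant synthetic cohort (shared gain noise on)."""
    return v.analyse_cohort(
        _COHORT_N,
        task_config=v.TaskConfig(n_trials=_COHORT_TRIALS),
        synth_config=v.SynthConfig(),
        seed=202,
    )


@pytest.fixture(scope="session")
def null_coupling_cohort_results() -> list[dict]:
    """Same cohort recipe with the shared gain noise switched off."""
    return v.analyse_cohort(
        _COHORT_N,
        task_config=v.TaskConfig(n_trials=_COHORT_TRIALS),
        synth_config=v.SynthConfig(sigma_eta=0.0),
        seed=303,
    )
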