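"""Shared fixtures: a reference synthetic study and its pipeline run.

The 45-subject study (15 per group, four conditions, 30 s at 3000 Hz) is the
study-scale default of the generator; it is session-scoped because trial
synthesis and decomposition dominate the suite's runtime.
"""
import warnings

import numpy as np
import pandas as pd
import pytest

import swaywave as sw


@pytest.fixture(autouse=True)
def _quiet_scale_warning():
    # the deep-level localization warning fires on every 30 s default run
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sw.SwayWaveWarning)
        yield


@pytest.fixture(scope="session")
def study45():
    return sw.generate_study(sw.SimulationConfig(n_per_group=15, seed=7))


@pytest.fixture(scope="session")
def pipeline45(study45):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sw.SwayWaveWarning)
        return sw.run_pipeline(
            sw.PipelineConfig(),
            trials=study45.trials,
            covariates=study45.covariates.drop(columns=["group"]),
        )


def make_covariate_row(subject_id="S001", **overrides):
    """One in-range covariate record for io validation tests."""
    row = {"subject_id": subject_id, "x1": 21.0, "x2": 387.0, "x3": 0.75}
    row.update({f"x{i}": 5.0 for i in range(4, 12)})
    row.update({f"x{i}": 50.0 for i in range(12, 24)})
    row["x24"] = 0.0
    row.update(overrides)
    return row


@pytest.fixture
def covariate_frame():
    def _make(n=3, **overrides):
        rows = [make_covariate_row(subject_id=f"S{i:03d}", **overrides)
                for i in range(1, n + 1)]
        return pd.DataFrame(rows)
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(42)
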