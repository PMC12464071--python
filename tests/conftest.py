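import numpy as np
import pandas as pd
import pytest

from vplearn import synth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def paper_like_cohort():
    """One paper-like cohort, staircase-measured, shared across tests."""
    spec = synth.cohort_preset("paper-like")
    return synth.simulate_cohort(
        spec, rng=np.random.default_rng(11), keep_trials=False
    )


@pytest.fixture(scope="session")
def small_trace_set():
    """60 synthetic gaze trials with ground-truth microsaccades."""
    spec = synth.TraceSpec(n_trials=60, seed=3)
    return synth.simulate_trace(spec)


def make_balanced_table(
    n_subjects=8,
    blocks=1,
    effects=None,
    noise_sd=0.0,
    subject_sd=0.0,
    rng=None,
    baseline=10.0,
):
    """Small balanced 4-factor cohort table with chosen additive effects.

    ``effects`` maps a factor name to a dict of level -> shift.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    df = synth.simulate_null_table(
        n_subjects=n_subjects,
        blocks=blocks,
        subject_sd=subject_sd,
        noise_sd=max(noise_sd, 1e-12),
        baseline=baseline,
        rng=rng,
    )
    if noise_sd == 0.0:
        df["threshold"] = baseline
        if subject_sd > 0:
            codes = pd.factorize(df["subject"])[0]
            df["threshold"] += subject_sd * rng.standard_normal(codes.max() + 1)[codes]
    for fac, shifts in (effects or {}).items():
        df["threshold"] = df["threshold"] + df[fac].map(shifts).fillna(0.0)
    return df
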