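import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import lhsurge as lh
from lhsurge.preprocess import LodConfig, preprocess_cohort

settings.register_profile("suite", derandomize=True, max_examples=100,
                          deadline=None)
settings.load_profile("suite")


def make_series(values, days=None, channel=lh.URINE, observed=None,
                pid="P001", cid="C1"):
    """Convenience CycleSeries builder for 10-day examples."""
    values = np.asarray(values, dtype=float)
    if days is None:
        days = np.arange(10, 10 + len(values))
    if observed is None:
        observed = ~np.isnan(values)
    return lh.CycleSeries(participant_id=pid, cycle_id=cid, channel=channel,
                          days=np.asarray(days), values=values,
                          observed=np.asarray(observed, dtype=bool))


@pytest.fixture
def clean_config():
    """Noise-free generator settings with no dropouts or failed collections."""
    return dataclasses.replace(
        lh.GeneratorConfig(),
        noise_cv=0.0, p_missing_day=0.0, p_collection_fail=0.0, seed=42,
    )


@pytest.fixture
def clean_cohort_series(clean_config):
    """A 60-cycle noise-free cohort with its normalized series (no censoring)."""
    cfg = dataclasses.replace(clean_config, n_participants=30,
                              cycles_per_participant=2, total_cycles=None)
    cohort = lh.generate_cohort(cfg)
    series = preprocess_cohort(cohort.raw_frame(), LodConfig(0, 0, 0, 0))
    return cohort, series
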