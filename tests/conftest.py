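import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from farolcare import (
    BeliefParams,
    VisitSeries,
    default_outpatient_config,
    generate_visit_series,
)


@pytest.fixture(scope="session")
def outpatient_series() -> VisitSeries:
    """One year of default synthetic outpatient counts (seed 1)."""
    return generate_visit_series(default_outpatient_config(1))


@pytest.fixture
def default_params(outpatient_series) -> BeliefParams:
    return BeliefParams(threshold=int(outpatient_series.median))


def make_series(counts, start="2020-01-01") -> VisitSeries:
    counts = np.asarray(counts, dtype=np.int64)
    return VisitSeries(pd.date_range(start, periods=len(counts), freq="D"), counts)
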