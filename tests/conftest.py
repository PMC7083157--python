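import numpy as np
import pandas as pd
import pytest

from phenoanomaly import (
    CatchArchive,
    SimulationConfig,
    SpringSeries,
    make_fixture_worked_example,
    simulate_catch_archive,
)
from phenoanomaly.catch_records import WINDOW_DAYS, day_to_date


def archive_from_counts(counts_by_year, station="test") -> CatchArchive:
    """Build an archive from {year: 45-array} (NaN = missing)."""
    return CatchArchive(
        station,
        {y: SpringSeries(y, np.asarray(c, dtype=float)) for y, c in counts_by_year.items()},
    )


def catches_frame(counts_by_year) -> pd.DataFrame:
    """date,count rows for every non-missing day (mimics the input file)."""
    rows = []
    for year, counts in sorted(counts_by_year.items()):
        for d, v in enumerate(np.asarray(counts, dtype=float), start=1):
            if not np.isnan(v):
                rows.append((day_to_date(year, d).isoformat(), v))
    return pd.DataFrame(rows, columns=["date", "count"])


@pytest.fixture
def worked_example():
    return make_fixture_worked_example()


@pytest.fixture
def sim_default():
    """One simulated archive under the default study conditions."""
    cfg = SimulationConfig(seed=11)
    archive, truth, clim = simulate_catch_archive(cfg)
    return cfg, archive, truth, clim


@pytest.fixture
def uniform_counts():
    return np.full(WINDOW_DAYS, 10.0)
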