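import numpy as np
import pytest

from cdpcast.records import ComboKey, ComboSeries, SurveyRecord


def make_series(observations, crop="cuke", cdp="mildew", pref="p01") -> ComboSeries:
    """Build a ComboSeries from {(year, month): di}."""
    return ComboSeries(ComboKey(crop, cdp, pref), dict(observations))


def make_records(rows):
    """Build SurveyRecords from (crop, cdp, pref, year, month, di) tuples."""
    return [SurveyRecord(*row) for row in rows]


@pytest.fixture
def seasonal_series():
    """Noiseless strictly month-seasonal series: DI depends on month only."""
    month_value = {4: 2.0, 5: 8.0, 6: 5.0, 7: 1.0}
    obs = {
        (year, m): v
        for year in range(2000, 2008)
        for m, v in month_value.items()
    }
    return make_series(obs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
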