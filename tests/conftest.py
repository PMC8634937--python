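"""Shared fixtures: small builders for binned series and record streams."""

from __future__ import annotations

from datetime import date, datetime, timedelta

import numpy as np
import pytest

from circwear.io import BinnedSeries, WearableRecord


@pytest.fixture
def make_series():
    """Factory for a BinnedSeries with explicit arrays (whole days)."""

    def _make(hr=None, activity=None, wear=None, sleep=None, n_days=1,
              start=date(2020, 3, 1)):
        n = n_days * 288
        hr_a = np.full(n, np.nan) if hr is None else np.asarray(hr, float)
        act_a = np.full(n, np.nan) if activity is None else np.asarray(activity, float)
        wear_a = (np.isfinite(hr_a) | np.isfinite(act_a)) if wear is None \
            else np.asarray(wear, bool)
        sleep_a = np.zeros(n, bool) if sleep is None else np.asarray(sleep, bool)
        return BinnedSeries(start_date=start, hr=hr_a, activity=act_a,
                            wear=wear_a, sleep=sleep_a)

    return _make


@pytest.fixture
def concat_series():
    """Concatenate single-day BinnedSeries into one multi-day series."""

    def _concat(series_list):
        s0 = series_list[0]
        return BinnedSeries(
            start_date=s0.start_date,
            hr=np.concatenate([s.hr for s in series_list]),
            activity=np.concatenate([s.activity for s in series_list]),
            wear=np.concatenate([s.wear for s in series_list]),
            sleep=np.concatenate([s.sleep for s in series_list]),
        )

    return _concat


@pytest.fixture
def write_records_csv(tmp_path):
    """Write WearableRecord-like tuples to a generic-dialect CSV."""

    def _write(rows, name="raw.csv"):
        path = tmp_path / name
        lines = ["timestamp,heart_rate,steps"]
        for ts, hr, steps in rows:
            lines.append(f"{ts},{'' if hr is None else hr},"
                         f"{'' if steps is None else steps}")
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
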