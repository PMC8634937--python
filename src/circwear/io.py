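"""Reading, binning, and screening of wearable heart-rate/step records.

Raw device exports arrive as delimited text with one row per reading at
irregular timestamps.  Everything downstream works on a uniform 5-minute
grid (288 bins per day): heart rate is averaged within each bin, steps are
summed, and bins with no data in either stream are marked non-wear.  A
noon-to-noon sleep heuristic flags the longest nightly run of inactive or
missing bins, since the phase model deliberately ignores sleep data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd

__all__ = [
    "WearableRecord",
    "BinnedSeries",
    "SubjectMeta",
    "read_wearable_csv",
    "read_metadata_csv",
    "bin_series",
    "detect_sleep",
    "wear_time_per_day",
    "apply_inclusion_filters",
]

log = logging.getLogger(__name__)

HR_MIN_BPM = 20.0   # plausibility gate, exclusive
HR_MAX_BPM = 250.0

_DIALECTS = {
    "generic": {"timestamp": "timestamp", "heart_rate": "heart_rate", "steps": "steps"},
    "applehealth_like": {"timestamp": "startDate", "heart_rate": "heartRate", "steps": "stepCount"},
    "fitbit_like": {"timestamp": "Time", "heart_rate": "Heart Rate", "steps": "Steps"},
}


@dataclass(frozen=True)
class WearableRecord:
    """One raw reading: local civil timestamp plus heart rate and/or steps."""

    timestamp: datetime
    heart_rate: float | None = None
    steps: int | None = None

    def __post_init__(self) -> None:
        if self.heart_rate is None and self.steps is None:
            raise ValueError("record must carry heart_rate or steps")
        if self.heart_rate is not None and not (HR_MIN_BPM < self.heart_rate < HR_MAX_BPM):
            raise ValueError(f"heart rate {self.heart_rate} outside plausibility gate")
        if self.steps is not None and (self.steps < 0 or int(self.steps) != self.steps):
            raise ValueError("steps must be a non-negative integer")


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    age_group: str = "unknown"  # under30 | 30to45 | over45 | unknown
    event_date: date | None = None
    timezone_label: str = "local"

    def __post_init__(self) -> None:
        if self.age_group not in {"under30", "30to45", "over45", "unknown"}:
            raise ValueError(f"unknown age_group {self.age_group!r}")


@dataclass
class BinnedSeries:
    """Uniform-grid series: hr (bpm, NaN = missing), activity (steps/bin,
    NaN = missing), wear and sleep masks.  The grid starts at local
    midnight of ``start_date`` and holds whole days.
    """

    start_date: date
    hr: np.ndarray
    activity: np.ndarray
    wear: np.ndarray
    sleep: np.ndarray
    bin_width: int = 5  # minutes

    def __post_init__(self) -> None:
        n = len(self.hr)
        if 1440 % self.bin_width:
            raise ValueError("bin_width must divide 1440")
        if n % self.bins_per_day:
            raise ValueError("series must hold whole days")
        for name in ("activity", "wear", "sleep"):
            if len(getattr(self, name)) != n:
                raise ValueError("all arrays must share one length")
        self.hr = np.asarray(self.hr, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.wear = np.asarray(self.wear, dtype=bool)
        self.sleep = np.asarray(self.sleep, dtype=bool)

    @property
    def bins_per_day(self) -> int:
        return 1440 // self.bin_width

    @property
    def n_days(self) -> int:
        return len(self.hr) // self.bins_per_day

    @property
    def dates(self) -> list[date]:
        return [self.start_date + timedelta(days=i) for i in range(self.n_days)]

    def hour_of_day(self) -> np.ndarray:
        """Clock hour at each bin start, in [0, 24)."""
        idx = np.arange(len(self.hr)) % self.bins_per_day
        return idx * self.bin_width / 60.0

    def day_slice(self, i: int) -> slice:
        return slice(i * self.bins_per_day, (i + 1) * self.bins_per_day)

    def to_frame(self) -> pd.DataFrame:
        bpd = self.bins_per_day
        n = len(self.hr)
        return pd.DataFrame({
            "date": [self.start_date + timedelta(days=i // bpd) for i in range(n)],
            "bin_index": np.arange(n) % bpd,
            "hr": self.hr,
            "steps": self.activity,
            "wear": self.wear.astype(int),
            "sleep": self.sleep.astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, bin_width: int = 5) -> "BinnedSeries":
        df = df.sort_values(["date", "bin_index"]).reset_index(drop=True)
        start = pd.to_datetime(df["date"].iloc[0]).date()
        return cls(
            start_date=start,
            hr=df["hr"].to_numpy(dtype=float),
            activity=df["steps"].to_numpy(dtype=float),
            wear=df["wear"].to_numpy(dtype=bool),
            sleep=df["sleep"].to_numpy(dtype=bool),
            bin_width=bin_width,
        )

    @classmethod
    def read_csv(cls, path, bin_width: int = 5) -> "BinnedSeries":
        return cls.from_frame(pd.read_csv(path), bin_width=bin_width)


def read_wearable_csv(path, dialect: str = "generic") -> list[WearableRecord]:
    """Read raw wearable rows, dropping malformed or implausible ones.

    Rows with an unparseable timestamp, a heart rate outside the
    (20, 250) bpm plausibility gate, or negative steps are skipped; the
    rejection count is logged.  Records are returned sorted by timestamp.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cols = _DIALECTS[dialect]
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        raise OSError(f"cannot read wearable file {path}: {exc}") from exc
    missing = [c for c in cols.values() if c not in df.columns and c != cols["steps"]
               and c != cols["heart_rate"]]
    if cols["timestamp"] not in df.columns:
        raise ValueError(f"missing timestamp column {cols['timestamp']!r}")

    ts = pd.to_datetime(df[cols["timestamp"]], errors="coerce", format="mixed")
    hr = pd.to_numeric(df.get(cols["heart_rate"]), errors="coerce") \
        if cols["heart_rate"] in df.columns else pd.Series(np.nan, index=df.index)
    steps = pd.to_numeric(df.get(cols["steps"]), errors="coerce") \
        if cols["steps"] in df.columns else pd.Series(np.nan, index=df.index)

    records: list[WearableRecord] = []
    rejected = 0
    for t, h, s in zip(ts, hr, steps):
        h_ok = pd.notna(h) and HR_MIN_BPM < h < HR_MAX_BPM
        s_ok = pd.notna(s) and s >= 0 and float(s).is_integer()
        if pd.isna(t) or not (h_ok or s_ok):
            rejected += 1
            continue
        if pd.notna(h) and not h_ok:
            rejected += 1  # bad hr alongside good steps: keep steps, count it
        records.append(WearableRecord(
            timestamp=t.to_pydatetime(),
            heart_rate=float(h) if h_ok else None,
            steps=int(s) if s_ok else None,
        ))
    if rejected:
        log.info("read_wearable_csv: rejected %d of %d rows in %s",
                 rejected, len(df), path)
    if not records:
        raise ValueError(f"no valid rows in {path}")
    records.sort(key=lambda r: r.timestamp)
    return records


def read_metadata_csv(path) -> list[SubjectMeta]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    out = []
    for _, row in df.iterrows():
        ev = row.get("event_date")
        out.append(SubjectMeta(
            subject_id=str(row["subject_id"]),
            age_group=str(row.get("age_group", "unknown")),
            event_date=pd.to_datetime(ev).date() if pd.notna(ev) else None,
        ))
    return out


def bin_series(records: list[WearableRecord], bin_width: int = 5) -> BinnedSeries:
    """Average heart rate and sum steps into uniform bins.

    Bin intervals are half-open [start, start + width); days run from
    local midnight.  Bins with data in neither stream are missing and
    non-wear.
    """
    if not records:
        raise ValueError("empty record list")
    if 1440 % bin_width:
        raise ValueError("bin_width must divide 1440")
    bpd = 1440 // bin_width
    t0 = min(r.timestamp for r in records)
    t1 = max(r.timestamp for r in records)
    start = t0.date()
    n_days = (t1.date() - start).days + 1
    n = n_days * bpd

    hr_sum = np.zeros(n)
    hr_cnt = np.zeros(n, dtype=int)
    st_sum = np.zeros(n)
    st_cnt = np.zeros(n, dtype=int)
    for r in records:
        minutes = (r.timestamp.date() - start).days * 1440 \
            + r.timestamp.hour * 60 + r.timestamp.minute \
            + r.timestamp.second / 60.0
        b = int(minutes // bin_width)
        if r.heart_rate is not None:
            hr_sum[b] += r.heart_rate
            hr_cnt[b] += 1
        if r.steps is not None:
            st_sum[b] += r.steps
            st_cnt[b] += 1

    hr = np.full(n, np.nan)
    hr[hr_cnt > 0] = hr_sum[hr_cnt > 0] / hr_cnt[hr_cnt > 0]
    act = np.full(n, np.nan)
    act[st_cnt > 0] = st_sum[st_cnt > 0]
    wear = (hr_cnt > 0) | (st_cnt > 0)
    return BinnedSeries(start_date=start, hr=hr, activity=act, wear=wear,
                        sleep=np.zeros(n, dtype=bool), bin_width=bin_width)


def _longest_run(candidate: np.ndarray) -> tuple[int, int]:
    """(start, length) of the longest True run; earliest start wins ties."""
    best_start, best_len = 0, 0
    i = 0
    n = len(candidate)
    while i < n:
        if candidate[i]:
            j = i
            while j < n and candidate[j]:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    return best_start, best_len


def detect_sleep(series: BinnedSeries, min_hours: float = 4.0,
                 zero_activity_as_sleep: bool = True) -> BinnedSeries:
    """Flag the nightly sleep episode on each noon-to-noon window.

    A bin is a sleep candidate when it is missing (non-wear, e.g. the
    device is charging) or records zero activity.  Per noon-to-noon
    window the single longest candidate run is flagged, provided it lasts
    at least ``min_hours``; ties break to the earliest start.
    """
    bpd = series.bins_per_day
    n = len(series.hr)
    candidate = ~series.wear
    if zero_activity_as_sleep:
        candidate = candidate | (series.activity == 0)
    sleep = np.zeros(n, dtype=bool)
    min_bins = int(round(min_hours * 60 / series.bin_width))
    half = bpd // 2
    w0 = -half
    while w0 < n:
        lo, hi = max(w0, 0), min(w0 + bpd, n)
        if hi > lo:
            s, length = _longest_run(candidate[lo:hi])
            if length >= min_bins:
                sleep[lo + s:lo + s + length] = True
        w0 += bpd
    return replace(series, sleep=sleep)


def wear_time_per_day(series: BinnedSeries) -> list[float]:
    """Hours of device wear per calendar day."""
    bpd = series.bins_per_day
    return [float(series.wear[series.day_slice(i)].sum()) * series.bin_width / 60.0
            for i in range(series.n_days)]


def apply_inclusion_filters(series: BinnedSeries, policy: str,
                            event_date: date | None = None,
                            days_pre: int = 35, days_post: int = 35,
                            ) -> tuple[bool, str]:
    """Screen a subject record against a named study policy.

    ``dlmo_study``: at most one calendar day without any wear, and at
    least 7 consecutive days carrying both heart-rate and activity data.
    ``social_rhythms``: every day spanning ``days_pre`` days before and
    ``days_post`` days after ``event_date`` (70 days at the defaults)
    must have at least one wear bin in each stream.
    """
    bpd = series.bins_per_day
    has_hr = np.array([np.isfinite(series.hr[series.day_slice(i)]).any()
                       for i in range(series.n_days)])
    has_act = np.array([np.isfinite(series.activity[series.day_slice(i)]).any()
                        for i in range(series.n_days)])
    if policy == "dlmo_study":
        zero_wear_days = sum(
            not series.wear[series.day_slice(i)].any() for i in range(series.n_days))
        if zero_wear_days > 1:
            return False, f"{zero_wear_days} days without wear (max 1)"
        both = has_hr & has_act
        best = run = 0
        for b in both:
            run = run + 1 if b else 0
            best = max(best, run)
        if best < 7:
            return False, f"only {best} consecutive complete days (need 7)"
        return True, "ok"
    if policy == "social_rhythms":
        if event_date is None:
            raise ValueError("social_rhythms policy requires event_date")
        first_needed = event_date - timedelta(days=days_pre)
        for d in range(days_pre + days_post):
            day = first_needed + timedelta(days=d)
            i = (day - series.start_date).days
            if i < 0 or i >= series.n_days or not (has_hr[i] and has_act[i]):
                return False, f"missing day {d + 1}"
        return True, "ok"
    raise ValueError(f"unknown inclusion policy {policy!r}")
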