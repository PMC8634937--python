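"""Alignment and internal-desynchrony statistics between phase markers.

Two daily phase markers are compared per subject: the predicted DLMO from
the pacemaker model and the fitted time of the heart-rate minimum (CRHR
phase).  The CRHR marker is shifted by a fixed -4.4 h, the population
mean offset between the two markers, and a day counts as aligned when the
DLMO estimate falls inside the shifted 80% credible interval of the CRHR
phase (circular containment, so intervals may wrap midnight).  Alignment
percentages and phase differences are summarized per subject over the
35-day windows before and after the disruption date, then compared across
the cohort with paired tests; phase shifts are aggregated by age group.
All phase arithmetic is circular on the 24-h clock.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
from scipy import stats

from .cosinor import PhaseTrack, circular_mean
from .io import BinnedSeries, SubjectMeta
from .oscillator import DlmoTrack

__all__ = [
    "AlignmentConfig",
    "AlignmentResult",
    "CohortSummary",
    "circular_diff",
    "day_alignment",
    "percent_days_aligned",
    "subject_alignment",
    "pre_post_alignment_test",
    "phase_shift_by_group",
    "uncertainty_weartime_correlation",
    "mean_profiles",
]


@dataclass(frozen=True)
class AlignmentConfig:
    """Fixed constants of the alignment analysis.

    ``crhr_shift_h`` is the population-mean CRHR-to-DLMO offset (-4.4 h),
    applied to the CRHR interval, not re-estimated.
    """

    crhr_shift_h: float = -4.4
    ci_level: float = 0.8
    pre_window_days: int = 35
    post_window_days: int = 35
    min_days_per_window: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.pre_window_days <= 0 or self.post_window_days <= 0:
            raise ValueError("windows must be positive")


@dataclass
class AlignmentResult:
    """Per-day alignment flags and pre/post summaries for one subject."""

    subject_id: str
    dates: list = field(default_factory=list)
    aligned: list = field(default_factory=list)
    abs_diff_h: list = field(default_factory=list)
    pct_aligned_pre: float = float("nan")
    pct_aligned_post: float = float("nan")
    mean_abs_diff_pre: float = float("nan")
    mean_abs_diff_post: float = float("nan")


@dataclass
class CohortSummary:
    """Cohort-level headline quantities."""

    pct_aligned_pre_mean: float
    pct_aligned_post_mean: float
    paired_t_p: float
    wilcoxon_p: float
    n_subjects: int
    group_shift: dict = field(default_factory=dict)  # group -> (mean, sem, n, p)
    between_group_p: dict = field(default_factory=dict)
    correlation: tuple = (float("nan"), float("nan"))


def circular_diff(t1: float, t2: float) -> float:
    """Minimal signed difference t1 - t2 on the 24-h circle, in (-12, 12]."""
    d = (float(t1) - float(t2)) % 24.0
    return d - 24.0 if d > 12.0 else d


def day_alignment(dlmo_h: float, crhr_low: float, crhr_high: float,
                  shift_h: float = -4.4) -> bool:
    """Is the DLMO inside the shifted CRHR interval (circular containment)?

    The interval runs counter-clockwise from ``crhr_low`` to ``crhr_high``
    (wrapping midnight when high < low); both endpoints are shifted by
    ``shift_h`` modulo 24 before the test.
    """
    lo = (crhr_low + shift_h) % 24.0
    hi = (crhr_high + shift_h) % 24.0
    span = (hi - lo) % 24.0
    return ((dlmo_h - lo) % 24.0) <= span


def _window_days(event_date: date, cfg: AlignmentConfig):
    pre = {event_date - timedelta(days=k) for k in range(1, cfg.pre_window_days + 1)}
    post = {event_date + timedelta(days=k) for k in range(1, cfg.post_window_days + 1)}
    return pre, post  # the event day itself belongs to neither window


def percent_days_aligned(dlmo_track: DlmoTrack, crhr_track: PhaseTrack,
                         window, cfg: AlignmentConfig = AlignmentConfig(),
                         ) -> float:
    """Percentage of aligned days among days where both markers exist.

    ``window`` is an iterable of dates; days with either marker missing
    do not enter the denominator.
    """
    dlmo = dict(zip(dlmo_track.dates, dlmo_track.dlmo_h))
    crhr = {d: (lo, hi) for d, lo, hi in
            zip(crhr_track.dates, crhr_track.ci_low_h, crhr_track.ci_high_h)}
    both = [d for d in window if d in dlmo and d in crhr]
    if not both:
        raise ValueError("no days with both phase markers in window")
    n_aligned = sum(day_alignment(dlmo[d], *crhr[d], cfg.crhr_shift_h)
                    for d in both)
    return 100.0 * n_aligned / len(both)


def subject_alignment(subject_id: str, dlmo_track: DlmoTrack,
                      crhr_track: PhaseTrack, event_date: date,
                      cfg: AlignmentConfig = AlignmentConfig(),
                      ) -> AlignmentResult:
    """Per-day alignment flags plus pre/post summaries for one subject."""
    dlmo = dict(zip(dlmo_track.dates, dlmo_track.dlmo_h))
    crhr = {d: (ph, lo, hi) for d, ph, lo, hi in
            zip(crhr_track.dates, crhr_track.phase_h,
                crhr_track.ci_low_h, crhr_track.ci_high_h)}
    res = AlignmentResult(subject_id=subject_id)
    pre, post = _window_days(event_date, cfg)
    stats_by_win = {"pre": ([], []), "post": ([], [])}
    for d in sorted(set(dlmo) & set(crhr)):
        ph, lo, hi = crhr[d]
        ok = day_alignment(dlmo[d], lo, hi, cfg.crhr_shift_h)
        diff = abs(circular_diff(dlmo[d], (ph + cfg.crhr_shift_h) % 24.0))
        res.dates.append(d)
        res.aligned.append(bool(ok))
        res.abs_diff_h.append(diff)
        if d in pre:
            stats_by_win["pre"][0].append(ok)
            stats_by_win["pre"][1].append(diff)
        elif d in post:
            stats_by_win["post"][0].append(ok)
            stats_by_win["post"][1].append(diff)
    for win, attr in (("pre", "pre"), ("post", "post")):
        flags, diffs = stats_by_win[win]
        if flags:
            setattr(res, f"pct_aligned_{attr}", 100.0 * np.mean(flags))
            setattr(res, f"mean_abs_diff_{attr}", float(np.mean(diffs)))
    return res


def pre_post_alignment_test(results: list[AlignmentResult]) -> dict:
    """Paired comparison of per-subject alignment before vs after the event.

    Two-sided paired t-test (primary) with a Wilcoxon signed-rank p
    reported alongside.  Subjects lacking either window are dropped.
    """
    pairs = [(r.pct_aligned_pre, r.pct_aligned_post) for r in results
             if np.isfinite(r.pct_aligned_pre) and np.isfinite(r.pct_aligned_post)]
    if len(pairs) < 2:
        raise ValueError("need at least 2 subjects with both windows")
    pre = np.array([p for p, _ in pairs])
    post = np.array([q for _, q in pairs])
    degenerate = bool(np.all(pre == post))
    if degenerate:
        t_p = w_p = 1.0
    else:
        t_p = float(stats.ttest_rel(pre, post).pvalue)
        try:
            w_p = float(stats.wilcoxon(pre, post).pvalue)
        except ValueError:
            w_p = 1.0
    return {
        "mean_pre": float(np.mean(pre)),
        "mean_post": float(np.mean(post)),
        "mean_drop": float(np.mean(pre - post)),
        "paired_t_p": t_p,
        "wilcoxon_p": w_p,
        "n": len(pairs),
        "degenerate": degenerate,
    }


def _subject_shift(track: PhaseTrack, event_date: date, cfg: AlignmentConfig,
                   ) -> float | None:
    pre_days, post_days = _window_days(event_date, cfg)
    pre = [p for d, p in zip(track.dates, track.phase_h) if d in pre_days]
    post = [p for d, p in zip(track.dates, track.phase_h) if d in post_days]
    if len(pre) < cfg.min_days_per_window or len(post) < cfg.min_days_per_window:
        return None
    return circular_diff(circular_mean(np.array(post)), circular_mean(np.array(pre)))


def phase_shift_by_group(tracks: dict[str, PhaseTrack],
                         metas: list[SubjectMeta],
                         cfg: AlignmentConfig = AlignmentConfig()) -> dict:
    """Post-minus-pre phase shift (circular, hours) aggregated by age group.

    Per subject the shift is the circular mean of post-window daily phases
    minus the circular mean of pre-window phases, taken as the minimal
    signed difference.  Per group: mean +/- SEM, a one-sample t-test
    against zero shift, and Welch t-tests between group pairs.
    """
    by_group: dict[str, list[float]] = {}
    excluded: list[str] = []
    for meta in metas:
        if meta.subject_id not in tracks or meta.event_date is None:
            continue
        shift = _subject_shift(tracks[meta.subject_id], meta.event_date, cfg)
        if shift is None:
            excluded.append(meta.subject_id)
            continue
        by_group.setdefault(meta.age_group, []).append(shift)
    out = {"groups": {}, "between": {}, "excluded": excluded}
    for g, vals in by_group.items():
        v = np.array(vals)
        sem = float(stats.sem(v)) if v.size > 1 else float("nan")
        p = float(stats.ttest_1samp(v, 0.0).pvalue) if v.size > 1 else float("nan")
        out["groups"][g] = {"mean": float(np.mean(v)), "sem": sem,
                            "n": int(v.size), "p_vs_zero": p}
    names = sorted(by_group)
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            if len(by_group[g1]) > 1 and len(by_group[g2]) > 1:
                p = float(stats.ttest_ind(by_group[g1], by_group[g2],
                                          equal_var=False).pvalue)
                out["between"][f"{g1}_vs_{g2}"] = p
    return out


def uncertainty_weartime_correlation(half_widths, data_quantity) -> tuple[float, float]:
    """Pearson correlation between data quantity and phase uncertainty.

    ``data_quantity`` is the per-day usable-bin count (or wear hours);
    both series are pooled over subject-days.  Returns (r, two-sided p).
    """
    x = np.asarray(data_quantity, dtype=float)
    y = np.asarray(half_widths, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def mean_profiles(series_list: list[BinnedSeries], event_dates: list[date],
                  cfg: AlignmentConfig = AlignmentConfig()) -> dict:
    """Cohort-mean daily profiles of heart rate and activity, pre and post.

    Per subject and bin-of-day, days in each window are averaged
    (missing bins propagate as missing, never as zero); the cohort mean
    and the SEM across subjects are then taken per bin.  Returns
    ``{stream: {window: {"mean": (288,), "sem": (288,), "n": int}}}``.
    """
    out: dict = {}
    for stream in ("hr", "activity"):
        out[stream] = {}
        for window in ("pre", "post"):
            profiles = []
            for series, ev in zip(series_list, event_dates):
                days, _ = _window_days(ev, cfg) if window == "pre" else (None, None)
                pre_d, post_d = _window_days(ev, cfg)
                want = pre_d if window == "pre" else post_d
                rows = []
                for i, d in enumerate(series.dates):
                    if d in want:
                        rows.append(getattr(series, stream)[series.day_slice(i)])
                if rows:
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        profiles.append(np.nanmean(np.vstack(rows), axis=0))
            if not profiles:
                out[stream][window] = {"mean": None, "sem": None, "n": 0,
                                       "empty": True}
                continue
            P = np.vstack(profiles)
            import warnings

            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(P, axis=0)
                n_eff = np.sum(np.isfinite(P), axis=0)
                sd = np.nanstd(P, axis=0, ddof=1) if P.shape[0] > 1 else np.zeros(P.shape[1])
            sem = np.where(n_eff > 1, sd / np.sqrt(np.maximum(n_eff, 1)), 0.0)
            out[stream][window] = {"mean": mean, "sem": sem, "n": P.shape[0]}
    return out
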