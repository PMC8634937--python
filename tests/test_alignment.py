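"""Circular phase arithmetic, containment, and cohort statistics."""

from datetime import date, timedelta

import numpy as np
import pytest
from scipy import stats

from circwear.alignment import (AlignmentConfig, AlignmentResult, circular_diff,
                                day_alignment, mean_profiles,
                                percent_days_aligned, phase_shift_by_group,
                                pre_post_alignment_test, subject_alignment,
                                uncertainty_weartime_correlation)
from circwear.cosinor import PhaseTrack
from circwear.io import SubjectMeta
from circwear.oscillator import DlmoTrack


def _brute_circular_diff(t1, t2):
    return min((t1 - t2 + k for k in (-24.0, 0.0, 24.0)), key=abs)


def _brute_contains(point, lo, hi, step=0.01):
    """Walk the interval on a fine grid from lo toward hi (circularly)."""
    h = lo
    span = (hi - lo) % 24.0
    steps = int(span / step) + 1
    for i in range(steps + 1):
        if abs(circular_diff(point, (lo + min(i * step, span)) % 24.0)) < step / 2:
            return True
    return False


class TestCircularDiff:
    def test_identity(self):
        assert circular_diff(5.0, 5.0) == 0.0

    def test_wraps_forward(self):
        assert circular_diff(23.0, 1.0) == pytest.approx(-2.0)

    def test_wraps_backward(self):
        assert circular_diff(1.0, 23.0) == pytest.approx(2.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(2000):
            t1, t2 = rng.uniform(0, 24, 2)
            assert circular_diff(t1, t2) == pytest.approx(
                _brute_circular_diff(t1, t2), abs=1e-9)

    def test_invariant_to_full_turn_relabel(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            t1, t2 = rng.uniform(0, 24, 2)
            assert circular_diff((t1 + 24.0) % 24.0, t2) == pytest.approx(
                circular_diff(t1, t2))


class TestDayAlignment:
    def test_midpoint_contained(self):
        assert day_alignment(12.0, 11.0, 13.0, shift_h=0.0)

    def test_wrapping_interval(self):
        # shifted interval (23.5, 0.5): 23.8 inside
        assert day_alignment(23.8, 23.5 + 4.4, 0.5 + 4.4)

    def test_outside(self):
        assert not day_alignment(7.0, 4.0 + 4.4, 6.0 + 4.4)

    def test_matches_brute_force_grid_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(2000):
            lo = rng.uniform(0, 24)
            hi = (lo + rng.uniform(0, 12)) % 24.0
            point = rng.uniform(0, 24)
            got = day_alignment(point, lo, hi, shift_h=0.0)
            want = _brute_contains(point, lo, hi)
            if abs(circular_diff(point, lo)) < 0.02 or \
               abs(circular_diff(point, hi)) < 0.02:
                continue  # boundary cases differ only at grid resolution
            assert got == want


class TestPercentDaysAligned:
    def _tracks(self, n, aligned_flags):
        d0 = date(2020, 3, 1)
        dates = [d0 + timedelta(days=i) for i in range(n)]
        crhr = PhaseTrack()
        dlmo = DlmoTrack()
        for i, ok in enumerate(aligned_flags):
            crhr.append(dates[i], 5.0, 4.5, 5.5, 0.5, 100)
            dlmo.dates.append(dates[i])
            dlmo.dlmo_h.append((5.0 if ok else 11.0))
        return dlmo, crhr, dates

    def test_all_aligned(self):
        dlmo, crhr, dates = self._tracks(5, [True] * 5)
        cfg = AlignmentConfig(crhr_shift_h=0.0)
        assert percent_days_aligned(dlmo, crhr, dates, cfg) == 100.0

    def test_seven_of_ten(self):
        dlmo, crhr, dates = self._tracks(10, [True] * 7 + [False] * 3)
        cfg = AlignmentConfig(crhr_shift_h=0.0)
        assert percent_days_aligned(dlmo, crhr, dates, cfg) == 70.0

    def test_missing_marker_days_excluded_from_denominator(self):
        dlmo, crhr, dates = self._tracks(10, [True] * 7 + [False] * 3)
        extra = [dates[-1] + timedelta(days=k) for k in (1, 2, 3)]
        cfg = AlignmentConfig(crhr_shift_h=0.0)
        assert percent_days_aligned(dlmo, crhr, dates + extra, cfg) == 70.0

    def test_no_overlap_raises(self):
        dlmo, crhr, dates = self._tracks(3, [True] * 3)
        with pytest.raises(ValueError):
            percent_days_aligned(dlmo, crhr,
                                 [date(1999, 1, 1)], AlignmentConfig())

    def test_self_alignment_is_total(self):
        # DLMO track equal to CRHR phases, zero shift: always contained
        d0 = date(2020, 3, 1)
        rng = np.random.default_rng(3)
        crhr = PhaseTrack()
        dlmo = DlmoTrack()
        dates = []
        for i in range(20):
            ph = rng.uniform(0, 24)
            d = d0 + timedelta(days=i)
            crhr.append(d, ph, (ph - 0.4) % 24, (ph + 0.4) % 24, 0.4, 50)
            dlmo.dates.append(d)
            dlmo.dlmo_h.append(ph)
            dates.append(d)
        cfg = AlignmentConfig(crhr_shift_h=0.0)
        assert percent_days_aligned(dlmo, crhr, dates, cfg) == 100.0


class TestPrePostTest:
    def _result(self, pre, post):
        r = AlignmentResult(subject_id="s")
        r.pct_aligned_pre = pre
        r.pct_aligned_post = post
        return r

    def test_imposed_drop_detected_with_power(self):
        rng = np.random.default_rng(0)
        detections = 0
        n_rep = 20
        for _ in range(n_rep):
            results = [self._result(p, p - 10.0 + rng.normal(0, 8))
                       for p in rng.uniform(60, 90, 50)]
            out = pre_post_alignment_test(results)
            detections += out["paired_t_p"] < 0.01
        assert detections >= 0.9 * n_rep

    def test_degenerate_equal_windows(self):
        out = pre_post_alignment_test([self._result(70, 70),
                                       self._result(80, 80)])
        assert out["degenerate"] and out["paired_t_p"] == 1.0

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            pre_post_alignment_test([self._result(70, 60)])


def _track_with_phases(pre_phases, post_phases, event):
    tr = PhaseTrack()
    for i, p in enumerate(pre_phases):
        d = event - timedelta(days=len(pre_phases) - i)
        tr.append(d, p % 24.0, p % 24.0, p % 24.0, 0.1, 100)
    for i, p in enumerate(post_phases):
        tr.append(event + timedelta(days=i + 1), p % 24.0, p % 24.0,
                  p % 24.0, 0.1, 100)
    return tr


class TestPhaseShiftByGroup:
    EVENT = date(2020, 3, 20)

    def test_recovers_imposed_group_shift(self):
        rng = np.random.default_rng(5)
        tracks, metas = {}, []
        true_shift = 1.26
        for s in range(12):
            base = rng.uniform(0, 24)
            pre = base + rng.normal(0, 0.2, 10)
            post = base + true_shift + rng.normal(0, 0.2, 10)
            sid = f"g{s}"
            tracks[sid] = _track_with_phases(pre, post, self.EVENT)
            metas.append(SubjectMeta(sid, "30to45", self.EVENT))
        out = phase_shift_by_group(tracks, metas,
                                   AlignmentConfig(pre_window_days=10,
                                                   post_window_days=10))
        g = out["groups"]["30to45"]
        assert abs(g["mean"] - true_shift) < 2 * g["sem"] + 0.05

    def test_null_subject_has_zero_shift(self):
        tracks = {"s": _track_with_phases([5.0] * 6, [5.0] * 6, self.EVENT)}
        metas = [SubjectMeta("s", "under30", self.EVENT)]
        out = phase_shift_by_group(tracks, metas,
                                   AlignmentConfig(pre_window_days=6,
                                                   post_window_days=6))
        assert out["groups"]["under30"]["mean"] == pytest.approx(0.0)

    def test_shift_across_midnight_is_circular(self):
        tracks = {"s": _track_with_phases([23.5] * 6, [0.5] * 6, self.EVENT)}
        metas = [SubjectMeta("s", "over45", self.EVENT)]
        out = phase_shift_by_group(tracks, metas,
                                   AlignmentConfig(pre_window_days=6,
                                                   post_window_days=6))
        assert out["groups"]["over45"]["mean"] == pytest.approx(1.0)

    def test_subject_below_day_minimum_excluded(self):
        tracks = {"s": _track_with_phases([5.0] * 2, [6.0] * 2, self.EVENT)}
        metas = [SubjectMeta("s", "under30", self.EVENT)]
        out = phase_shift_by_group(tracks, metas, AlignmentConfig())
        assert out["excluded"] == ["s"] and not out["groups"]


class TestUncertaintyCorrelation:
    def test_perfect_negative_line(self):
        x = np.arange(10.0)
        r, _ = uncertainty_weartime_correlation(10.0 - x, x)
        assert r == pytest.approx(-1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(20):
            r, _ = uncertainty_weartime_correlation(rng.normal(size=1000),
                                                    rng.normal(size=1000))
            hits += abs(r) < 0.1
        assert hits >= 19

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_weartime_correlation([1.0, 2.0], [2.0, 1.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_weartime_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMeanProfiles:
    def test_single_day_equals_itself(self, make_series):
        hr = np.full(288, np.nan)
        hr[100:200] = 70.0
        s = make_series(hr=hr)
        ev = s.start_date + timedelta(days=1)  # the one day is "pre"
        out = mean_profiles([s], [ev])
        np.testing.assert_allclose(out["hr"]["pre"]["mean"][100:200], 70.0)
        assert np.isnan(out["hr"]["pre"]["mean"][0])

    def test_two_flat_subjects_mean_and_sem(self, make_series):
        s60 = make_series(hr=np.full(288, 60.0))
        s70 = make_series(hr=np.full(288, 70.0))
        ev = s60.start_date + timedelta(days=1)
        out = mean_profiles([s60, s70], [ev, ev])
        np.testing.assert_allclose(out["hr"]["pre"]["mean"], 65.0)
        np.testing.assert_allclose(out["hr"]["pre"]["sem"], 5.0)

    def test_missing_bins_propagate_not_zero(self, make_series):
        hr = np.full(288, 60.0)
        hr[0:10] = np.nan
        s = make_series(hr=hr)
        ev = s.start_date + timedelta(days=1)
        out = mean_profiles([s], [ev])
        assert np.isnan(out["hr"]["pre"]["mean"][:10]).all()

    def test_empty_window_flagged(self, make_series):
        s = make_series(hr=np.full(288, 60.0))
        ev = s.start_date - timedelta(days=40)  # no data in either window
        out = mean_profiles([s], [ev])
        assert out["hr"]["pre"]["n"] == 0 and out["hr"]["pre"].get("empty")


class TestSubjectAlignment:
    def test_event_day_in_neither_window(self):
        event = date(2020, 3, 20)
        crhr = PhaseTrack()
        dlmo = DlmoTrack()
        for off in (-1, 0, 1):
            d = event + timedelta(days=off)
            crhr.append(d, 5.0, 4.0, 6.0, 1.0, 100)
            dlmo.dates.append(d)
            dlmo.dlmo_h.append(0.6)  # 5.0 - 4.4: exactly aligned
        res = subject_alignment("s", dlmo, crhr, event)
        assert len(res.dates) == 3
        assert res.pct_aligned_pre == 100.0 and res.pct_aligned_post == 100.0
        # one day in each window; the event day contributes to neither
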