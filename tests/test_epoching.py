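import numpy as np
import pandas as pd
import pytest

from conftest import make_epoch, sort_median
from vocmotion import epoching
from vocmotion.epoching import (analytic_envelope, baseline_diffs,
                                envelope_baseline_correct, extract_epochs,
                                full_hilbert_envelope,
                                grand_average_envelope, locate_inflection,
                                window_medians)
from vocmotion.types import (EPOCH_LEN, ONSET_INDEX, MagnitudeSeries,
                             Placement, VocEvent, WindowBounds,
                             epoch_time_grid)

PL = Placement("infant", "arm", "left")
BOUNDS = WindowBounds()


def series(values, t0=0.0, mask=None):
    values = np.asarray(values, float)
    t = t0 + np.arange(values.size) / 60.0
    return MagnitudeSeries(t=t, value=values, rate=60.0, placement=PL,
                           mask=mask)


def test_window_sample_counts():
    # at 60 Hz, half-open windows hold 96/54/54 samples
    assert BOUNDS.sample_slice("base").stop - \
        BOUNDS.sample_slice("base").start == 96
    for w in ("pre", "during"):
        sl = BOUNDS.sample_slice(w)
        assert sl.stop - sl.start == 54
    assert BOUNDS.sample_slice("during").start == ONSET_INDEX


class TestExtractEpochs:
    def test_mid_series_event(self, rng):
        s = series(rng.normal(size=1200))  # 20 s
        eps = extract_epochs(s, [VocEvent(10.0, 10.5)], BOUNDS)
        assert len(eps) == 1
        ep = eps[0]
        assert not ep.excluded
        assert ep.raw.size == EPOCH_LEN

    def test_edge_event_excluded(self, rng):
        s = series(rng.normal(size=1200))
        with pytest.warns(UserWarning):
            eps = extract_epochs(s, [VocEvent(1.0, 1.4)], BOUNDS)
        assert eps[0].excluded and eps[0].reason == "edge"

    def test_artifact_overlap_excluded(self, rng):
        mask = np.zeros(1200, bool)
        mask[700:705] = True  # t ~ 11.7 s, inside [6.5, 15] span
        s = series(rng.normal(size=1200), mask=mask)
        with pytest.warns(UserWarning):
            eps = extract_epochs(s, [VocEvent(10.0, 10.5)], BOUNDS)
        assert eps[0].excluded and eps[0].reason == "artifact"

    def test_overlapping_events_flagged_and_optionally_excluded(self, rng):
        s = series(rng.normal(size=2400))  # 40 s
        evs = [VocEvent(10.0, 10.5), VocEvent(12.0, 12.4),
               VocEvent(30.0, 30.5)]
        eps = extract_epochs(s, evs, BOUNDS)
        assert [e.overlaps_next for e in eps] == [True, False, False]
        assert all(not e.excluded for e in eps)
        eps2 = extract_epochs(s, evs, BOUNDS, exclude_overlapping=True)
        assert eps2[0].excluded and eps2[0].reason == "overlap"


class TestBaselineCorrect:
    def test_constant(self):
        ep = make_epoch(np.full(EPOCH_LEN, 2.0))
        envelope_baseline_correct(ep, BOUNDS)
        assert np.max(np.abs(ep.baselined)) < 1e-12

    def test_sinusoid_about_offset(self):
        t = epoch_time_grid()
        A, m = 1.5, 4.0
        ep = make_epoch(m + A * np.sin(2 * np.pi * 5 * t))
        envelope_baseline_correct(ep, BOUNDS)
        tail = ep.baselined[BOUNDS.reference_slice()]
        assert abs(np.mean(tail)) < 0.02 * A

    def test_shift_invariance(self, rng):
        base = rng.normal(size=EPOCH_LEN)
        ep1 = make_epoch(base)
        ep2 = make_epoch(base + 7.3)
        envelope_baseline_correct(ep1, BOUNDS)
        envelope_baseline_correct(ep2, BOUNDS)
        assert np.max(np.abs(ep1.baselined - ep2.baselined)) < 1e-9

    def test_idempotent(self, rng):
        t = epoch_time_grid()
        ep = make_epoch(2.0 + np.sin(2 * np.pi * 4 * t)
                        + 0.1 * rng.normal(size=EPOCH_LEN))
        envelope_baseline_correct(ep, BOUNDS)
        again = make_epoch(ep.baselined.copy())
        envelope_baseline_correct(again, BOUNDS)
        assert np.max(np.abs(again.baselined - ep.baselined)) < 1e-6


class TestAnalyticEnvelope:
    def test_zero_signal(self):
        ep = make_epoch(np.zeros(EPOCH_LEN))
        analytic_envelope(ep)
        assert np.max(ep.envelope) == 0.0

    def test_tone_amplitude(self):
        t = epoch_time_grid()
        ep = make_epoch(2.0 * np.sin(2 * np.pi * 5 * t))
        analytic_envelope(ep)
        mid = ep.envelope[100:400]
        assert np.max(np.abs(mid - 2.0)) / 2.0 < 0.05

    def test_am_burst_peak_location(self):
        t = epoch_time_grid()
        gauss = np.exp(-0.5 * (t / 0.5) ** 2)
        x = gauss * np.sin(2 * np.pi * 6 * t)
        ep = make_epoch(x)
        analytic_envelope(ep)
        oracle = full_hilbert_envelope(x)
        assert abs(int(np.argmax(ep.envelope)) -
                   int(np.argmax(oracle))) <= 2

    def test_tracks_full_hilbert_oracle_mid_epoch(self, rng):
        t = epoch_time_grid()
        x = np.sin(2 * np.pi * 6 * t) * (1.0 + 0.3 * np.sin(2 * np.pi * t))
        ep = make_epoch(x)
        analytic_envelope(ep)
        oracle = full_hilbert_envelope(x)
        mid = slice(60, -60)
        rel = np.abs(ep.envelope[mid] - oracle[mid]) / np.max(oracle)
        assert np.percentile(rel, 95) < 0.05


class TestGrandAverage:
    def test_identical_epochs(self, rng):
        c = rng.normal(size=EPOCH_LEN)
        mean, se = grand_average_envelope([c, c, c])
        assert np.allclose(mean, c)
        assert np.allclose(se, 0.0)

    def test_two_curve_closed_form(self):
        mean, se = grand_average_envelope(
            [np.zeros(EPOCH_LEN), np.full(EPOCH_LEN, 2.0)])
        assert np.allclose(mean, 1.0)
        assert np.allclose(se, 1.0)  # sd=sqrt(2), se=sd/sqrt(2)

    def test_clt_against_population_curve(self, rng):
        t = epoch_time_grid()
        truth = 1.0 + 0.5 * np.exp(-0.5 * (t / 0.7) ** 2)
        curves = truth + rng.normal(0, 0.4, size=(200, EPOCH_LEN))
        mean, se = grand_average_envelope(list(curves))
        frac_ok = np.mean(np.abs(mean - truth) < 3 * se)
        assert frac_ok >= 0.99

    def test_single_epoch_rejected(self):
        with pytest.raises(ValueError):
            grand_average_envelope([np.zeros(EPOCH_LEN)])


class TestLocateInflection:
    def test_ramp_knee(self):
        t = epoch_time_grid()
        curve = np.where(t < 0.9, 1.0 + t * 0.0, 1.0)
        curve = 1.0 + np.clip(t, 0, 0.9)  # rises to knee at +0.9 s
        out = locate_inflection(curve, smooth_s=0.0)
        assert out["post"] == pytest.approx(0.9, abs=1 / 60 + 1e-9)

    def test_symmetric_tent(self):
        t = epoch_time_grid()
        a = 1.2
        curve = np.clip(a - np.abs(t), 0, None)
        out = locate_inflection(curve, smooth_s=0.0)
        assert out["post"] == pytest.approx(-out["pre"], abs=1 / 60 + 1e-9)

    def test_simulated_audio_bursts(self, rng):
        # mean envelope of 0.6 s bursts: boundary lands in [0.5, 1.3] s
        t = epoch_time_grid()
        curves = []
        for _ in range(80):
            dur = rng.lognormal(np.log(0.6), 0.3)
            env = np.where((t >= 0) & (t < dur), 1.0, 0.05)
            curves.append(env + rng.normal(0, 0.05, t.size))
        mean, _ = grand_average_envelope(curves)
        out = locate_inflection(mean)
        assert 0.5 <= out["post"] <= 1.3


class TestWindowMedians:
    def _stepped(self, base, pre, during, **kw):
        v = np.zeros(EPOCH_LEN)
        v[BOUNDS.sample_slice("base")] = base
        v[BOUNDS.sample_slice("pre")] = pre
        v[BOUNDS.sample_slice("during")] = during
        return make_epoch(v, as_envelope=True, **kw)

    def test_constant_windows(self):
        eps = [self._stepped(1, 2, 3, side="left"),
               self._stepped(1, 2, 3, side="right")]
        rows = window_medians(eps, BOUNDS).set_index("window")
        assert rows.loc["base", "median"] == 1
        assert rows.loc["pre", "median"] == 2
        assert rows.loc["during", "median"] == 3

    def test_side_average(self):
        eps = [self._stepped(1, 1, 1, side="left"),
               self._stepped(3, 3, 3, side="right")]
        rows = window_medians(eps, BOUNDS)
        assert (rows["median"] == 2.0).all()
        assert (rows["n_sides"] == 2).all()

    def test_against_sort_based_oracle(self, rng):
        eps = []
        for side in ("left", "right"):
            v = rng.normal(size=EPOCH_LEN) ** 2
            eps.append(make_epoch(v, side=side, as_envelope=True))
        rows = window_medians(eps, BOUNDS).set_index("window")
        for w in ("base", "pre", "during"):
            sl = BOUNDS.sample_slice(w)
            oracle = np.mean([sort_median(ep.envelope[sl]) for ep in eps])
            assert rows.loc[w, "median"] == pytest.approx(oracle, abs=1e-12)

    def test_side_permutation_symmetry(self, rng):
        a = make_epoch(rng.normal(size=EPOCH_LEN) ** 2, side="left",
                       as_envelope=True)
        b = make_epoch(rng.normal(size=EPOCH_LEN) ** 2, side="right",
                       as_envelope=True)
        r1 = window_medians([a, b], BOUNDS)
        a.placement, b.placement = b.placement, a.placement
        r2 = window_medians([b, a], BOUNDS)
        pd.testing.assert_frame_equal(r1, r2)

    def test_scale_equivariance(self, rng):
        eps = [make_epoch(rng.normal(size=EPOCH_LEN) ** 2, side=s,
                          as_envelope=True) for s in ("left", "right")]
        r1 = window_medians(eps, BOUNDS)
        for ep in eps:
            ep.envelope = ep.envelope * 3.0
        r2 = window_medians(eps, BOUNDS)
        assert np.allclose(r2["median"], 3.0 * r1["median"])

    def test_missing_side_flagged(self):
        eps = [self._stepped(1, 2, 3, side="left")]
        rows = window_medians(eps, BOUNDS)
        assert (rows["n_sides"] == 1).all()


class TestBaselineDiffs:
    def _rows(self, base, pre, during):
        return pd.DataFrame({
            "infant_id": ["i"] * 3, "time_point": [6] * 3,
            "limb": ["arm"] * 3, "window": ["base", "pre", "during"],
            "event": [0] * 3, "median": [base, pre, during]})

    def test_arithmetic(self):
        out = baseline_diffs(self._rows(1.0, 2.0, 3.0))
        assert out.loc[0, "diff_pre"] == 1.0
        assert out.loc[0, "diff_during"] == 2.0

    def test_pre_equals_base(self):
        out = baseline_diffs(self._rows(1.5, 1.5, 2.0))
        assert out.loc[0, "diff_pre"] == 0.0

    def test_noise_free_simulated_diffs_exact(self, quiet_simconfig):
        from vocmotion.synthetic import simulate_session
        from vocmotion import preprocess
        cfg = quiet_simconfig
        sess, _ = simulate_session("x", 9, (0.0, 0.0), cfg, seed=2,
                                   degrade=False)
        eps = []
        for ch in sess.channels:
            if ch.placement.wearer != "infant":
                continue
            s = preprocess.highpass(preprocess.magnitude(ch))
            chunk = extract_epochs(s, sess.events, BOUNDS, infant_id="x",
                                   time_point=9)
            for ep in chunk:
                envelope_baseline_correct(ep, BOUNDS)
                analytic_envelope(ep)
            eps.extend(chunk)
        rows = window_medians(eps, BOUNDS)
        diffs = baseline_diffs(rows)
        for limb in ("arm", "leg"):
            sub = diffs[diffs["limb"] == limb]
            want_pre = cfg.delta(9, limb, "pre")
            want_dur = cfg.delta(9, limb, "during")
            assert np.mean(sub["diff_pre"]) == pytest.approx(want_pre,
                                                             abs=0.02)
            assert np.mean(sub["diff_during"]) == pytest.approx(want_dur,
                                                                abs=0.02)
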