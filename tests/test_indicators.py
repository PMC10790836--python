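"""Indicator extraction: window conventions, integrals, anticipation delay."""

import numpy as np
import pytest

import riskbn
from riskbn.design import SessionDesign, TrialSpec
from riskbn.eda import ScrEvent
from riskbn.indicators import (
    WindowParams,
    assign_scr_indicators,
    compute_sa_indicators,
    compute_w_start,
    extract_indicators,
)
from riskbn.synthesize import SliderTrace


def toy_design(t_levels, ttc=2.0, offset=1.5):
    trials = tuple(
        TrialSpec(i, ttc, offset, "same", "left", t_start=tl - ttc, t_level=tl)
        for i, tl in enumerate(t_levels)
    )
    return SessionDesign(participant_id=0, trials=trials)


def slider_from(t_end, bumps, rate=20.0):
    """Piecewise-linear slider: bumps are (onset, peak_time, end, height)."""
    t = np.arange(int(t_end * rate)) / rate
    y = np.zeros_like(t)
    for t0, tp, t1, h in bumps:
        up = (t >= t0) & (t <= tp)
        down = (t > tp) & (t <= t1)
        y[up] = h * (t[up] - t0) / (tp - t0)
        y[down] = h * (t1 - t[down]) / (t1 - tp)
    return SliderTrace(t=t, y=y, rate=rate)


class TestSaIndicators:
    def test_zero_slider_gives_zero_indicators(self):
        design = toy_design([20.0, 45.0])
        slider = slider_from(70.0, [])
        out = compute_sa_indicators(slider, design)
        assert (out.msa == 0).all() and (out.isa == 0).all()

    def test_triangle_height_and_area(self):
        # height 0.8, base 5 s -> mSA = 0.8, iSA = 0.8*5/2 = 2.0
        design = toy_design([20.0])
        slider = slider_from(40.0, [(17.0, 20.0, 22.0, 0.8)])
        out = compute_sa_indicators(slider, design)
        assert out.msa[0] == pytest.approx(0.8, abs=1e-12)
        assert out.isa[0] == pytest.approx(2.0, abs=1e-9)

    def test_half_sine_area_matches_dense_quadrature(self):
        design = toy_design([20.0])
        rate = 20.0
        t = np.arange(int(40 * rate)) / rate
        y = np.where((t >= 18) & (t <= 22), np.sin(np.pi * (t - 18) / 4.0), 0.0)
        out = compute_sa_indicators(SliderTrace(t=t, y=y, rate=rate), design)
        dense = np.linspace(18, 22, 200001)
        oracle = np.trapezoid(np.sin(np.pi * (dense - 18) / 4.0), dense)
        assert out.isa[0] == pytest.approx(oracle, abs=1e-3)

    def test_unbounded_window_warns_and_falls_back(self):
        design = toy_design([20.0, 45.0])
        t = np.arange(int(70 * 20)) / 20.0
        y = np.full_like(t, 0.2)  # never returns to zero
        with pytest.warns(UserWarning):
            out = compute_sa_indicators(SliderTrace(t=t, y=y, rate=20.0), design)
        assert (out.msa == 0.2).all()


class TestWStart:
    def test_constant_anticipation(self):
        design = toy_design([20.0, 45.0])
        slider = slider_from(
            70.0, [(16.0, 20.0, 23.0, 0.5), (41.0, 45.0, 48.0, 0.5)]
        )
        assert compute_w_start(slider, design) == pytest.approx(4.0, abs=0.06)

    def test_mean_of_two_deltas(self):
        # anticipations 2 s and 4 s -> w_start = 3 s
        design = toy_design([20.0, 45.0])
        slider = slider_from(
            70.0, [(18.0, 20.0, 22.0, 0.5), (41.0, 45.0, 48.0, 0.5)]
        )
        assert compute_w_start(slider, design) == pytest.approx(3.0, abs=0.06)

    def test_silent_trials_excluded_from_mean(self):
        design = toy_design([20.0, 45.0, 70.0])
        slider = slider_from(
            95.0, [(18.0, 20.0, 22.0, 0.5), (68.0, 70.0, 72.0, 0.5)]
        )
        assert compute_w_start(slider, design) == pytest.approx(2.0, abs=0.06)

    def test_all_silent_raises(self):
        design = toy_design([20.0])
        with pytest.raises(ValueError):
            compute_w_start(slider_from(40.0, []), design)


class TestScrWindows:
    def test_window_boundaries_left_closed_right_open(self):
        design = toy_design([20.0])
        w = WindowParams(w_start=4.0, w_end=3.0)
        inside = [ScrEvent(20.0 + 2.9, 0.3)]   # within the 3 s after passing
        outside = [ScrEvent(20.0 + 3.1, 0.3)]  # too late
        at_left = [ScrEvent(16.0, 0.3)]        # exactly at t_level - w_start
        at_right = [ScrEvent(23.0, 0.3)]       # exactly at t_level + w_end
        assert assign_scr_indicators(inside, design, w).nscr[0] == 1
        assert assign_scr_indicators(outside, design, w).nscr[0] == 0
        assert assign_scr_indicators(at_left, design, w).nscr[0] == 1
        assert assign_scr_indicators(at_right, design, w).nscr[0] == 0

    def test_empty_window_gives_zero_pair(self):
        design = toy_design([20.0])
        out = assign_scr_indicators([], design, WindowParams(4.0))
        assert out.nscr[0] == 0 and out.mscr[0] == 0.0

    def test_mscr_is_max_amplitude_in_window(self):
        design = toy_design([20.0])
        ev = [ScrEvent(19.0, 0.2), ScrEvent(21.0, 0.7), ScrEvent(22.0, 0.4)]
        out = assign_scr_indicators(ev, design, WindowParams(4.0))
        assert out.nscr[0] == 3 and out.mscr[0] == pytest.approx(0.7)

    def test_overlapping_windows_rejected(self):
        design = toy_design([20.0, 26.0])
        with pytest.raises(ValueError):
            assign_scr_indicators([], design, WindowParams(w_start=10.0))

    def test_unsorted_events_rejected(self):
        design = toy_design([20.0])
        with pytest.raises(ValueError):
            assign_scr_indicators(
                [ScrEvent(21.0, 0.3), ScrEvent(19.0, 0.3)], design, WindowParams(4.0)
            )


class TestEndToEnd:
    def test_zero_noise_extraction_matches_ground_truth(self, clean_trace_session):
        """Indicators extracted from noise-free simulated traces equal the
        generative per-trial values: mSA and nSCR exactly, iSA to quadrature
        tolerance, mSCR to the amplitude-recovery tolerance of the
        deconvolution chain."""
        s = clean_trace_session
        table = extract_indicators(s["sim"].slider, s["events"], s["design"])
        m = table.merge(s["sim"].truth, on=["participant_id", "trial_id"],
                        suffixes=("", "_gt"))
        assert np.array_equal(m.msa, m.msa_gt)
        assert np.max(np.abs(m.isa - m.isa_gt)) < 1e-3
        assert np.array_equal(m.nscr, m.nscr_gt)
        pos = m[m.mscr_gt > 0]
        assert np.max(np.abs(pos.mscr - pos.mscr_gt) / pos.mscr_gt) < 0.02

    def test_translation_invariance_of_windows(self):
        design = toy_design([20.0, 45.0])
        slider = slider_from(70.0, [(17.0, 20.0, 22.0, 0.8), (42.0, 45.0, 47.0, 0.4)])
        shift = 100.0
        shifted_design = toy_design([20.0 + shift, 45.0 + shift])
        shifted = SliderTrace(t=slider.t + shift, y=slider.y, rate=slider.rate)
        a = compute_sa_indicators(slider, design)
        b = compute_sa_indicators(shifted, shifted_design)
        assert np.allclose(a.msa, b.msa) and np.allclose(a.isa, b.isa)
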