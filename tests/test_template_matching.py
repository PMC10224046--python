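from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scgbeat.ecg_reference import detect_r_peaks
from scgbeat.errors import (
    BoundsError,
    DegenerateTemplateError,
    InsufficientDataError,
    LengthError,
)
from scgbeat.io_records import BeatAnnotations, SignalRecord
from scgbeat.synthetic import SynthConfig, generate_record, systolic_peak_latency_s
from scgbeat.preprocess import preprocess_record
from scgbeat.template_matching import (
    NccSeries,
    Template,
    beats_from_peaks,
    compute_ncc,
    compute_ncc_record,
    find_ncc_peaks,
    select_template,
    suggest_template,
)

from .oracles import local_maxima, ncc_literal, prominence_literal


def _template(samples, **kw):
    kw.setdefault("case_label", 1)
    kw.setdefault("start_index", 0)
    kw.setdefault("systolic_peak_offset", int(np.argmax(samples)))
    return Template(samples=np.asarray(samples, dtype=float), **kw)


class TestTemplateType:
    def test_constant_template_rejected(self):
        with pytest.raises(DegenerateTemplateError):
            _template([1.0, 1.0, 1.0])

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateTemplateError):
            _template([1.0])

    def test_offset_bounds(self):
        with pytest.raises(Exception):
            _template([0.0, 1.0], systolic_peak_offset=5)


class TestSelectTemplate:
    def test_synthetic_case1_peak_offset(self, clean_synth, clean_preprocessed):
        rec = clean_preprocessed
        r0 = clean_synth.truth_r.times_s[5]
        tpl = select_template(rec, (r0, r0 + 0.55), case_label=1)
        peak_time = (tpl.start_index + tpl.systolic_peak_offset) / rec.fs
        truth = clean_synth.truth_sys_peak.times_s[5]
        assert abs(peak_time - truth) <= 0.005
        # case-1 bounds span into the diastolic complex (default onset 380 ms)
        assert len(tpl) / rec.fs > 0.40

    def test_case2_shorter_same_offset_semantics(self, clean_synth, clean_preprocessed):
        rec = clean_preprocessed
        r0 = clean_synth.truth_r.times_s[5]
        tpl1 = select_template(rec, (r0, r0 + 0.55), case_label=1)
        tpl2 = select_template(rec, (r0, r0 + 0.20), case_label=2)
        assert len(tpl2) < len(tpl1)
        peak_time = (tpl2.start_index + tpl2.systolic_peak_offset) / rec.fs
        assert abs(peak_time - clean_synth.truth_sys_peak.times_s[5]) <= 0.005

    def test_zero_region_degenerate(self):
        rec = SignalRecord("x", fs=100.0, scg=np.zeros(1000), ecg=np.zeros(1000))
        with pytest.raises(DegenerateTemplateError):
            select_template(rec, (1.0, 2.0), 1)

    def test_out_of_bounds(self):
        rec = SignalRecord("x", fs=100.0, scg=np.random.default_rng(0).normal(size=100),
                           ecg=np.zeros(100))
        with pytest.raises(BoundsError):
            select_template(rec, (0.5, 5.0), 1)


class TestComputeNcc:
    def test_self_similarity_is_one(self):
        t = _template([0.0, 1.0, 0.5, -0.2])
        out = compute_ncc(t.samples, t)
        assert out.values[0] == pytest.approx(1.0, abs=1e-12)

    def test_negated_template_is_minus_one(self):
        t = _template([0.0, 1.0, 0.5, -0.2])
        out = compute_ncc(-t.samples, t)
        assert out.values[0] == pytest.approx(-1.0, abs=1e-12)

    def test_worked_example_matches_literal_formula(self):
        s = [1.0, 3.0, 2.0, 5.0, 4.0, 1.0]
        t = _template([3.0, 2.0, 5.0])
        out = compute_ncc(np.asarray(s), t)
        assert len(out.values) == 4
        # frozen from the literal per-lag evaluation
        np.testing.assert_allclose(
            out.values, [-0.32732684, 1.0, -0.14285714, -0.83862787], atol=1e-6
        )
        np.testing.assert_allclose(out.values, ncc_literal(s, t.samples), atol=1e-12)

    def test_template_longer_than_signal(self):
        t = _template(np.arange(10.0))
        with pytest.raises(LengthError):
            compute_ncc(np.zeros(5), t)

    def test_degenerate_window_is_zero_not_nan(self):
        s = np.concatenate([np.full(10, 3.0), [0.0, 1.0, 0.0]])
        t = _template([0.0, 1.0, 0.0])
        out = compute_ncc(s, t)
        assert np.all(np.isfinite(out.values))
        assert out.values[0] == 0.0

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 201)
        L = rng.integers(2, min(31, n + 1))
        s = rng.normal(size=n)
        t = rng.normal(size=L)
        out = compute_ncc(s, _template(t))
        np.testing.assert_allclose(out.values, ncc_literal(s, t), atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1),
           st.floats(0.1, 100.0), st.floats(-50.0, 50.0))
    def test_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        s = rng.normal(size=100)
        t = _template(rng.normal(size=20))
        base = compute_ncc(s, t).values
        scaled = compute_ncc(a * s + b, t).values
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_symmetry_window_vs_template(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=50)
        t = rng.normal(size=12)
        k = 17
        v1 = compute_ncc(s, _template(t)).values[k]
        v2 = compute_ncc(t, _template(s[k : k + 12])).values[0]
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_large_signal_fft_path_matches_oracle(self):
        rng = np.random.default_rng(11)
        s = rng.normal(size=9000)
        t = rng.normal(size=600)  # forces the FFT route (N*L > 4e6)
        out = compute_ncc(s, _template(t))
        lags = [0, 1234, 5000, len(out.values) - 1]
        expect = ncc_literal(s, t)
        np.testing.assert_allclose(out.values[lags], expect[lags], atol=1e-9)


class TestFindNccPeaks:
    def _series(self, values, fs=1000.0):
        return NccSeries(values=np.asarray(values, dtype=float), fs=fs)

    def test_both_peaks_kept_when_distance_allows(self):
        s = self._series([0.0, 0.9, 0.0, 0.8, 0.0])
        out = find_ncc_peaks(s, 0.5, 0.0005)
        np.testing.assert_array_equal(out.peak_lags, [1, 3])

    def test_higher_peak_wins_under_min_distance(self):
        s = self._series([0.0, 0.9, 0.0, 0.8, 0.0])
        out = find_ncc_peaks(s, 0.5, 0.004)
        np.testing.assert_array_equal(out.peak_lags, [1])

    def test_monotone_series_has_no_peaks(self):
        s = self._series(np.linspace(-1, 1, 50))
        out = find_ncc_peaks(s, 0.1, 0.001)
        assert len(out.peak_lags) == 0

    def test_tie_earlier_lag_wins(self):
        s = self._series([0.0, 0.9, 0.0, 0.9, 0.0])
        out = find_ncc_peaks(s, 0.5, 0.004)
        np.testing.assert_array_equal(out.peak_lags, [1])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_prominence_against_literal_walk(self, seed):
        rng = np.random.default_rng(seed)
        v = np.tanh(rng.normal(0, 0.5, size=80))  # in (-1, 1), no plateaus
        out = find_ncc_peaks(self._series(v), min_prominence=0.5, min_distance_s=0.0)
        maxima = local_maxima(v)
        for lag in out.peak_lags:
            assert lag in maxima
            assert prominence_literal(v, lag) >= 0.5 - 1e-12
        # completeness when the distance constraint is inactive
        expect = [i for i in maxima if prominence_literal(v, i) >= 0.5]
        np.testing.assert_array_equal(out.peak_lags, expect)

    def test_min_distance_invariant(self):
        rng = np.random.default_rng(42)
        v = np.clip(rng.normal(0, 0.5, size=500), -1, 1)
        out = find_ncc_peaks(self._series(v, fs=100.0), 0.3, 0.1)
        if len(out.peak_lags) > 1:
            assert np.min(np.diff(out.peak_lags)) >= 0.1 * 100.0 - 1e-9


class TestBeatsFromPeaks:
    def test_arithmetic(self):
        s = NccSeries(values=np.zeros(200), fs=1000.0, lag_zero_time_s=0.0,
                      peak_lags=np.array([100]))
        t = _template(np.arange(60.0), systolic_peak_offset=50)
        beats = beats_from_peaks(s, t)
        assert beats.times_s[0] == pytest.approx(0.150)
        assert beats.label == "NCC"

    def test_empty(self):
        s = NccSeries(values=np.zeros(10), fs=1000.0, peak_lags=np.array([], dtype=int))
        beats = beats_from_peaks(s, _template([0.0, 1.0]))
        assert len(beats) == 0

    def test_offset_cancels_in_ibis(self):
        lags = np.array([100, 1100, 2150])
        s = NccSeries(values=np.zeros(3000), fs=1000.0, peak_lags=lags)
        for off in (0, 37):
            t = _template(np.arange(60.0), systolic_peak_offset=off)
            ibis = np.diff(beats_from_peaks(s, t).times_s)
            np.testing.assert_allclose(ibis, np.diff(lags) / 1000.0)


class TestSuggestTemplate:
    def test_full_pipeline_sensitivity_100(self, noisy_synth, noisy_preprocessed):
        from scgbeat.evaluation import classify_detections, ppv, sensitivity

        rec = noisy_preprocessed
        rres = detect_r_peaks(rec.ecg, rec.fs)
        tpl = suggest_template(rec, rres.peaks, 1)
        assert not tpl.low_confidence
        series = find_ncc_peaks(compute_ncc_record(rec, tpl))
        beats = beats_from_peaks(series, tpl)
        report = classify_detections(noisy_synth.truth_r, beats)
        assert sensitivity(report) == 100.0
        assert ppv(report) == 100.0

    def test_pure_noise_low_confidence(self):
        rng = np.random.default_rng(9)
        n = 30_000
        rec = SignalRecord("noise", fs=1000.0, scg=rng.normal(size=n),
                           ecg=rng.normal(size=n))
        fake_r = BeatAnnotations(np.arange(0.5, 29.0, 1.0))
        tpl = suggest_template(rec, fake_r, 1)
        assert tpl.low_confidence

    def test_deterministic(self, noisy_synth, noisy_preprocessed):
        rec = noisy_preprocessed
        rres = detect_r_peaks(rec.ecg, rec.fs)
        a = suggest_template(rec, rres.peaks, 1)
        b = suggest_template(rec, rres.peaks, 1)
        assert a.start_index == b.start_index
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_too_few_beats(self):
        rec = SignalRecord("x", fs=100.0,
                           scg=np.random.default_rng(0).normal(size=1000),
                           ecg=np.zeros(1000))
        with pytest.raises(InsufficientDataError):
            suggest_template(rec, BeatAnnotations([1.0, 2.0, 3.0]), 1)
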