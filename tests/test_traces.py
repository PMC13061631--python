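"""Peak-metric extraction, aggregation factor and aggregation calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepagg.traces import (
    AggregationProfile,
    DeprotectionPeakMetrics,
    MalformedPeakError,
    SynthesisTrace,
    UnusableTraceError,
    aggregation_factor,
    classify,
    interpolate_special_residues,
    peak_metrics,
)
from tests.conftest import gaussian_peak

FWHM_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class TestPeakMetrics:
    def test_gaussian_fwhm_matches_closed_form(self):
        t, y = gaussian_peak(sigma=1.0)
        m = peak_metrics(t, y)
        assert m.fwhm == pytest.approx(FWHM_SIGMA, abs=1e-3)
        assert m.height == pytest.approx(1.0, abs=1e-6)

    def test_triangle_fwhm_by_similar_triangles(self):
        # isosceles triangle height 2, base 4 s, flat zero shoulders
        t = np.linspace(-4, 4, 801)
        y = np.clip(2.0 - np.abs(t), 0.0, None)
        m = peak_metrics(t, y)
        assert m.fwhm == pytest.approx(2.0, abs=1e-9)
        assert m.height == pytest.approx(2.0)

    def test_baseline_is_subtracted(self):
        t, y = gaussian_peak(sigma=1.5, height=0.8, baseline=0.3)
        m = peak_metrics(t, y)
        assert m.height == pytest.approx(0.8, abs=1e-4)
        assert m.fwhm == pytest.approx(1.5 * FWHM_SIGMA, rel=1e-3)

    def test_flat_signal_is_malformed(self):
        t = np.linspace(0, 10, 100)
        with pytest.raises(MalformedPeakError):
            peak_metrics(t, np.zeros_like(t))

    @pytest.mark.parametrize(
        "t, y, err",
        [
            (np.array([0, 2, 1, 3]), np.array([0, 1, 0, 0]), ValueError),  # non-monotone
            (np.linspace(0, 1, 10), np.ones(10), ValueError),  # too few samples
        ],
    )
    def test_invalid_inputs(self, t, y, err):
        with pytest.raises(err):
            peak_metrics(t, y)


class TestAggregationFactor:
    def test_identity_peak_scores_zero(self):
        ref = DeprotectionPeakMetrics(height=1.0, fwhm=4.0)
        assert aggregation_factor(ref, ref) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "height_ratio, fwhm_ratio, expected",
        [(1.0, 1.3, 30.0), (0.9, 1.05, 15.0), (0.5, 1.0, 50.0)],
    )
    def test_percent_scale_arithmetic(self, height_ratio, fwhm_ratio, expected):
        ref = DeprotectionPeakMetrics(height=2.0, fwhm=5.0)
        peak = DeprotectionPeakMetrics(height=2.0 * height_ratio, fwhm=5.0 * fwhm_ratio)
        assert aggregation_factor(peak, ref) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None)
    @given(
        h=st.floats(0.2, 3.0),
        w=st.floats(0.5, 20.0),
        gain=st.floats(0.1, 10.0),
        stretch=st.floats(0.1, 10.0),
    )
    def test_invariant_to_gain_and_time_rescaling(self, h, w, gain, stretch):
        """AF is unitless: joint detector-gain and time-axis rescaling of
        both peaks leaves it unchanged."""
        ref = DeprotectionPeakMetrics(height=1.0, fwhm=4.0)
        peak = DeprotectionPeakMetrics(height=h, fwhm=w)
        scaled_ref = DeprotectionPeakMetrics(height=gain * 1.0, fwhm=stretch * 4.0)
        scaled = DeprotectionPeakMetrics(height=gain * h, fwhm=stretch * w)
        assert aggregation_factor(scaled, scaled_ref) == pytest.approx(
            aggregation_factor(peak, ref), rel=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(w1=st.floats(1.0, 10.0), w2=st.floats(1.0, 10.0), h1=st.floats(0.2, 2.0), h2=st.floats(0.2, 2.0))
    def test_monotone_in_width_and_height(self, w1, w2, h1, h2):
        ref = DeprotectionPeakMetrics(height=1.0, fwhm=4.0)
        wider = aggregation_factor(DeprotectionPeakMetrics(h1, max(w1, w2)), ref)
        narrower = aggregation_factor(DeprotectionPeakMetrics(h1, min(w1, w2)), ref)
        assert wider >= narrower
        shorter = aggregation_factor(DeprotectionPeakMetrics(min(h1, h2), w1), ref)
        taller = aggregation_factor(DeprotectionPeakMetrics(max(h1, h2), w1), ref)
        assert shorter >= taller


class TestInterpolation:
    def _metrics(self, pairs):
        return [DeprotectionPeakMetrics(h, w, step=i + 1) for i, (h, w) in enumerate(pairs)]

    def test_midpoint_between_neighbours(self):
        metrics = self._metrics([(1.0, 4.0), (1.0, 4.0), (5.0, 9.0), (1.2, 4.4)])
        out, replaced = interpolate_special_residues(metrics, ["A", "G", "H", "V"])
        assert replaced == {3}
        assert out[2].height == pytest.approx(1.1)
        assert out[2].fwhm == pytest.approx(4.2)

    def test_no_special_residues_is_identity(self):
        metrics = self._metrics([(1.0, 4.0), (1.1, 4.1)])
        out, replaced = interpolate_special_residues(metrics, ["A", "G"])
        assert replaced == set()
        assert out == metrics

    def test_trailing_special_copies_previous(self):
        metrics = self._metrics([(1.0, 4.0), (1.2, 4.4), (9.9, 9.9)])
        out, replaced = interpolate_special_residues(metrics, ["A", "G", "C"])
        assert replaced == {3}
        assert (out[2].height, out[2].fwhm) == (pytest.approx(1.2), pytest.approx(4.4))

    def test_consecutive_specials_interpolate_linearly(self):
        metrics = self._metrics([(1.0, 3.0), (9.0, 9.0), (9.0, 9.0), (4.0, 6.0)])
        out, replaced = interpolate_special_residues(metrics, ["A", "H", "C", "G"])
        assert replaced == {2, 3}
        assert out[1].height == pytest.approx(2.0)
        assert out[2].height == pytest.approx(3.0)

    def test_all_special_is_unusable(self):
        metrics = self._metrics([(1.0, 4.0), (1.0, 4.0)])
        with pytest.raises(UnusableTraceError):
            interpolate_special_residues(metrics, ["H", "C"])


def _trace_from_metrics(pairs, residues):
    """Build a synthetic trace whose peaks realise given (height, fwhm)."""
    peaks = []
    for h, w in pairs:
        t, y = gaussian_peak(sigma=w / FWHM_SIGMA, height=h, half_span=60.0, n=1201)
        peaks.append((t + 60.0, y))
    return SynthesisTrace(id="t", residues=list(residues), peaks=peaks)


class TestClassify:
    def test_first_strict_exceedance_sets_onset(self):
        # widths chosen to give AF = [0, 5, 12, 25, 18]
        widths = [4.0 * (1 + af / 100) for af in (0, 5, 12, 25, 18)]
        trace = _trace_from_metrics([(1.0, w) for w in widths], "GAVLF")
        prof = classify(trace)
        assert prof.sequence_label is True
        assert prof.onset_step == 4
        assert prof.step_labels.tolist() == [False, False, False, True, True]
        np.testing.assert_allclose(prof.af_values, [0, 5, 12, 25, 18], atol=0.2)

    def test_threshold_is_strict(self):
        widths = [4.0, 4.0 * 1.199, 4.0 * 1.200]
        trace = _trace_from_metrics([(1.0, w) for w in widths], "GAV")
        prof = classify(trace)
        assert prof.sequence_label is False
        assert prof.onset_step is None
        assert not prof.step_labels.any()

    def test_first_step_af_is_exactly_zero(self):
        trace = _trace_from_metrics([(1.0, 4.0), (1.0, 4.0)], "GA")
        prof = classify(trace)
        assert prof.af_values[0] == 0.0

    def test_his_step_is_interpolated_before_af(self):
        # His at step 2 with an absurd peak; neighbours are baseline
        trace = _trace_from_metrics([(1.0, 4.0), (0.2, 12.0), (1.0, 4.0)], "GHA")
        prof = classify(trace)
        assert prof.interpolated_steps == {2}
        assert prof.sequence_label is False

    def test_classify_is_deterministic_and_idempotent(self, small_benchmark):
        _, traces_list = small_benchmark
        tr = traces_list[0]
        p1, p2 = classify(tr), classify(tr)
        np.testing.assert_array_equal(p1.af_values, p2.af_values)
        assert p1.onset_step == p2.onset_step

    def test_single_step_trace_rejected(self):
        trace = _trace_from_metrics([(1.0, 4.0)], "G")
        with pytest.raises(ValueError):
            classify(trace)

    def test_malformed_step_reports_index(self):
        t = np.linspace(0, 10, 100)
        trace = SynthesisTrace(id="t", residues=["G", "A"],
                               peaks=[gaussian_peak(1.0, half_span=8.0, n=100), (t, np.zeros_like(t))])
        with pytest.raises(MalformedPeakError, match="step 2"):
            classify(trace)


class TestRoundTrip:
    def test_planted_onsets_recovered_exactly(self, small_benchmark):
        """Noise-free synthetic traces: the analyzer recovers every
        planted onset and raises no false aggregation calls."""
        records, traces_list = small_benchmark
        for rec, tr in zip(records, traces_list):
            prof = classify(tr)
            assert prof.onset_step == rec.onset_step
            assert prof.sequence_label == rec.sequence_label

    def test_explicit_broadening_construction(self):
        """broadening 0.3, no height decay: the onset step itself shows
        FWHM 1.3x baseline and AF 30."""
        from pepagg.curation import PeptideRecord
        from pepagg.synthdata import TraceModelConfig, synth_trace

        rec = PeptideRecord(id="x", sequence="GAVLFKAG")
        tc = TraceModelConfig(broadening_per_step=0.3, height_decay_per_step=0.0, noise_sd=0.0)
        trace = synth_trace(rec, onset_step=5, trace_config=tc)
        prof = classify(trace)
        assert prof.onset_step == 5
        assert prof.af_values[4] == pytest.approx(30.0, abs=0.5)
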