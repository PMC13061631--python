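"""Synthetic generator: sampling, planted labels, traces, calibration."""

import numpy as np
import pytest
from scipy.special import expit

from pepagg.alphabet import AA_ORDER, vector_from_mapping
from pepagg.synthdata import (
    SyntheticConfig,
    TraceModelConfig,
    bayes_accuracy,
    make_benchmark,
    planted_labels,
    sample_peptides,
    synth_trace,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"length_range": (3, 10)},
            {"length_range": (10, 8)},
            {"label_noise": 0.5},
            {"label_noise": -0.1},
            {"composition_prior": np.zeros(20)},
            {"beta": np.zeros(19)},
            {"n_peptides": 0},
        ],
    )
    def test_invalid_fields_rejected(self, kw):
        with pytest.raises(ValueError):
            SyntheticConfig(**kw)

    @pytest.mark.parametrize(
        "kw",
        [
            {"baseline_fwhm": 0.0},
            {"peak_points": 10},
            {"broadening_per_step": -0.1},
            {"height_decay_per_step": 1.0},
            {"noise_sd": -1.0},
        ],
    )
    def test_invalid_trace_fields_rejected(self, kw):
        with pytest.raises(ValueError):
            TraceModelConfig(**kw)


class TestSamplePeptides:
    def test_deterministic_in_seed(self):
        cfg = SyntheticConfig(n_peptides=50, seed=5)
        a = [r.sequence for r in sample_peptides(cfg)]
        b = [r.sequence for r in sample_peptides(SyntheticConfig(n_peptides=50, seed=5))]
        assert a == b
        c = [r.sequence for r in sample_peptides(SyntheticConfig(n_peptides=50, seed=6))]
        assert a != c

    def test_degenerate_prior_gives_homopolymer(self):
        prior = np.full(20, 1e-9)
        prior[AA_ORDER.index("V")] = 1e6
        cfg = SyntheticConfig(n_peptides=5, length_range=(10, 10), composition_prior=prior, seed=0)
        for rec in sample_peptides(cfg):
            assert rec.sequence == "V" * 10

    def test_lengths_within_range(self):
        cfg = SyntheticConfig(n_peptides=1000, length_range=(8, 20), seed=1)
        lengths = {len(r.sequence) for r in sample_peptides(cfg)}
        assert lengths <= set(range(8, 21))
        assert {8, 20} <= lengths  # extremes reached at n=1000


class TestPlantedLabels:
    def test_zero_beta_gives_coin_flip_rate(self):
        cfg = SyntheticConfig(n_peptides=10000, beta=np.zeros(20), bias=0.0,
                              label_noise=0.0, seed=2)
        recs = planted_labels(sample_peptides(cfg), cfg)
        rate = np.mean([r.sequence_label for r in recs])
        assert abs(rate - 0.5) <= 3 * np.sqrt(0.25 / 10000)

    def test_saturated_bias_labels_everything(self):
        cfg = SyntheticConfig(n_peptides=200, beta=np.zeros(20), bias=10.0,
                              label_noise=0.0, seed=3)
        recs = planted_labels(sample_peptides(cfg), cfg)
        assert all(r.sequence_label for r in recs)

    def test_homopolymer_probabilities_match_logistic(self):
        beta = vector_from_mapping({"V": 4.0, "F": -4.0})
        n = 4000
        for aa, logit in (("V", 4.0), ("F", -4.0)):
            cfg = SyntheticConfig(n_peptides=n, beta=beta, label_noise=0.0, seed=4)
            recs = [r.__class__(id=f"{aa}{i}", sequence=aa * 10) for i, r in
                    enumerate(sample_peptides(cfg))]
            labelled = planted_labels(recs, cfg)
            rate = np.mean([r.sequence_label for r in labelled])
            p = expit(logit)
            assert abs(rate - p) <= 3 * np.sqrt(p * (1 - p) / n) + 1e-9

    def test_label_rate_matches_generator_mean(self):
        """Monte-Carlo calibration: empirical aggregating fraction tracks
        E[logistic(beta.c + bias)] over the composition law."""
        cfg = SyntheticConfig(n_peptides=8000, label_noise=0.0, seed=5)
        recs = planted_labels(sample_peptides(cfg), cfg)
        rate = np.mean([r.sequence_label for r in recs])
        ps = np.array([expit(float(cfg.beta @ r.composition())) for r in recs])
        se = np.sqrt(np.mean(ps * (1 - ps)) / len(recs))
        assert abs(rate - ps.mean()) <= 3 * se


class TestSynthTrace:
    def test_no_onset_means_identical_peaks(self, make_record):
        rec = make_record("GAVLFKAG")
        tc = TraceModelConfig(noise_sd=0.0)
        trace = synth_trace(rec, None, tc)
        t0, y0 = trace.peaks[0]
        for t, y in trace.peaks[1:]:
            np.testing.assert_array_equal(y, y0)

    def test_post_onset_broadening_schedule(self, make_record):
        from pepagg.traces import peak_metrics

        rec = make_record("GAVLFKAGLV")
        tc = TraceModelConfig(broadening_per_step=0.3, height_decay_per_step=0.0, noise_sd=0.0)
        trace = synth_trace(rec, 4, tc)
        base = peak_metrics(*trace.peaks[0])
        at_onset = peak_metrics(*trace.peaks[3])
        after = peak_metrics(*trace.peaks[4])
        assert at_onset.fwhm / base.fwhm == pytest.approx(1.3, rel=5e-3)
        assert after.fwhm / base.fwhm == pytest.approx(1.69, rel=5e-3)

    def test_broadening_saturates_at_cap(self, make_record):
        from pepagg.traces import peak_metrics

        rec = make_record("G" * 20)
        tc = TraceModelConfig(broadening_per_step=0.5, max_broadening=2.0,
                              height_decay_per_step=0.0, noise_sd=0.0)
        trace = synth_trace(rec, 2, tc)
        last = peak_metrics(*trace.peaks[-1])
        base = peak_metrics(*trace.peaks[0])
        assert last.fwhm / base.fwhm == pytest.approx(2.0, rel=5e-3)

    def test_onset_outside_sequence_rejected(self, make_record):
        rec = make_record("GAVLF")
        with pytest.raises(ValueError):
            synth_trace(rec, 6, TraceModelConfig())


class TestMakeBenchmark:
    def test_reproducible_bundle(self):
        cfg = SyntheticConfig(n_peptides=30, seed=9)
        tc = TraceModelConfig(seed=9)
        r1, t1 = make_benchmark(cfg, tc)
        r2, t2 = make_benchmark(cfg, tc)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        assert [r.onset_step for r in r1] == [r.onset_step for r in r2]
        np.testing.assert_array_equal(t1[0].peaks[0][1], t2[0].peaks[0][1])

    def test_onsets_in_window_and_labels_consistent(self):
        cfg = SyntheticConfig(n_peptides=400, seed=10)
        recs, _ = make_benchmark(cfg, TraceModelConfig(seed=10))
        for rec in recs:
            if rec.sequence_label:
                assert rec.onset_step is not None
                # sampled from steps 5-15, clipped/shifted within the sequence
                assert 2 <= rec.onset_step <= min(16, len(rec.sequence))
            else:
                assert rec.onset_step is None


class TestBayesAccuracy:
    def test_zero_beta_gives_half(self):
        cfg = SyntheticConfig(beta=np.zeros(20), bias=0.0, label_noise=0.0)
        assert bayes_accuracy(cfg, n_mc=2000, seed=0) == pytest.approx(0.5)

    def test_saturated_model_accuracy_is_one_minus_noise(self):
        cfg = SyntheticConfig(beta=np.zeros(20), bias=20.0, label_noise=0.1)
        assert bayes_accuracy(cfg, n_mc=2000, seed=0) == pytest.approx(0.9, abs=1e-6)
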