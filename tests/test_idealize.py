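"""Idealization chain: histogram, mixture fit, levels, segments, events."""

import numpy as np
import pytest

from mitopore import ValidationError
from mitopore.config import AnalysisConfig
from mitopore.idealize import (
    build_histogram,
    detect_transitions,
    extract_levels,
    fit_mixture,
    idealize,
)
from mitopore.simulate import RecordingProtocol

from conftest import square_trace

PROTO_20MV = RecordingProtocol(duration=1.0)


class TestHistogram:
    def test_constant_trace_occupies_single_bin(self):
        tr = square_trace([(1.0, 250.0)])  # 5 pA at +20 mV
        h = build_histogram(tr)
        occupied = np.flatnonzero(h.counts)
        assert occupied.size == 1
        lo, hi = h.bin_edges[occupied[0]], h.bin_edges[occupied[0] + 1]
        assert lo <= 5.0 <= hi

    def test_two_value_mixture_two_equal_bins(self):
        tr = square_trace([(0.5, 0.0), (0.5, 800.0)])  # 0 and 16 pA
        h = build_histogram(tr)
        occupied = np.flatnonzero(h.counts)
        assert occupied.size == 2
        assert h.counts[occupied[0]] == h.counts[occupied[1]]

    def test_counts_conserved_for_noisy_input(self):
        tr = square_trace([(0.5, 0.0), (0.5, 800.0)], noise_sd=0.7, seed=1)
        h = build_histogram(tr, window=(0.1, 0.9))
        assert h.counts.sum() == h.n_samples == 8000

    def test_empty_window_rejected(self):
        tr = square_trace([(1.0, 0.0)])
        with pytest.raises(ValidationError):
            build_histogram(tr, window=(0.5, 0.5))


class TestMixtureFit:
    def test_single_gaussian_recovered(self, rng):
        x = rng.normal(0.0, 0.5, 10_000)
        fit = fit_mixture(x)
        assert fit.k == 1
        w, mu, sd = fit.components[0]
        assert abs(mu) < 0.05
        assert abs(sd - 0.5) < 0.05

    def test_two_gaussians_recovered(self, rng):
        x = np.concatenate([rng.normal(0, 0.5, 8000), rng.normal(16, 0.5, 8000)])
        fit = fit_mixture(x)
        assert fit.k == 2
        assert abs(fit.components[0][1] - 0.0) < 0.1
        assert abs(fit.components[1][1] - 16.0) < 0.1

    def test_three_components_recovered(self, rng):
        """Closed, sub and full-open peaks at 0 / 8.7 / 16.5 pA."""
        x = np.concatenate([
            rng.normal(0.0, 0.5, 9000),
            rng.normal(8.7, 0.5, 5000),
            rng.normal(16.5, 0.5, 6000),
        ])
        fit = fit_mixture(x)
        assert fit.k == 3
        means = [c[1] for c in fit.components]
        assert means == pytest.approx([0.0, 8.7, 16.5], abs=0.1)

    def test_binned_fit_agrees_with_raw_sample_reference(self, rng):
        """The histogram EM matches scikit-learn's raw-sample EM."""
        x = np.concatenate([rng.normal(0, 0.5, 6000), rng.normal(16, 0.5, 4000)])
        binned = fit_mixture(x, method="binned")
        raw = fit_mixture(x, method="raw")
        assert binned.k == raw.k == 2
        for cb, cr in zip(binned.components, raw.components):
            assert cb[1] == pytest.approx(cr[1], abs=0.05)  # means
            assert cb[0] == pytest.approx(cr[0], abs=0.02)  # weights

    def test_mixture_estimates_tighten_with_sample_size(self, rng):
        errs = []
        for n in (1000, 100_000):
            x = np.concatenate([rng.normal(0, 0.5, n), rng.normal(16, 0.5, n)])
            fit = fit_mixture(x)
            errs.append(abs(fit.components[1][1] - 16.0)
                        + abs(fit.components[1][2] - 0.5))
        assert errs[1] < errs[0]

    def test_determinism(self, rng):
        x = np.concatenate([rng.normal(0, 0.5, 3000), rng.normal(16, 0.5, 3000)])
        assert fit_mixture(x) == fit_mixture(x)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            fit_mixture(np.zeros(100))


def _fit_from_components(comps):
    from mitopore.idealize import MixtureFit
    return MixtureFit(components=tuple(comps), k=len(comps),
                      log_likelihood=0.0, score=0.0, n_fit_samples=10_000)


class TestExtractLevels:
    def test_single_component_baseline_only(self):
        fit = _fit_from_components([(1.0, 0.2, 0.5)])
        lv = extract_levels(fit, PROTO_20MV)
        assert lv.n_levels == 1
        assert lv.conductances.tolist() == [0.0]

    def test_16_pA_at_20_mV_gives_800_pS(self):
        fit = _fit_from_components([(0.5, 0.0, 0.5), (0.5, 16.0, 0.5)])
        lv = extract_levels(fit, PROTO_20MV)
        assert lv.conductances[1] == pytest.approx(800.0)

    def test_sub_threshold_component_merged_into_baseline(self):
        """0.8 pA peak over sigma = 0.5 baseline: within 3 sigma, merged."""
        fit = _fit_from_components([(0.6, 0.0, 0.5), (0.4, 0.8, 0.5)])
        lv = extract_levels(fit, PROTO_20MV)
        assert lv.n_levels == 1

    def test_split_open_peak_is_remerged(self):
        fit = _fit_from_components([
            (0.5, 0.0, 0.3), (0.25, 15.8, 0.3), (0.25, 16.2, 0.3)])
        lv = extract_levels(fit, PROTO_20MV)
        assert lv.n_levels == 2

    def test_low_weight_smear_component_dropped(self):
        fit = _fit_from_components([
            (0.59, 0.0, 0.3), (0.01, 8.0, 3.0), (0.40, 16.0, 0.3)])
        lv = extract_levels(fit, PROTO_20MV)
        assert lv.n_levels == 2


class TestIdealize:
    def test_noiseless_square_wave_recovered_exactly(self):
        segs = [(0.1, 0.0), (0.1, 800.0)] * 5
        tr = square_trace(segs, filtered=False)
        fit = fit_mixture(tr.current)
        lv = extract_levels(fit, tr.protocol)
        ideal = idealize(tr, lv, AnalysisConfig())
        truth = tr.truth.conductance_at(tr.times)
        got = lv.conductances[ideal.labels()]
        assert np.allclose(got, truth, atol=1e-6)

    def test_noisy_square_wave_sample_accuracy(self):
        segs = [(0.2, 0.0), (0.2, 800.0)] * 4
        tr = square_trace(segs, noise_sd=0.5, seed=3, filtered=True)
        fit = fit_mixture(tr.current)
        lv = extract_levels(fit, tr.protocol)
        ideal = idealize(tr, lv, AnalysisConfig())
        truth = tr.truth.conductance_at(tr.times)
        got = lv.conductances[ideal.labels()]
        match = np.isclose(got, truth, atol=50.0)
        assert match.mean() > 0.99
        # boundaries within 2 filter rise times of the truth jumps
        fs = tr.protocol.sampling_rate
        bnds = ideal.segments[1:, 0] / fs
        for tb in tr.truth.jump_times[1:]:
            assert np.min(np.abs(bnds - tb)) < 2 * 0.68e-3

    def test_single_level_one_segment(self):
        tr = square_trace([(1.0, 0.0)], noise_sd=0.3, seed=1)
        fit = fit_mixture(tr.current)
        lv = extract_levels(fit, tr.protocol)
        ideal = idealize(tr, lv, AnalysisConfig())
        assert ideal.segments.shape[0] == 1

    def test_partition_tiles_whole_trace(self):
        segs = [(0.15, 0.0), (0.1, 400.0), (0.2, 800.0), (0.15, 0.0),
                (0.2, 800.0), (0.2, 0.0)]
        tr = square_trace(segs, noise_sd=0.5, seed=7, filtered=True)
        fit = fit_mixture(tr.current)
        lv = extract_levels(fit, tr.protocol)
        ideal = idealize(tr, lv, AnalysisConfig())
        assert ideal.segments[0, 0] == 0
        assert ideal.segments[-1, 1] == tr.current.size
        assert np.all(ideal.segments[1:, 0] == ideal.segments[:-1, 1])
        assert ideal.dwell_times.sum() == pytest.approx(1.0)


class TestDetectTransitions:
    def test_constant_idealization_no_events(self):
        tr = square_trace([(1.0, 0.0)], noise_sd=0.2, seed=2)
        fit = fit_mixture(tr.current)
        lv = extract_levels(fit, tr.protocol)
        ideal = idealize(tr, lv, AnalysisConfig())
        assert detect_transitions(ideal, tr) == []

    def test_constructed_path_delta_g_sequence(self):
        """0 -> 800 -> 300 -> 800 pS steps give +800, -500, +500."""
        segs = [(0.3, 0.0), (0.3, 800.0), (0.3, 300.0), (0.3, 800.0)]
        tr = square_trace(segs, noise_sd=0.4, seed=5, filtered=True)
        fit = fit_mixture(tr.current)
        lv = extract_levels(fit, tr.protocol)
        ideal = idealize(tr, lv, AnalysisConfig())
        ev = detect_transitions(ideal, tr)
        deltas = [e.delta_g for e in ev]
        assert deltas == pytest.approx([800.0, -500.0, 500.0], abs=30.0)
        assert all(e.duration_ms < 5.0 for e in ev)

    def test_delta_g_antisymmetry_on_reversed_path(self):
        segs = [(0.3, 0.0), (0.4, 800.0), (0.3, 300.0)]
        fwd = square_trace(segs, filtered=True)
        rev = square_trace(segs[::-1], filtered=True)

        def deltas(tr):
            fit = fit_mixture(tr.current)
            lv = extract_levels(fit, tr.protocol)
            ideal = idealize(tr, lv, AnalysisConfig())
            return [e.delta_g for e in detect_transitions(ideal, tr)]

        assert deltas(fwd) == pytest.approx(
            [-d for d in reversed(deltas(rev))], abs=1.0)

    def test_linear_ramp_duration_is_10_to_90_span(self):
        """A 20 ms linear ramp between levels reads ~16 ms (10-90%)."""
        segs = [(0.5, 0.0), (0.5, 800.0)]
        tr = square_trace(segs, ramps=[0.020], filtered=False)
        fit = fit_mixture(tr.current)
        lv = extract_levels(fit, tr.protocol)
        ideal = idealize(tr, lv, AnalysisConfig())
        ev = detect_transitions(ideal, tr)
        assert len(ev) == 1
        assert ev[0].duration_ms == pytest.approx(16.0, abs=1.5)
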