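"""Channel and assay simulators: validation, determinism, CTMC statistics."""

import math

import numpy as np
import pytest

from mitopore import (
    ChannelModel,
    Intervention,
    ModelError,
    RecordingProtocol,
    ValidationError,
    gaussian_lowpass,
    make_preset,
    make_rate_matrix,
    simulate_channel_trace,
    simulate_crc,
    simulate_cell_timecourse,
    simulate_ocr,
    simulate_state_path,
    simulate_swelling,
    stationary_distribution,
)
from mitopore.presets import PRESET_NAMES, simulate_preset
from mitopore.simulate import CrcParams, OcrParams, SwellingParams, TimecourseParams


def two_state_model(g_open=800.0, k_open=5.0, k_close=5.0, **kw):
    return ChannelModel(
        states=(("closed", 0.0), ("open", g_open)),
        rates=make_rate_matrix([[0.0, k_open], [k_close, 0.0]]),
        **kw,
    )


class TestModelValidation:
    def test_rejects_single_state(self):
        with pytest.raises(ModelError):
            ChannelModel(states=(("closed", 0.0),), rates=np.zeros((1, 1)))

    def test_rejects_bad_row_sums(self):
        q = np.array([[-1.0, 2.0], [1.0, -1.0]])
        with pytest.raises(ModelError):
            ChannelModel(states=(("closed", 0.0), ("open", 800.0)), rates=q)

    def test_rejects_negative_off_diagonal(self):
        with pytest.raises(ModelError):
            make_rate_matrix([[0.0, -1.0], [1.0, 0.0]])

    def test_rejects_conducting_closed_state(self):
        with pytest.raises(ModelError):
            ChannelModel(states=(("closed", 5.0), ("open", 800.0)),
                         rates=np.zeros((2, 2)))

    def test_protocol_rejects_cutoff_above_nyquist(self):
        with pytest.raises(ValidationError):
            RecordingProtocol(duration=1.0, sampling_rate=1000.0,
                              filter_cutoff=600.0)

    def test_intervention_beyond_duration_rejected(self):
        model = two_state_model()
        iv = Intervention(time=20.0, label="CsA")
        with pytest.raises(ValidationError):
            simulate_channel_trace(model, RecordingProtocol(duration=10.0), (iv,))


class TestChannelTrace:
    def test_degenerate_model_is_baseline_noise_only(self):
        """All rates zero from the closed state: pure baseline + noise."""
        model = ChannelModel(
            states=(("closed", 0.0), ("open", 800.0)),
            rates=np.zeros((2, 2)), noise_sd=0.5, baseline_current=0.0,
        )
        tr = simulate_channel_trace(model, RecordingProtocol(duration=10.0), seed=4)
        assert np.all(tr.truth.states == 0)
        assert abs(tr.raw_current.std() - 0.5) < 0.01
        assert abs(tr.raw_current.mean()) < 0.02

    def test_two_state_occupancy_matches_stationary_distribution(self):
        """Open fraction of a 5/5 s^-1 two-state channel ~ 0.5 over 60 s."""
        model = two_state_model()
        jumps, states = simulate_state_path(model, 60.0, seed=11)
        bounds = np.append(jumps, 60.0)
        open_frac = np.sum(np.diff(bounds)[states == 1]) / 60.0
        pi = stationary_distribution(model.rates)
        assert pi == pytest.approx([0.5, 0.5])
        # Monte-Carlo s.e. of an alternating-renewal occupancy fraction
        se = math.sqrt(2 * 0.1 * 0.25 / 60.0)
        assert abs(open_frac - 0.5) < 3 * se

    def test_identical_seed_identical_trace(self):
        model, ivs = make_preset("wt_hela_ptp")
        p = RecordingProtocol(duration=5.0)
        ivs = ()
        a = simulate_channel_trace(model, p, ivs, seed=9)
        b = simulate_channel_trace(model, p, ivs, seed=9)
        c = simulate_channel_trace(model, p, ivs, seed=10)
        assert np.array_equal(a.current, b.current)
        assert not np.array_equal(a.current, c.current)

    def test_zero_multiplier_intervention_freezes_path(self):
        model = two_state_model()
        mult = {(0, 1): 0.0, (1, 0): 0.0}
        iv = Intervention.from_dict(3.0, "Ba2+", mult)
        jumps, states = simulate_state_path(model, 20.0, seed=3,
                                            interventions=(iv,))
        assert jumps[-1] <= 3.0 + 1e-12

    def test_open_level_current_matches_conductance(self):
        """Unfiltered open-level mean = baseline + g * V_h within 3 s.e."""
        model = two_state_model(g_open=827.0, noise_sd=0.5, baseline_current=0.5)
        p = RecordingProtocol(duration=30.0)
        tr = simulate_channel_trace(model, p, seed=5)
        open_mask = tr.truth.state_at(tr.times) == 1
        n = open_mask.sum()
        expected = 0.5 + 827.0 * 20.0 / 1000.0
        se = 0.5 / math.sqrt(n)
        assert abs(tr.raw_current[open_mask].mean() - expected) < 3 * se

    def test_filter_preserves_dc_exactly(self):
        x = np.full(10_000, 7.25)
        y = gaussian_lowpass(x, 10_000.0, 500.0)
        assert np.allclose(y, x, rtol=1e-9, atol=0)

    def test_filter_rise_time_near_nominal(self):
        """10-90% step response of the 500 Hz filter ~ 0.68 ms."""
        x = np.zeros(4000)
        x[2000:] = 1.0
        y = gaussian_lowpass(x, 10_000.0, 500.0)
        i10 = np.argmax(y > 0.1)
        i90 = np.argmax(y > 0.9)
        rise_ms = (i90 - i10) / 10_000.0 * 1000.0
        assert 0.5 < rise_ms < 0.9


class TestPresets:
    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_presets_are_valid_models(self, name):
        model, ivs = make_preset(name)
        assert model.n_states >= 2
        for iv in ivs:
            assert iv.time <= 90.0

    def test_unknown_preset_raises(self):
        from mitopore.errors import PresetError
        with pytest.raises(PresetError):
            make_preset("nonesuch")

    def test_null_closed_produces_no_events(self):
        model, ivs = make_preset("null_closed")
        assert ivs == ()
        jumps, states = simulate_state_path(model, 30.0, seed=0)
        assert len(states) == 1 and states[0] == 0

    def test_wt_preset_open_level_current_near_16_5_pA(self):
        """Full open level of the wild-type preset: 827 pS x 20 mV = 16.5 pA."""
        tr = simulate_preset("wt_hela_ptp", seed=2, duration=30.0,
                             jitter_cv=0.0)
        model, _ = make_preset("wt_hela_ptp")
        open_idx = int(np.argmax(model.conductances))
        mask = tr.truth.state_at(tr.times) == open_idx
        assert mask.sum() > 1000
        drift = model.drift_slope * tr.times[mask].mean()
        open_mean = tr.raw_current[mask].mean() - model.baseline_current - drift
        assert open_mean == pytest.approx(16.54, abs=0.15)

    def test_full_mmc_conductance_in_megachannel_range(self):
        model, _ = make_preset("full_mmc")
        assert 1300.0 <= model.conductances.max() <= 1500.0

    def test_jitter_changes_conductance_not_structure(self):
        a = simulate_preset("wt_hela_ptp", seed=1, duration=5.0)
        b = simulate_preset("wt_hela_ptp", seed=2, duration=5.0)
        assert a.truth.conductances_pS[2] != b.truth.conductances_pS[2]


class TestAssaySimulators:
    def test_swelling_without_ca_is_flat_until_alamethicin(self):
        p = SwellingParams(noise_sd=0.0)
        s = simulate_swelling(p, with_ca=False, seed=0)
        pre_ala = s.a540[s.times < p.ala_time]
        assert np.allclose(pre_ala, p.a0)
        assert np.allclose(s.a540[s.times >= p.ala_time], p.ala_floor)

    def test_swelling_instant_decay_closed_form(self):
        """rate -> inf: A drops to A0 - amplitude right after Ca2+."""
        p = SwellingParams(a0=1.0, swollen_amplitude=0.3, ala_floor=0.4,
                           rate_constant=1e6, noise_sd=0.0)
        s = simulate_swelling(p, with_ca=True, seed=0)
        mid = (s.times > p.ca_time + 1) & (s.times < p.ala_time)
        assert np.allclose(s.a540[mid], 0.7, atol=1e-6)

    def test_swelling_rejects_ala_before_ca(self):
        with pytest.raises(ValidationError):
            SwellingParams(ca_time=100.0, ala_time=50.0)

    def test_crc_zero_capacity_never_takes_up(self):
        s = simulate_crc(CrcParams(capacity=0.0, noise_sd=0.0), seed=0)
        # fluorescence never returns to baseline after the first pulse
        after = s.fluorescence[s.times > s.pulse_times[0] + 5.0]
        assert np.all(after > 0.5 * s.pulse_size)

    def test_crc_determinism(self):
        a = simulate_crc(CrcParams(capacity=10.0), seed=5)
        b = simulate_crc(CrcParams(capacity=10.0), seed=5)
        assert np.array_equal(a.fluorescence, b.fluorescence)

    def test_crc_default_protein_is_study_value(self):
        assert CrcParams(capacity=10.0).protein == 0.4
        assert CrcParams(capacity=10.0).pulse_size == 2.5

    def test_timecourse_full_protection_stays_flat(self):
        p = TimecourseParams(
            n_rois=10, noise_sd=0.0,
            protection_factors=(("none", 1.0), ("full", math.inf)),
        )
        s = simulate_cell_timecourse(p, drug="full", seed=1)
        assert np.all(np.isnan(s.onset_times))
        base = s.calcein[:, 0]
        assert np.allclose(s.calcein[:, -1], base)

    def test_timecourse_unknown_drug_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cell_timecourse(TimecourseParams(), drug="mystery", seed=0)

    def test_timecourse_sampling_interval_default_30s(self):
        s = simulate_cell_timecourse(TimecourseParams(n_rois=2), seed=0)
        assert np.allclose(np.diff(s.times), 30.0)

    def test_ocr_injection_order_and_levels(self):
        p = OcrParams(noise_sd=0.0)
        s = simulate_ocr(p, seed=0)
        assert [lab for lab, _ in s.injections] == [
            "oligomycin", "FCCP", "rotenone", "antimycin A"]
        assert s.ocr[s.times < p.oligo_time].mean() == pytest.approx(p.basal)
        assert s.ocr[-1] == pytest.approx(p.basal * p.nonmito_fraction)


class TestStationaryDistribution:
    def test_detailed_balance_three_state(self):
        q = make_rate_matrix([[0, 2.0, 4.0], [1.0, 0, 2.0], [1.0, 0.5, 0]])
        pi = stationary_distribution(q)
        assert np.allclose(pi @ q, 0.0, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0)

    def test_reducible_chain_rejected(self):
        with pytest.raises(ModelError):
            stationary_distribution(np.zeros((2, 2)))
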