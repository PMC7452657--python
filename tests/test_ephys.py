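import numpy as np
import pytest

from striatype import (
    AdExParams,
    FEATURE_NAMES,
    Recording,
    StepProtocol,
    Sweep,
    WaveformSpec,
    compose_waveform,
    detect_spikes,
    extract_features,
    preset,
    simulate_adex,
)
from striatype.ephys import (
    adaptation_features,
    ap_waveform_features,
    compute_capacitance,
    compute_input_resistance,
    compute_rheobase,
    compute_rmp,
    compute_sag,
    features_table,
)
from striatype.exceptions import ExtractionError


def flat_recording(levels_by_amp, fs=10_000.0, pulse_shape=None):
    """Recording whose sweeps sit at a baseline and step to a given level.

    ``levels_by_amp`` maps stimulus (pA) -> (baseline mV, pulse level mV).
    ``pulse_shape(amp, t_pulse)`` may override the pulse segment entirely.
    """
    amps = tuple(sorted(levels_by_amp))
    proto = StepProtocol(step_amplitudes=amps, sampling_rate=fs)
    i0, i1 = proto.pulse_window()
    sweeps = []
    for amp in amps:
        base, level = levels_by_amp[amp]
        v = np.full(proto.n_samples, base)
        if pulse_shape is not None:
            v[i0:i1] = pulse_shape(amp, np.arange(i1 - i0) / fs)
        else:
            v[i0:i1] = level
        sweeps.append(Sweep(amp, v, proto.dt))
    return Recording("manual", proto, sweeps, series_resistance=10.0)


class TestDetection:
    def test_flat_trace_has_no_spikes(self):
        sw = Sweep(0.0, np.full(20_000, -70.0), 5e-5)
        assert detect_spikes(sw) == []

    def test_composed_single_ap(self):
        spec = WaveformSpec(ap_times=(0.5,), ap_peaks=(40.0,))
        rec = compose_waveform(spec, StepProtocol())
        events = detect_spikes(rec.sweep_at(100.0))
        assert len(events) == 1
        ev = events[0]
        dt_ms = 0.05
        slope = spec.true_max_rise()
        assert ev.half_width == pytest.approx(1.0, abs=dt_ms)
        assert ev.amplitude == pytest.approx(80.0, abs=slope * dt_ms)
        assert ev.v_peak == pytest.approx(40.0, abs=1e-9)

    @pytest.mark.parametrize("name", ["msn", "thin", "fan"])
    def test_count_matches_marker_crossing_oracle(self, name):
        """Detected spikes equal brute-force upward crossings of the
        simulator's peak-marker level on every sweep."""
        p = preset(name)
        rec = simulate_adex(p, noise_sd=0.3, seed=3)
        level = p.V_cut - 2.0  # below the marker even with measurement noise
        for sw in rec.sweeps:
            crossings = int(
                np.sum((sw.samples[1:] >= level) & (sw.samples[:-1] < level))
            )
            assert len(detect_spikes(sw)) == crossings

    def test_low_sampling_rate_warns(self):
        sw = Sweep(0.0, np.full(5000, -70.0), 1e-3)
        with pytest.warns(UserWarning, match="10 kHz"):
            detect_spikes(sw)


class TestPassiveFeatures:
    def test_rmp_exact_on_noise_free_cell(self, passive_recording):
        assert compute_rmp(passive_recording) == pytest.approx(-80.0, abs=1e-9)

    def test_rmp_two_sweeps_arithmetic(self):
        rec = flat_recording({-50.0: (-70.0, -75.0), 0.0: (-72.0, -72.0)})
        assert compute_rmp(rec) == pytest.approx(-71.0)

    def test_rmp_noise_averages_out(self, passive_params):
        rec = simulate_adex(passive_params, noise_sd=1.0, seed=11)
        assert compute_rmp(rec) == pytest.approx(-80.0, abs=0.1)

    def test_input_resistance_ideal_ohmic(self):
        # delta-V = 0.1 mV/pA -> exactly 100 MOhm
        rec = flat_recording(
            {a: (-70.0, -70.0 + 0.1 * a) for a in (-200.0, -100.0, -50.0, 50.0)}
        )
        assert compute_input_resistance(rec) == pytest.approx(100.0)

    def test_input_resistance_passive_simulation(self, passive_recording):
        assert compute_input_resistance(passive_recording) == pytest.approx(100.0, rel=0.05)

    def test_zero_response_gives_zero_resistance(self):
        rec = flat_recording({a: (-70.0, -70.0) for a in (-100.0, -50.0, 50.0)})
        assert compute_input_resistance(rec) == pytest.approx(0.0, abs=1e-9)

    def test_capacitance_recovers_simulator_truth(self, passive_recording):
        cap, tau = compute_capacitance(passive_recording)
        assert cap == pytest.approx(150.0, rel=0.05)
        assert tau == pytest.approx(15.0, rel=0.05)

    def test_doubling_capacitance_doubles_estimate(self, passive_params):
        import dataclasses

        doubled = dataclasses.replace(passive_params, C=2 * passive_params.C)
        rec = simulate_adex(doubled, noise_sd=0.0)
        cap, _ = compute_capacitance(rec)
        assert cap == pytest.approx(300.0, rel=0.05)

    def test_instant_step_is_degenerate(self):
        rec = flat_recording({a: (-70.0, -70.0 + 0.1 * a) for a in (-100.0, -50.0, 0.0)})
        with pytest.raises(ExtractionError):
            compute_capacitance(rec, input_resistance=100.0)

    def test_sag_from_min_and_steady(self):
        def pulse(amp, t):
            if amp != -200.0:
                return np.full(t.size, -70.0)
            # dip to -95 mV then settle at -85 mV
            return -85.0 - 10.0 * np.exp(-t / 0.05)

        rec = flat_recording(
            {-200.0: (-70.0, None), -150.0: (-70.0, -70.0)}, pulse_shape=pulse
        )
        # v_min ~ -95 at t=0, steady -85
        assert compute_sag(rec) == pytest.approx(10.0, abs=0.1)

    def test_monotone_exponential_has_zero_sag(self, passive_recording):
        assert compute_sag(passive_recording) == pytest.approx(0.0, abs=0.05)

    def test_subthreshold_adaptation_produces_sag(self, adex_reference):
        p = AdExParams(C=100.0, g_L=5.0, E_L=-75.0, V_T=0.0, Delta_T=0.5,
                       a=5.0, tau_w=100.0, b=0.0)
        proto = StepProtocol()
        rec = simulate_adex(p, proto, noise_sd=0.0)
        sag = compute_sag(rec)
        assert sag > 0.5
        # refined-step oracle on the -200 pA sweep
        _, trace = adex_reference(p, -200.0, proto, 0.025)
        i0, i1 = proto.pulse_window()
        ref = trace[::2][: proto.n_samples]
        s0 = i1 - int(0.1 * proto.sampling_rate)
        ref_sag = np.mean(ref[s0:i1]) - np.min(ref[i0:i1])
        assert sag == pytest.approx(ref_sag, abs=0.2)


class TestSpikeFeatures:
    def _composed(self, times, peaks):
        spec = WaveformSpec(
            ap_times=tuple(times), ap_peaks=tuple(peaks), ahp_dur=6.0
        )
        return compose_waveform(spec, StepProtocol()), spec

    def test_rheobase_smallest_spiking_step(self):
        rec, _ = self._composed((0.5,), (40.0,))
        assert compute_rheobase(rec) == 100.0

    def test_rheobase_undefined_without_spikes(self, passive_recording):
        assert np.isnan(compute_rheobase(passive_recording))

    def test_rheobase_matches_crossing_oracle_on_preset(self):
        p = preset("msn")
        rec = simulate_adex(p, noise_sd=0.3, seed=5)
        truth = {float(k): len(v) for k, v in rec.metadata["spike_times"].items()}
        expected = min((a for a, n in truth.items() if n > 0), default=np.nan)
        assert compute_rheobase(rec) == expected

    def test_waveform_features_from_first_spike_only(self):
        rec, spec = self._composed((0.45, 0.60), (40.0, 10.0))
        feats = ap_waveform_features(rec)
        assert feats["ap_amplitude"] == pytest.approx(80.0, abs=4.1)
        assert feats["ap_half_width"] == pytest.approx(1.0, abs=0.06)
        assert feats["ahp_amplitude"] == pytest.approx(10.0, abs=4.1)
        assert feats["max_rise_rate"] == pytest.approx(80.0, abs=2.0)
        assert feats["max_fall_rate"] == pytest.approx(80.0, abs=2.0)

    def test_waveform_features_undefined_without_rheobase(self, passive_recording):
        feats = ap_waveform_features(passive_recording)
        assert all(np.isnan(v) for v in feats.values())

    def test_uniform_train_has_unit_adaptation(self):
        times = tuple(0.3 + 0.01 * i for i in range(10))
        rec, _ = self._composed(times, (40.0,) * 10)
        freq, amp, defined = adaptation_features(rec)
        assert defined
        assert freq == pytest.approx(1.0, abs=0.02)
        assert amp == pytest.approx(1.0, abs=0.02)

    def test_lengthening_isis_frequency_adaptation(self):
        # ISIs 10, 20, ..., 80 ms: ratio 8
        isis = np.arange(10.0, 81.0, 10.0) / 1000.0
        times = tuple(0.25 + np.concatenate(([0.0], np.cumsum(isis))))
        assert len(times) == 9
        spec = WaveformSpec(ap_times=times, ap_peaks=(40.0,) * 9, ahp_dur=6.0)
        # extend to 10 spikes with one more 80 ms ISI would change the ratio;
        # keep 9 spikes on one sweep and a 10-spike train elsewhere instead.
        times10 = tuple(0.25 + np.concatenate(([0.0], np.cumsum(np.r_[isis, 0.08]))))
        spec10 = WaveformSpec(ap_times=times10, ap_peaks=(40.0,) * 10, ahp_dur=6.0)
        rec = compose_waveform(spec10, StepProtocol())
        freq, _, defined = adaptation_features(rec)
        assert defined
        assert freq == pytest.approx(8.0, abs=0.1)

    def test_nine_spikes_everywhere_leaves_adaptation_undefined(self):
        times = tuple(0.3 + 0.02 * i for i in range(9))
        rec, _ = self._composed(times, (40.0,) * 9)
        freq, amp, defined = adaptation_features(rec)
        assert not defined and np.isnan(freq) and np.isnan(amp)


class TestExtraction:
    def test_vector_has_twelve_features(self, passive_recording):
        feats = extract_features(passive_recording)
        assert feats.as_vector().shape == (12,)
        assert list(feats.as_series().index[:12]) == list(FEATURE_NAMES)

    def test_passive_cell_flags(self, passive_recording):
        feats = extract_features(passive_recording)
        assert not feats.rheobase_defined and not feats.adaptation_defined
        for name in ("rheobase", "ap_amplitude", "freq_adaptation"):
            assert np.isnan(getattr(feats, name))
        for name in ("capacitance", "input_resistance", "rmp", "sag"):
            assert np.isfinite(getattr(feats, name))

    def test_extraction_is_deterministic(self):
        rec = simulate_adex(preset("thin"), noise_sd=0.3, seed=9)
        a = extract_features(rec).as_vector()
        b = extract_features(rec).as_vector()
        np.testing.assert_array_equal(a, b)

    def test_features_table_layout(self, passive_recording):
        rec2 = simulate_adex(preset("fan"), noise_sd=0.3, seed=2, cell_id="fan0")
        table = features_table([extract_features(passive_recording), extract_features(rec2)])
        assert table.shape[0] == 2
        assert list(table.columns[:12]) == list(FEATURE_NAMES)

    def test_qc_gate_rejects_depolarized_cell(self):
        p = AdExParams(C=100.0, g_L=5.0, E_L=-45.0, V_T=0.0, Delta_T=0.5)
        rec = simulate_adex(p, noise_sd=0.0)
        with pytest.raises(ExtractionError, match="QC"):
            extract_features(rec, require_qc=True)
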