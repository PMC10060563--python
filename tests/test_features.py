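"""Feature extraction: spike detection, f-I curve, rheobase, R_in, passive/AP shape."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from painephys.features import (
    FICurve,
    compute_fi_curve,
    compute_input_resistance,
    compute_passive_and_ap_features,
    detect_spikes,
    estimate_rheobase,
    extract_cell_features,
)
from painephys.neuron import (
    NeuronParams,
    Recording,
    StepProtocol,
    simulate_neuron,
    spike_waveform,
)

from conftest import brute_force_spike_times_s


def _paste_spikes(protocol, params, at_ms):
    """Hand-built flat trace with stereotyped spike waveforms pasted at given times."""
    v = np.full(protocol.n_samples, -70.0)
    wave = spike_waveform(params, protocol.dt_ms)
    for t in at_ms:
        i = int(round(t / protocol.dt_ms))
        v[i] = params.spike_threshold_mV
        v[i + 1 : i + 1 + wave.size] = wave[: protocol.n_samples - i - 1]
    return v


class TestDetectSpikes:
    def test_flat_sweep_has_no_spikes(self, protocol):
        v = np.full(protocol.n_samples, -70.0)
        assert detect_spikes(v, protocol).size == 0

    def test_empty_sweep_rejected(self, protocol):
        with pytest.raises(ValueError):
            detect_spikes(np.array([]), protocol)

    def test_pasted_waveforms_found_at_their_times(self, protocol, quiet_cell):
        v = _paste_spikes(protocol, quiet_cell, [100.0, 200.0, 300.0])
        t = detect_spikes(v, protocol)
        assert t.size == 3
        np.testing.assert_allclose(t, [0.1, 0.2, 0.3], atol=0.5e-3)

    def test_matches_ground_truth_on_noiseless_lif(self, quiet_cell, protocol):
        rec = simulate_neuron(quiet_cell, protocol, seed=0)
        for s, amp in enumerate(protocol.current_amplitudes_pA):
            t = detect_spikes(rec.sweeps[s], protocol)
            true_t = np.asarray(rec.ground_truth["spike_times_s"][s])
            assert t.size == true_t.size
            if t.size:
                np.testing.assert_allclose(t, true_t, atol=0.5e-3)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000), noise=st.sampled_from([0.0, 0.3, 0.5]))
    def test_equivalent_to_brute_force_scan(self, seed, noise):
        """Vectorized detection == exhaustive per-sample criterion check."""
        proto = StepProtocol(baseline_ms=50.0, step_ms=200.0, post_ms=50.0)
        params = NeuronParams(150.0, 120.0, voltage_noise_sd_mV=noise)
        rec = simulate_neuron(params, proto, seed=seed)
        for sweep in rec.sweeps:
            got = detect_spikes(sweep, proto)
            want = brute_force_spike_times_s(sweep, proto.dt_ms)
            np.testing.assert_allclose(got, want, atol=1e-12)


class TestFICurve:
    def test_all_subthreshold_gives_zero_counts(self, quiet_cell):
        proto = StepProtocol(current_amplitudes_pA=(-300.0, -100.0, 50.0, 150.0))
        rec = simulate_neuron(quiet_cell, proto, seed=0)
        fi = compute_fi_curve(rec)
        assert np.all(fi.spike_counts == 0)

    def test_ten_step_protocol_gives_ten_points(self, quiet_cell, protocol):
        fi = compute_fi_curve(simulate_neuron(quiet_cell, protocol, seed=0))
        assert len(fi) == 10

    def test_counts_zero_below_and_nondecreasing_above_rheobase(self, quiet_cell, protocol):
        fi = compute_fi_curve(simulate_neuron(quiet_cell, protocol, seed=0))
        below = fi.currents_pA < quiet_cell.rheobase_pA
        assert np.all(fi.spike_counts[below] == 0)
        above = fi.spike_counts[~below]
        assert np.all(np.diff(above) >= 0) and above[-1] > 0

    def test_rate_is_count_over_step_duration(self, quiet_cell, protocol):
        fi = compute_fi_curve(simulate_neuron(quiet_cell, protocol, seed=0))
        np.testing.assert_allclose(fi.firing_rates_Hz, fi.spike_counts / 0.5)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            FICurve(np.array([0.0, 100.0]), np.array([-1.0, 2.0]), np.array([0.0, 4.0]))


class TestRheobase:
    def _fi(self, currents, counts):
        c = np.asarray(currents, float)
        n = np.asarray(counts, float)
        return FICurve(c, n, n / 0.5)

    def test_spec_shaped_curve_brackets_and_matches_dense_grid(self):
        currents = np.arange(-300.0, 601.0, 100.0)
        counts = [0, 0, 0, 0, 0, 4, 8, 11, 13, 15]
        est, flags = estimate_rheobase(self._fi(currents, counts))
        assert flags == []
        assert 100.0 < est <= 200.0
        # independent dense-grid evaluation of the same monotone spline
        from scipy.interpolate import PchipInterpolator

        nn = currents >= 0
        spl = PchipInterpolator(currents[nn], np.asarray(counts, float)[nn])
        grid = np.arange(101.0, 201.0, 1.0)
        expected = grid[np.flatnonzero(spl(grid) >= 1.0)[0]]
        assert est == pytest.approx(expected)

    def test_silent_cell_is_flagged_undefined(self):
        est, flags = estimate_rheobase(self._fi(np.arange(-300, 601, 100), np.zeros(10)))
        assert est is None and "rheobase_undefined" in flags

    def test_everything_spiking_returns_smallest_current_flagged(self):
        currents = np.arange(0.0, 401.0, 100.0)
        est, flags = estimate_rheobase(self._fi(currents, [2, 5, 8, 10, 12]))
        assert est == 0.0 and "rheobase_all_spiking" in flags

    def test_noiseless_lif_estimate_within_one_grid_step(self, quiet_cell, protocol):
        fi = compute_fi_curve(simulate_neuron(quiet_cell, protocol, seed=0))
        est, flags = estimate_rheobase(fi)
        assert flags == []
        assert abs(est - quiet_cell.rheobase_pA) <= 100.0
        assert 200.0 < est <= 300.0  # bracket: last zero-count was 200 pA


class TestInputResistance:
    def test_ohms_law_on_noiseless_cell(self, quiet_cell, protocol):
        rec = simulate_neuron(quiet_cell, protocol, seed=0)
        rin, dv, flags = compute_input_resistance(rec)
        assert rin == pytest.approx(100.0, rel=0.02)
        assert dv == pytest.approx(-30.0, rel=0.02)
        assert flags == []

    def test_recovers_r150_within_one_percent(self, protocol):
        params = NeuronParams(150.0, 150.0, voltage_noise_sd_mV=0.0)
        rin, _, _ = compute_input_resistance(simulate_neuron(params, protocol, seed=0))
        assert rin == pytest.approx(150.0, rel=0.01)

    def test_flat_sweep_flagged_implausible(self, protocol):
        sweeps = np.full((10, protocol.n_samples), -70.0)
        rec = Recording(sweeps, protocol, "c", "a")
        rin, dv, flags = compute_input_resistance(rec)
        assert rin == 0.0 and dv == 0.0
        assert "rin_implausible" in flags

    def test_missing_hyperpolarizing_sweep_rejected(self, quiet_cell):
        proto = StepProtocol(current_amplitudes_pA=(-200.0, 0.0, 200.0))
        rec = simulate_neuron(quiet_cell, proto, seed=0)
        with pytest.raises(ValueError):
            compute_input_resistance(rec)

    def test_gaussian_noise_changes_estimate_below_3_percent(self, protocol):
        quiet = NeuronParams(100.0, 100.0, voltage_noise_sd_mV=0.0)
        noisy = NeuronParams(100.0, 100.0, voltage_noise_sd_mV=0.5)
        r0, _, _ = compute_input_resistance(simulate_neuron(quiet, protocol, seed=0))
        for seed in range(5):
            r1, _, _ = compute_input_resistance(simulate_neuron(noisy, protocol, seed=seed))
            assert abs(r1 - r0) / r0 < 0.03


class TestPassiveAndAPFeatures:
    def test_parameter_recovery_grid(self, protocol):
        # R_m in {50,100,200,300} MOhm: R_in within 2%, tau within 5% of R*C
        for rm in (50.0, 100.0, 200.0, 300.0):
            params = NeuronParams(rm, 100.0, voltage_noise_sd_mV=0.0)
            rec = simulate_neuron(params, protocol, seed=0)
            rin, _, _ = compute_input_resistance(rec)
            feats = compute_passive_and_ap_features(rec)
            assert rin == pytest.approx(rm, rel=0.02)
            assert feats.tau_ms == pytest.approx(params.tau_ms, rel=0.05)

    def test_rmp_equals_flat_baseline(self, quiet_cell, protocol):
        rec = simulate_neuron(quiet_cell, protocol, seed=0)
        feats = compute_passive_and_ap_features(rec)
        assert feats.rmp_mV == pytest.approx(-70.0, abs=0.05)

    def test_pasted_waveform_amplitude_is_peak_minus_threshold(self, quiet_cell, protocol):
        # threshold crossing at -50 mV, peak +30 mV -> amplitude 80 mV
        rec = simulate_neuron(quiet_cell, protocol, seed=0)
        feats = compute_passive_and_ap_features(rec)
        assert feats.ap_threshold_mV == pytest.approx(-50.0, abs=0.5)
        assert feats.ap_amplitude_mV == pytest.approx(80.0, abs=1.0)
        assert 0.2 < feats.ap_halfwidth_ms < 2.0

    def test_silent_cell_ap_features_flagged(self, protocol):
        sweeps = np.full((10, protocol.n_samples), -70.0)
        rec = Recording(sweeps, protocol, "c", "a")
        feats = compute_passive_and_ap_features(rec)
        assert "ap_no_spikes" in feats.flags
        assert np.isnan(feats.ap_amplitude_mV)


class TestExtractCellFeatures:
    def test_assembles_ten_point_fi_curve_and_passes_qc(self, quiet_cell, protocol):
        rec = simulate_neuron(quiet_cell, protocol, seed=0, cell_id="c1", animal_id="a1")
        f = extract_cell_features(rec)
        assert len(f.fi) == 10
        assert not f.excluded
        assert f.cell_id == "c1" and f.animal_id == "a1"
        assert f.n_spikes_at(200.0) == 0.0

    def test_silent_cell_is_excluded_from_composites(self, protocol):
        sweeps = np.full((10, protocol.n_samples), -70.0)
        f = extract_cell_features(Recording(sweeps, protocol, "c", "a"))
        assert f.rheobase_pA is None
        assert f.excluded

    def test_malformed_recording_rejected(self, protocol):
        with pytest.raises(ValueError):
            Recording(np.zeros((3, protocol.n_samples)), protocol, "c", "a")
        with pytest.raises(ValueError):
            Recording(np.zeros((10, 17)), protocol, "c", "a")
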