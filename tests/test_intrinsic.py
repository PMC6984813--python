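import math

import numpy as np
import pytest

from clampkit import intrinsic as ip
from clampkit.core import VOLTAGE, Sweep
from clampkit.simulate import SimNeuronSpec, sim_step_protocol

from conftest import FS, make_step_sweepset, make_sweep


def _voltage(samples, fs=FS):
    return make_sweep(samples, kind=VOLTAGE, fs=fs)


def _triangle_spike(base_v=-60.0, peak_v=20.0, base_width_ms=2.0, at=0.05,
                    total_s=0.2, fs=FS):
    """Symmetric triangular spike (half-amplitude width = base/2)."""
    n = int(total_s * fs)
    y = np.full(n, base_v)
    half = int(base_width_ms / 2 * fs / 1e3)
    i0 = int(at * fs)
    y[i0 : i0 + half] = np.linspace(base_v, peak_v, half, endpoint=False)
    y[i0 + half : i0 + 2 * half] = np.linspace(peak_v, base_v, half, endpoint=False)
    return _voltage(y)


class TestDetectAps:
    def test_subthreshold_sweep(self):
        y = -60.0 + 5.0 * np.sin(np.linspace(0, 10, 2000))
        assert ip.detect_aps(_voltage(y)) == []

    def test_current_sweep_rejected(self):
        with pytest.raises(ValueError):
            ip.detect_aps(make_sweep(np.zeros(100)))

    def test_triangle_spike_detected(self):
        aps = ip.detect_aps(_triangle_spike())
        assert len(aps) == 1
        ap = aps[0]
        assert ap.peak_v == pytest.approx(20.0, abs=0.5)
        assert ap.amplitude > 0

    def test_threshold_matches_dense_grid_oracle(self):
        # logistic upstroke: V(t) = -60 + 80/(1+exp(-(t-t0)/s))
        t0, s = 0.05, 0.0005  # max slope 80/(4s) = 40 V/s
        t = np.arange(int(0.1 * FS)) / FS
        y = -60 + 80 / (1 + np.exp(-(t - t0) / s))
        aps = ip.detect_aps(_voltage(y))
        assert len(aps) == 1
        # oracle: dV/dt = 80/(4s) * sech^2 term; crossing of 20 V/s found by
        # brute force on a 100x denser grid (centered differences, like the
        # implementation, converge to the analytic derivative)
        td = np.arange(int(0.1 * FS * 100)) / (FS * 100)
        yd = -60 + 80 / (1 + np.exp(-(td - t0) / s))
        dvd = np.gradient(yd) * FS * 100 / 1000
        cross = td[np.argmax(dvd >= 20.0)]
        assert aps[0].threshold_t == pytest.approx(cross, abs=1.5 / FS)

    def test_two_spikes_isi(self):
        y = np.full(int(0.2 * FS), -60.0)
        for at in (0.05, 0.065):
            spike = _triangle_spike(at=at).samples
            y = np.maximum(y, spike)
        aps = ip.detect_aps(_voltage(y))
        assert len(aps) == 2
        assert (aps[1].peak_t - aps[0].peak_t) * 1e3 == pytest.approx(15.0, abs=0.2)

    def test_dc_offset_invariance(self):
        base = _triangle_spike()
        shifted = _voltage(base.samples + 17.0)
        a, b = ip.detect_aps(base)[0], ip.detect_aps(shifted)[0]
        assert b.threshold_v == pytest.approx(a.threshold_v + 17.0, abs=1e-9)
        assert b.amplitude == pytest.approx(a.amplitude, abs=1e-9)
        assert b.halfwidth == pytest.approx(a.halfwidth, abs=1e-9)


class TestApWaveformFeatures:
    def test_triangle_halfwidth(self):
        # symmetric triangle, total base width 2 ms -> halfwidth 1 ms
        aps = ip.detect_aps(_triangle_spike(base_width_ms=2.0))
        assert aps[0].halfwidth == pytest.approx(1.0, abs=0.11)

    def test_no_ahp_when_v_stays_at_baseline(self):
        # trace returns to baseline = threshold region; never below threshold
        aps = ip.detect_aps(_triangle_spike())
        assert aps[0].ahp_magnitude <= 0
        # threshold is on the rising flank (>= base) so trough-at-baseline
        # can only be <= 0; with V never below threshold it is exactly 0
        y = _triangle_spike().samples
        y[y < -60] = -60
        aps2 = ip.detect_aps(_voltage(y))
        if aps2[0].threshold_v <= -60.0:
            assert aps2[0].ahp_magnitude == 0.0

    def test_gaussian_rise_exponential_fall_halfwidth(self):
        # analytic crossings: gaussian rise sd=0.3ms, exponential fall tau=1ms
        fs = FS
        amp, thr = 80.0, -60.0
        t = np.arange(int(0.05 * fs)) / fs
        peak_t = 0.02
        sd, tau = 0.3e-3, 1.0e-3
        y = np.where(
            t <= peak_t,
            thr + amp * np.exp(-((t - peak_t) ** 2) / (2 * sd**2)),
            thr + amp * np.exp(-(t - peak_t) / tau),
        )
        aps = ip.detect_aps(_voltage(y))
        assert len(aps) == 1
        # closed-form half-amplitude crossings relative to detected threshold
        half = (aps[0].peak_v + aps[0].threshold_v) / 2
        frac = (half - thr) / amp
        t_up = peak_t - sd * math.sqrt(-2 * math.log(frac))
        t_down = peak_t + tau * (-math.log(frac))
        expected = (t_down - t_up) * 1e3
        assert aps[0].halfwidth == pytest.approx(expected, abs=0.1)

    def test_phase_plot_contract(self):
        aps = ip.detect_aps(_triangle_spike())
        pp = ip.phase_plot(_triangle_spike(), aps)
        assert len(pp.v) == len(pp.dvdt)


def _rc_sweep(current, r_m=100.0, tau_ms=20.0, v0=-60.0, sag_pct=0.0,
              onset=0.2, dur=0.6, post=0.4, fs=FS):
    n = int((onset + dur + post) * fs)
    y = np.full(n, v0)
    i0, i1 = int(onset * fs), int((onset + dur) * fs)
    t = np.arange(i1 - i0) / fs
    dv = current * r_m * 1e-3
    y[i0:i1] += dv * (1 - np.exp(-t / (tau_ms * 1e-3)))
    t2 = np.arange(n - i1) / fs
    y[i1:] = v0 + (y[i1 - 1] - v0) * np.exp(-t2 / (tau_ms * 1e-3))
    return _voltage(y)


class TestPassiveFeatures:
    def test_ohmic_membrane_resistance(self):
        fine = make_step_sweepset(
            lambda c: _rc_sweep(c, r_m=100.0), range(-100, 101, 10)
        )
        out = ip.passive_features(fine)
        # 1 mV per 10 pA -> 100 MOhm (small charging-window bias allowed)
        assert out["membrane_resistance"] == pytest.approx(100.0, rel=0.03)

    def test_decay_tau(self):
        fine = make_step_sweepset(
            lambda c: _rc_sweep(c, tau_ms=20.0), range(-100, 101, 10)
        )
        out = ip.passive_features(fine)
        assert out["membrane_decay_tau"] == pytest.approx(20.0, abs=0.5)

    def test_sag_formula_direct(self):
        # V_bl=-60, V_min=-80, V_ss=-75 -> 25%
        def build(c):
            n = int(1.2 * FS)
            y = np.full(n, -60.0)
            i0, i1 = int(0.2 * FS), int(0.8 * FS)
            if c == -200.0:
                y[i0:i1] = -75.0
                y[i0 : i0 + 100] = np.linspace(-60, -80, 100)
                y[i0 + 100 : i0 + 200] = np.linspace(-80, -75, 200)[::2]
                t2 = np.arange(n - i1) / FS
                y[i1:] = -60.0 - 15.0 * np.exp(-t2 / 0.02)  # smooth recovery
            return _voltage(y)

        coarse = make_step_sweepset(build, range(-200, 401, 25))
        out = ip.passive_features(coarse, coarse)
        assert out["sag"] == pytest.approx(25.0, abs=0.5)
        assert out["rebound_spikes"] == 0.0

    def test_simulated_neuron_recovery(self):
        spec = SimNeuronSpec(r_m=200.0, tau_m=20.0, sag_fraction=25.0,
                             rebound_count=2, rheobase=150.0, noise_sd=0.05)
        fine, _ = sim_step_protocol(spec, "fine", seed=3)
        coarse, _ = sim_step_protocol(spec, "coarse", seed=4)
        out = ip.passive_features(fine, coarse)
        assert out["membrane_resistance"] == pytest.approx(200.0, rel=0.05)
        assert out["membrane_decay_tau"] == pytest.approx(20.0, rel=0.05)
        assert out["sag"] == pytest.approx(25.0, abs=2.0)
        assert out["rebound_spikes"] == 2.0


def _train_sweep(spike_peaks_ms, current, onset=0.2, dur=0.6, fs=FS,
                 halfwidths=None, amplitudes=None):
    """Plateau at threshold with triangular spikes at given times (ms)."""
    n = int((onset + dur + 0.4) * fs)
    y = np.full(n, -60.0)
    i0, i1 = int(onset * fs), int((onset + dur) * fs)
    if spike_peaks_ms:
        y[i0:i1] = -45.0
        ramp = int(0.01 * fs)  # slow charge to the plateau (< 20 V/s)
        y[i0 : i0 + ramp] = np.linspace(-60.0, -45.0, ramp)
        hws = halfwidths or [0.6] * len(spike_peaks_ms)
        amps = amplitudes or [70.0] * len(spike_peaks_ms)
        for t_ms, hw, amp in zip(spike_peaks_ms, hws, amps):
            half = int(hw * fs / 1e3)
            p = i0 + int(t_ms * fs / 1e3)
            y[p - half : p] = np.linspace(-45.0, -45.0 + amp, half, endpoint=False)
            y[p : p + half] = np.linspace(-45.0 + amp, -45.0, half, endpoint=False)
    return _voltage(y)


class TestTrainFeatures:
    def _series(self, trains):
        """trains: {current: spike times ms} for the coarse series."""
        return make_step_sweepset(
            lambda c: _train_sweep(trains.get(c, []), c), range(-200, 401, 25)
        )

    def test_regular_isis_max_fr(self):
        trains = {}
        for c in range(100, 401, 25):
            trains[float(c)] = list(np.arange(20.0, 580.0, 10.0))  # 100 Hz
        out = ip.train_features(self._series(trains))
        assert out["max_firing_rate"] == pytest.approx(100.0, rel=0.01)
        assert out["fr_adaptation"] == pytest.approx(1.0, rel=0.01)
        assert out["latency_first_ap"] == pytest.approx(20.0, abs=0.2)

    def test_adaptation_ratio(self):
        # ISIs 10, 20, 20, 20 ms at rheobase + 50
        trains = {100.0: [20.0, 30.0], 150.0: [20.0, 30.0, 50.0, 70.0, 90.0]}
        for c in range(175, 401, 25):
            trains[float(c)] = [20.0, 30.0, 50.0, 70.0, 90.0, 110.0]
        out = ip.train_features(self._series(trains))
        assert out["fr_adaptation"] == pytest.approx(10.0 / 20.0, rel=0.01)

    def test_identical_waveforms_unity_ratios(self):
        trains = {100.0: [50.0]}
        for c in range(125, 401, 25):
            trains[float(c)] = [20.0, 60.0, 100.0, 140.0, 180.0]
        out = ip.train_features(self._series(trains))
        assert out["ap_broadening"] == pytest.approx(1.0, abs=0.02)
        assert out["ap_amplitude_adaptation"] == pytest.approx(1.0, abs=0.02)
        assert out["delta_ahp"] == pytest.approx(0.0, abs=0.5)

    def test_too_few_aps_flagged(self):
        trains = {100.0: [50.0], 150.0: [50.0, 70.0]}
        out = ip.train_features(self._series(trains))
        assert math.isnan(out["fr_adaptation"])
        assert math.isnan(out["ap_amplitude_adaptation"])

    def test_max_fr_monotone_in_planted_rate(self):
        rates = [50.0, 100.0, 200.0]
        measured = []
        for r in rates:
            spec = SimNeuronSpec(max_rate=r, rheobase=150.0, noise_sd=0.05)
            coarse, _ = sim_step_protocol(spec, "coarse", seed=int(r))
            measured.append(ip.train_features(coarse)["max_firing_rate"])
        assert measured == sorted(measured)


class TestStimulusResponse:
    def _evoked_cc(self, epsp_mv=4.0, ap_on_first=False):
        from clampkit.core import ProtocolMetadata, SweepSet

        n = int(1.2 * FS)
        y = np.full(n, -60.0)
        stims = [0.6 + k * 0.05 for k in range(5)]
        for stim in stims:
            i0 = int((stim + 0.015) * FS)
            bump = epsp_mv * np.exp(-np.arange(300) / (5e-3 * FS))
            rise = np.linspace(0, epsp_mv, 50, endpoint=False)
            y[i0 - 50 : i0] += rise
            y[i0 : i0 + 300] += bump
        if ap_on_first:
            spike = _triangle_spike(at=0.0, base_width_ms=2.0).samples[: int(0.02 * FS)]
            i0 = int((stims[0] + 0.005) * FS)
            y[i0 : i0 + spike.size] = np.maximum(y[i0 : i0 + spike.size], spike + 80)
        sweep = Sweep(samples=y, sampling_rate=FS, signal_kind=VOLTAGE,
                      stimulus_times=stims,
                      artifact_windows=[(s, s + 2e-3) for s in stims])
        proto = ProtocolMetadata(protocol_kind="evoked_cc", stim_frequency=20.0,
                                 stim_count=5, stimulation_charge=273.0)
        return SweepSet(sweeps=[sweep], protocol=proto)

    def test_subthreshold_epsp(self):
        sr = ip.stimulus_response_features(self._evoked_cc(epsp_mv=4.0))
        assert sr.aps_per_stimulus == 0.0
        assert np.max(sr.subthreshold_epsp_amplitudes) == pytest.approx(4.0, abs=0.3)
        assert sr.v_rest == pytest.approx(-60.0, abs=0.1)

    def test_ap_counting(self):
        sr = ip.stimulus_response_features(self._evoked_cc(ap_on_first=True))
        assert sr.aps_per_stimulus == pytest.approx(0.2)

    def test_stimulation_charge_metadata(self):
        sset = self._evoked_cc()
        assert sset.protocol.stimulation_charge == 273.0


class TestDrugTimecourse:
    FS_LOW = 100.0

    def _vm(self, samples):
        return Sweep(samples=samples, sampling_rate=self.FS_LOW,
                     signal_kind=VOLTAGE)

    def test_constant(self):
        vm = self._vm(np.full(int(900 * self.FS_LOW), -55.0))
        tc = ip.drug_timecourse(vm, drug_onset=240.0)
        assert tc.delta_vm == pytest.approx(0.0, abs=1e-9)
        assert tc.bin_s == 30.0

    def test_step_change(self):
        n = int(900 * self.FS_LOW)
        y = np.full(n, -55.0)
        y[int(240 * self.FS_LOW):] = -60.0
        tc = ip.drug_timecourse(self._vm(y), drug_onset=240.0)
        assert tc.delta_vm == pytest.approx(-5.0, abs=1e-9)

    def test_exponential_approach(self):
        n = int(900 * self.FS_LOW)
        t = np.arange(n) / self.FS_LOW
        onset = 240.0
        y = np.full(n, -55.0)
        post = t >= onset
        y[post] = -55.0 - 6.0 * (1 - np.exp(-(t[post] - onset) / 60.0))
        tc = ip.drug_timecourse(self._vm(y), drug_onset=onset)
        assert tc.delta_vm == pytest.approx(-6.0, rel=0.02)

    def test_insufficient_duration(self):
        vm = self._vm(np.zeros(int(100 * self.FS_LOW)))
        with pytest.raises(ValueError):
            ip.drug_timecourse(vm, drug_onset=50.0)


class TestAssembleFeatureVector:
    def test_roster_is_exactly_15(self):
        assert len(ip.PROPERTY_NAMES) == 15
        vec = ip.MembranePropertyVector()
        assert len(vec.to_series()) == 15

    def test_missing_series_flagged(self):
        spec = SimNeuronSpec(noise_sd=0.05)
        fine, _ = sim_step_protocol(spec, "fine", seed=5)
        vec = ip.assemble_feature_vector(fine, None)
        assert "sag" in vec.missing  # no -200 pA step in the fine series
        assert "rebound_spikes" in vec.missing
        assert not math.isnan(vec.membrane_resistance)

    def test_full_recovery_within_tolerances(self):
        spec = SimNeuronSpec(
            r_m=250.0, tau_m=18.0, sag_fraction=20.0, rebound_count=1,
            rheobase=125.0, max_rate=150.0, ap_halfwidth=0.6, noise_sd=0.05,
        )
        fine, _ = sim_step_protocol(spec, "fine", seed=6)
        coarse, truth = sim_step_protocol(spec, "coarse", seed=7)
        vec = ip.assemble_feature_vector(fine, coarse)
        assert vec.missing == ()
        assert vec.membrane_resistance == pytest.approx(250.0, rel=0.05)
        assert vec.membrane_decay_tau == pytest.approx(18.0, rel=0.05)
        assert vec.sag == pytest.approx(20.0, abs=2.0)
        assert vec.max_firing_rate == pytest.approx(truth.max_firing_rate, rel=0.02)
        assert vec.ap_halfwidth == pytest.approx(truth.ap_halfwidth, abs=0.1)
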