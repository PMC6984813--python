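"""Ground-truth synthetic recordings and feature tables.

Every generator is a pure function of (spec, seed).  Voltage dynamics are
phenomenological — a leaky integrator with an explicit sag relaxation and
parametric AP waveforms written into the trace — because the acceptance
surface is feature recovery, not biophysics.  Quantities that are
discretized onto the sample grid (spike times, halfwidths) are reported in
the attached ground truth at their *realized* values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from clampkit.core import (
    COARSE_STEP_CURRENTS,
    CURRENT,
    FINE_STEP_CURRENTS,
    VOLTAGE,
    ProtocolMetadata,
    Sweep,
    SweepSet,
)
from clampkit.intrinsic import PROPERTY_NAMES, MembranePropertyVector

FS_LABEL, NFS_LABEL = "FS", "nFS"

SAG_CURRENT_MAX = -150.0  # pA; sag relaxation applied at or below this step


@dataclass
class SimNeuronSpec:
    """Parametric neuron for the current-step simulator."""

    class_label: str = FS_LABEL
    r_m: float = 200.0  # MOhm
    tau_m: float = 12.0  # ms
    v_rest: float = -60.0  # mV
    rheobase: float = 150.0  # pA (multiple of 25 keeps both series consistent)
    max_rate: float = 200.0  # Hz
    sag_fraction: float = 5.0  # %
    rebound_count: int = 0
    ap_threshold: float = -40.0  # mV
    ap_amplitude: float = 65.0  # mV
    ap_halfwidth: float = 0.5  # ms
    ahp_magnitude: float = -12.0  # mV (trough relative to threshold)
    ahp_latency: float = 6.0  # ms
    fr_adaptation: float = 0.9  # ISI_first / mean(last two ISIs)
    ap_broadening: float = 1.05
    ap_amplitude_adaptation: float = 0.95
    delta_ahp: float = -1.0  # mV
    rheobase_rate: float = 8.0  # Hz at rheobase
    latency_first_ap: float = 50.0  # ms
    noise_sd: float = 0.1  # mV
    tau_sag: float = 80.0  # ms


@dataclass
class SimEvokedSpec:
    success_prob: float = 0.5
    u_amp: float = -20.0  # pA (all-or-none)
    latency: float = 2.0  # ms after artifact end
    jitter_sd: float = 0.3  # ms
    rise: float = 0.5  # ms (kernel rise time constant)
    tau_decay: float = 3.0  # ms
    noise_sd: float = 2.0  # pA
    n_sweeps: int = 30
    stimulation_charge: float = 273.0  # nC
    sweep_s: float = 1.2
    stim_time: float = 0.6  # s
    artifact_ms: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.success_prob <= 1.0:
            raise ValueError("success_prob must be in [0, 1]")


@dataclass
class SimSpontSpec:
    rate: float = 5.0  # Hz, Poisson
    amp_median: float = 20.0  # pA (lognormal median)
    amp_shape: float = 0.3  # lognormal sigma
    rise: float = 0.5  # ms
    tau: float = 4.0  # ms
    noise_sd: float = 2.0  # pA
    duration: float = 300.0  # s

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


# ---------------------------------------------------------------------------
# AP and PSC kernels
# ---------------------------------------------------------------------------


def _ap_kernel(
    fs: float,
    amplitude: float,
    halfwidth_ms: float,
    ahp_mv: float,
    ahp_latency_ms: float,
    recovery_tau_ms: float = 15.0,
) -> tuple[np.ndarray, float]:
    """Spike waveform relative to threshold; returns (kernel, realized hw ms).

    Linear rise (0.8·hw) to the peak and fall (1.2·hw) back to threshold —
    so the half-amplitude width is the requested halfwidth — then a
    half-cosine dip to the AHP trough at ``ahp_latency`` and an exponential
    recovery.
    """
    ms = fs / 1e3
    n_r = int(round(0.8 * halfwidth_ms * ms))
    n_f = int(round(1.2 * halfwidth_ms * ms))
    if n_r < 2 or n_f < 2:
        raise ValueError("halfwidth below 2 sample periods")
    rise = np.linspace(0.0, amplitude, n_r + 1)[1:]
    fall = np.linspace(amplitude, 0.0, n_f + 1)[1:]
    n_trough = max(2, int(round(ahp_latency_ms * ms)) - n_r - n_f)
    dip = ahp_mv * (1 - np.cos(np.linspace(0, np.pi, n_trough + 1)[1:])) / 2.0
    n_rec = int(round(5 * recovery_tau_ms * ms))
    rec = ahp_mv * np.exp(-np.arange(1, n_rec + 1) / (recovery_tau_ms * ms))
    realized_hw = (n_r + n_f) / 2.0 / ms
    return np.concatenate([rise, fall, dip, rec]), realized_hw


def psc_kernel(fs: float, rise_ms: float, tau_ms: float, spans: float = 8.0) -> np.ndarray:
    """Unit-peak double-exponential PSC kernel."""
    n = int(round(spans * tau_ms * 1e-3 * fs))
    t = np.arange(n) / fs * 1e3
    k = np.exp(-t / tau_ms) - np.exp(-t / rise_ms)
    return k / k.max()


# ---------------------------------------------------------------------------
# Current-step protocol
# ---------------------------------------------------------------------------


def _spike_plan(
    spec: SimNeuronSpec, current: float, fs: float, step_s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Realized spike times (s, step-relative) and first-200-ms min ISI.

    Rate ramps linearly from ``rheobase_rate`` at rheobase to ``max_rate``
    at the penultimate coarse step (+375 pA); the top step (+400) fires a
    truncated train so max-FR step selection sees attenuation.  The first
    ISI is the base ISI, later ISIs base/fr_adaptation.
    """
    ms = fs / 1e3
    i_peak = COARSE_STEP_CURRENTS[-2]  # +375 pA
    frac = np.clip(
        (current - spec.rheobase) / max(i_peak - spec.rheobase, 25.0), 0.0, 1.0
    )
    rate = spec.rheobase_rate + frac * (spec.max_rate - spec.rheobase_rate)
    lat_samples = max(
        int(round(spec.latency_first_ap * ms * spec.rheobase / max(current, 1.0))),
        int(round(2.0 * ms)),
    )
    isi1 = max(2, int(round(fs / rate)))
    isi_late = max(2, int(round(isi1 / spec.fr_adaptation)))
    # keep the last AHP inside the step
    end = int(round((step_s - (spec.ahp_latency + 25.0) * 1e-3) * fs))
    times = [lat_samples]
    nxt = lat_samples + isi1
    while nxt < end:
        times.append(nxt)
        nxt += isi_late
    if current >= COARSE_STEP_CURRENTS[-1]:  # attenuated top step
        times = times[: max(1, len(times) // 2)]
    return np.asarray(times, dtype=int), np.asarray([isi1, isi_late], dtype=int)


def _write_train(
    v: np.ndarray,
    onset_i: int,
    spike_samples: np.ndarray,
    spec: SimNeuronSpec,
    fs: float,
) -> dict:
    """Overwrite the suprathreshold plateau with the AP train; return realized
    per-spike waveform parameters."""
    n = len(spike_samples)
    amps = np.full(n, spec.ap_amplitude)
    hws = np.full(n, spec.ap_halfwidth)
    ahps = np.full(n, spec.ahp_magnitude)
    if n >= 2:
        hws[1:] = spec.ap_halfwidth * spec.ap_broadening
        ahps[:] = np.linspace(
            spec.ahp_magnitude, spec.ahp_magnitude + spec.delta_ahp, n
        )
    if n >= 4:
        amps[:] = np.linspace(
            spec.ap_amplitude, spec.ap_amplitude * spec.ap_amplitude_adaptation, n
        )
        amps[-3:] = spec.ap_amplitude * spec.ap_amplitude_adaptation
        amps[0] = spec.ap_amplitude
    elif n >= 2:
        amps[1:] = spec.ap_amplitude * spec.ap_amplitude_adaptation
    realized_hw = np.empty(n)
    for k, s in enumerate(spike_samples):
        kernel, realized_hw[k] = _ap_kernel(
            fs, amps[k], hws[k], ahps[k], spec.ahp_latency
        )
        i0 = onset_i + s
        stop = len(v)
        if k + 1 < n:
            stop = min(stop, onset_i + spike_samples[k + 1])
        m = min(kernel.size, stop - i0)
        if m > 0:
            v[i0 : i0 + m] = spec.ap_threshold + kernel[:m]
    return {"amps": amps, "hws": realized_hw, "ahps": ahps}


def sim_step_sweep(
    spec: SimNeuronSpec,
    current: float,
    rng: np.random.Generator,
    fs: float = 10_000.0,
    onset_s: float = 0.2,
    step_s: float = 0.6,
    post_s: float = 0.6,
) -> tuple[Sweep, dict]:
    """One 600 ms square-step voltage response with ground truth."""
    ms = fs / 1e3
    n = int(round((onset_s + step_s + post_s) * fs))
    onset_i, offset_i = int(round(onset_s * fs)), int(round((onset_s + step_s) * fs))
    v = np.full(n, spec.v_rest)
    tau = spec.tau_m * ms  # samples
    truth: dict = {"current": current, "spike_times": np.array([])}

    spiking = current >= spec.rheobase
    dv_inf = (
        spec.ap_threshold - spec.v_rest
        if spiking
        else current * spec.r_m * 1e-3
    )
    t_step = np.arange(offset_i - onset_i)
    if not spiking and current <= SAG_CURRENT_MAX and spec.sag_fraction > 0:
        # charge to the trough, then relax toward steady state with tau_sag
        dv_ss = dv_inf * (1.0 - spec.sag_fraction / 100.0)
        t_min = int(round(5 * tau))
        charge = dv_inf * (1 - np.exp(-t_step[:t_min] / tau)) / (1 - math.exp(-5))
        relax = dv_ss + (dv_inf - dv_ss) * np.exp(
            -(t_step[t_min:] - t_min) / (spec.tau_sag * ms)
        )
        v[onset_i:offset_i] += np.concatenate([charge, relax]) - 0.0
        v_end = v[offset_i - 1]
    else:
        v[onset_i:offset_i] += dv_inf * (1 - np.exp(-t_step / tau))
        v_end = v[offset_i - 1]

    # post-step relaxation back to rest
    t_post = np.arange(n - offset_i)
    v[offset_i:] = spec.v_rest + (v_end - spec.v_rest) * np.exp(-t_post / tau)

    if spiking:
        spike_samples, isis = _spike_plan(spec, current, fs, step_s)
        waveforms = _write_train(v, onset_i, spike_samples, spec, fs)
        truth["spike_times"] = onset_i / fs + spike_samples / fs
        truth["isis"] = isis / fs
        truth["waveforms"] = waveforms

    if np.isclose(current, -200.0) and spec.rebound_count > 0:
        kernel, _ = _ap_kernel(
            fs, spec.ap_amplitude, spec.ap_halfwidth, spec.ahp_magnitude,
            spec.ahp_latency,
        )
        for k in range(spec.rebound_count):
            i0 = offset_i + int(round((0.03 + 0.06 * k) * fs))
            m = min(kernel.size, n - i0)
            v[i0 : i0 + m] += kernel[:m]

    v = v + rng.normal(0.0, spec.noise_sd, size=n)
    sweep = Sweep(
        samples=v,
        sampling_rate=fs,
        signal_kind=VOLTAGE,
        step_current=float(current),
    )
    return sweep, truth


def sim_step_protocol(
    spec: SimNeuronSpec,
    protocol: str = "coarse",
    seed: int = 0,
    fs: float = 10_000.0,
) -> tuple[SweepSet, MembranePropertyVector]:
    """Simulate one of the two current-step series with attached ground truth.

    ``protocol`` is ``"fine"`` (−100→+100 pA, 10 pA) or ``"coarse"``
    (−200→+400 pA, 25 pA); steps are 600 ms at 10 kHz.
    """
    currents = {"fine": FINE_STEP_CURRENTS, "coarse": COARSE_STEP_CURRENTS}.get(protocol)
    if currents is None:
        raise ValueError("protocol must be 'fine' or 'coarse'")
    rng = np.random.default_rng(seed)
    sweeps, truths = [], {}
    for c in currents:
        sweep, t = sim_step_sweep(spec, float(c), rng, fs=fs)
        sweeps.append(sweep)
        truths[float(c)] = t
    meta = ProtocolMetadata(
        protocol_kind="current_steps_cc",
        step_currents=tuple(float(c) for c in currents),
        step_duration=0.6,
        step_onset=0.2,
    )
    sset = SweepSet(sweeps=sweeps, protocol=meta)
    return sset, _ground_truth_vector(spec, truths, fs)


def _ground_truth_vector(
    spec: SimNeuronSpec, truths: dict, fs: float
) -> MembranePropertyVector:
    """Ground truth at realized (sample-grid) values where applicable."""
    vec = MembranePropertyVector(
        membrane_resistance=spec.r_m,
        membrane_decay_tau=spec.tau_m,
        sag=spec.sag_fraction,
        rebound_spikes=float(spec.rebound_count),
        ap_threshold=spec.ap_threshold,
        ap_amplitude=spec.ap_amplitude,
        delta_ahp=spec.delta_ahp,
        ahp_magnitude=spec.ahp_magnitude,
        ahp_latency=spec.ahp_latency,
    )
    rheo = min(
        (c for c, t in truths.items() if len(t["spike_times"])), default=None
    )
    if rheo is None:
        return vec
    spiking = sorted(c for c in truths if len(truths[c].get("spike_times", [])))
    # realized max rate at the penultimate coarse step (the top one attenuates)
    peak_current = spiking[-1]
    if peak_current >= COARSE_STEP_CURRENTS[-1] and len(spiking) > 1:
        peak_current = spiking[-2]
    isi1 = truths[peak_current]["isis"][0]
    vec.max_firing_rate = 1.0 / isi1
    vec.latency_first_ap = (truths[rheo]["spike_times"][0] - 0.2) * 1e3
    wf = truths[rheo]["waveforms"]
    vec.ap_halfwidth = wf["hws"][0]
    plus50 = rheo + 50.0
    if plus50 in truths and len(truths[plus50]["spike_times"]) >= 4:
        isis = np.diff(truths[plus50]["spike_times"])
        vec.fr_adaptation = float(isis[0] / np.mean(isis[-2:]))
        w = truths[plus50]["waveforms"]
        vec.ap_broadening = float(w["hws"][1] / w["hws"][0])
        vec.ap_amplitude_adaptation = float(np.mean(w["amps"][-3:]) / w["amps"][0])
        vec.delta_ahp = float(w["ahps"][-1] - w["ahps"][0])
    return vec


# ---------------------------------------------------------------------------
# Evoked and spontaneous voltage-clamp sweeps
# ---------------------------------------------------------------------------


def sim_evoked(
    spec: SimEvokedSpec, seed: int = 0, fs: float = 10_000.0
) -> tuple[SweepSet, pd.DataFrame]:
    """Bernoulli success/failure evoked sweeps with fixed all-or-none amplitude.

    Each sweep is Gaussian noise with a stimulus artifact; with probability
    ``success_prob`` a PSC of fixed amplitude starts at artifact end +
    N(latency, jitter_sd²).  Returns the SweepSet and a per-sweep truth
    table (success, onset, latency_ms).
    """
    if spec.n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(round(spec.sweep_s * fs))
    kernel = psc_kernel(fs, spec.rise, spec.tau_decay)
    if kernel.size >= n:
        raise ValueError("kernel longer than sweep")
    art_start = spec.stim_time
    art_end = spec.stim_time + spec.artifact_ms * 1e-3
    rows, sweeps = [], []
    for i in range(spec.n_sweeps):
        y = rng.normal(0.0, spec.noise_sd, size=n)
        # biphasic stimulus artifact inside the annotated window
        a0 = int(round(art_start * fs))
        y[a0 : a0 + 5] += np.array([120.0, -80.0, 40.0, -20.0, 10.0])
        success = bool(rng.random() < spec.success_prob)
        lat = math.nan
        onset = math.nan
        if success:
            lat = spec.latency + rng.normal(0.0, spec.jitter_sd)
            onset = art_end + lat * 1e-3
            i0 = int(round(onset * fs))
            m = min(kernel.size, n - i0)
            y[i0 : i0 + m] += spec.u_amp * kernel[:m]
        rows.append({"sweep": i, "success": success, "onset": onset,
                     "latency_ms": lat, "amplitude": spec.u_amp if success else 0.0})
        sweeps.append(
            Sweep(
                samples=y,
                sampling_rate=fs,
                signal_kind=CURRENT,
                stimulus_times=[art_start],
                artifact_windows=[(art_start, art_end)],
                holding=-70.0,
            )
        )
    meta = ProtocolMetadata(
        protocol_kind="evoked_vc",
        stim_count=1,
        stimulation_charge=spec.stimulation_charge,
    )
    return SweepSet(sweeps=sweeps, protocol=meta), pd.DataFrame(rows)


def sim_spontaneous(
    spec: SimSpontSpec, seed: int = 0, fs: float = 10_000.0
) -> tuple[Sweep, pd.DataFrame]:
    """Poisson PSC train on Gaussian noise with lognormal amplitudes."""
    if spec.duration < 1.0:
        raise ValueError("duration must be >= 1 s")
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * fs))
    y = rng.normal(0.0, spec.noise_sd, size=n)
    kernel = psc_kernel(fs, spec.rise, spec.tau)
    times, amps = [], []
    if spec.rate > 0:
        t = rng.exponential(1.0 / spec.rate)
        while t < spec.duration - kernel.size / fs:
            amp = spec.amp_median * math.exp(spec.amp_shape * rng.standard_normal())
            i0 = int(round(t * fs))
            y[i0 : i0 + kernel.size] -= amp * kernel
            times.append(t)
            amps.append(amp)
            t += rng.exponential(1.0 / spec.rate)
    sweep = Sweep(
        samples=y, sampling_rate=fs, signal_kind=CURRENT, holding=-70.0
    )
    peak_offset = int(np.argmax(psc_kernel(fs, spec.rise, spec.tau))) / fs
    truth = pd.DataFrame(
        {"onset": times, "peak_time": np.asarray(times) + peak_offset, "amplitude": amps}
    )
    return sweep, truth


# ---------------------------------------------------------------------------
# Feature tables and cohorts
# ---------------------------------------------------------------------------

#: baseline (mean, sd) per property for the synthetic feature table;
#: non-canonical — the study's population means are not printed in the text.
FEATURE_BASELINES: dict[str, tuple[float, float]] = {
    "membrane_resistance": (250.0, 80.0),
    "membrane_decay_tau": (18.0, 5.0),
    "sag": (15.0, 6.0),
    "rebound_spikes": (1.0, 1.0),
    "max_firing_rate": (120.0, 40.0),
    "ap_threshold": (-40.0, 3.0),
    "ap_amplitude": (65.0, 8.0),
    "ap_halfwidth": (0.8, 0.2),
    "ahp_magnitude": (-12.0, 3.0),
    "ahp_latency": (8.0, 3.0),
    "delta_ahp": (0.0, 1.0),
    "latency_first_ap": (100.0, 40.0),
    "fr_adaptation": (0.8, 0.15),
    "ap_broadening": (1.15, 0.1),
    "ap_amplitude_adaptation": (0.85, 0.1),
}

#: class-contrast direction for the salient trio (FS relative to nFS)
SALIENT_FEATURES = {"max_firing_rate": +1.0, "sag": -1.0, "ap_halfwidth": -1.0}
MINOR_FEATURES = {"membrane_decay_tau": -1.0, "ahp_latency": -1.0}


def sim_feature_table(
    n_per_class: tuple[int, int] = (60, 45),
    separation_sd: float = 4.0,
    seed: int = 0,
    minor_separation_sd: float = 1.0,
):
    """Two-class 15-property Gaussian table (default 60 FS / 45 nFS rows).

    Class mean differences of ``separation_sd`` standard deviations are
    planted on max_firing_rate, sag and ap_halfwidth, plus
    ``minor_separation_sd`` on a minor feature set.
    """
    from clampkit.classify import FeatureTable

    if separation_sd < 0:
        raise ValueError("separation_sd must be >= 0")
    n_fs, n_nfs = n_per_class
    if min(n_fs, n_nfs) < 2:
        raise ValueError("need at least 2 neurons per class")
    rng = np.random.default_rng(seed)
    labels = np.array([FS_LABEL] * n_fs + [NFS_LABEL] * n_nfs)
    cols = {}
    for name in PROPERTY_NAMES:
        mean, sd = FEATURE_BASELINES[name]
        x = rng.normal(mean, sd, size=n_fs + n_nfs)
        direction = SALIENT_FEATURES.get(name)
        sep = separation_sd
        if direction is None:
            direction = MINOR_FEATURES.get(name)
            sep = minor_separation_sd
        if direction is not None:
            shift = direction * sep * sd / 2.0
            x[:n_fs] += shift
            x[n_fs:] -= shift
        cols[name] = x
    table = FeatureTable(pd.DataFrame(cols), labels=labels)
    return table, labels


def random_neuron_spec(
    class_label: str, rng: np.random.Generator, noise_sd: float = 0.1
) -> SimNeuronSpec:
    """Draw a neuron spec from the (non-canonical) class-default ranges."""
    u = rng.uniform
    if class_label == FS_LABEL:
        return SimNeuronSpec(
            class_label=FS_LABEL,
            r_m=u(150, 300),
            tau_m=u(8, 15),
            rheobase=float(rng.choice(np.arange(100, 251, 25))),
            max_rate=u(150, 280),
            sag_fraction=u(2, 8),
            rebound_count=0,
            ap_threshold=u(-42, -38),
            ap_amplitude=u(55, 75),
            ap_halfwidth=u(0.35, 0.6),
            ahp_magnitude=u(-18, -10),
            ahp_latency=u(4, 9),
            fr_adaptation=u(0.8, 1.0),
            ap_broadening=u(1.0, 1.1),
            ap_amplitude_adaptation=u(0.9, 1.0),
            delta_ahp=u(-2, 0),
            latency_first_ap=u(20, 60),
            noise_sd=noise_sd,
        )
    if class_label == NFS_LABEL:
        return SimNeuronSpec(
            class_label=NFS_LABEL,
            r_m=u(200, 400),
            tau_m=u(15, 25),
            rheobase=float(rng.choice(np.arange(50, 151, 25))),
            max_rate=u(40, 100),
            sag_fraction=u(15, 35),
            rebound_count=int(rng.integers(1, 4)),
            ap_threshold=u(-42, -38),
            ap_amplitude=u(55, 70),
            ahp_magnitude=u(-15, -5),
            ap_halfwidth=u(0.7, 1.2),
            ahp_latency=u(9, 14),
            fr_adaptation=u(0.45, 0.75),
            ap_broadening=u(1.1, 1.35),
            ap_amplitude_adaptation=u(0.7, 0.9),
            delta_ahp=u(0, 3),
            latency_first_ap=u(60, 150),
            noise_sd=noise_sd,
        )
    raise ValueError(f"unknown class {class_label!r}")


def sim_cohort(
    n_fs: int,
    n_nfs: int,
    seed: int = 0,
    noise_sd: float = 0.1,
) -> list[dict]:
    """Simulate a cohort: per neuron, both step series plus ground truth."""
    rng = np.random.default_rng(seed)
    cohort = []
    for k in range(n_fs + n_nfs):
        label = FS_LABEL if k < n_fs else NFS_LABEL
        spec = random_neuron_spec(label, rng, noise_sd=noise_sd)
        sub_seed = int(rng.integers(2**31))
        fine, _ = sim_step_protocol(spec, "fine", seed=sub_seed)
        coarse, truth = sim_step_protocol(spec, "coarse", seed=sub_seed + 1)
        cell_id = f"sim_{label}_{k:03d}"
        for sset in (fine, coarse):
            sset.cell_id = cell_id
        cohort.append(
            {
                "cell_id": cell_id,
                "class_label": label,
                "spec": spec,
                "fine": fine,
                "coarse": coarse,
                "truth": truth,
            }
        )
    return cohort
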