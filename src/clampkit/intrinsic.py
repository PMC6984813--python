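"""Action-potential extraction and intrinsic membrane properties.

All measures derive from two series of 600 ms square current steps
(−100→+100 pA at 10 pA intervals; −200→+400 pA at 25 pA intervals):

* AP threshold at the first 20 V/s upward crossing of dV/dt, amplitude,
  halfwidth, AHP magnitude/latency — at rheobase;
* max firing rate, latency to first AP, firing-rate adaptation, AP
  broadening, amplitude adaptation, ΔAHP — from the coarse series;
* membrane resistance (I–V slope below rheobase), membrane decay τ, sag,
  rebound spikes — passive measures.

The roster of 15 properties lives in :data:`PROPERTY_NAMES`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

import pandas as pd

from clampkit.core import Sweep, SweepSet, align_average, dvdt

AP_DVDT_THRESHOLD = 20.0  # V/s
AHP_WINDOW_S = 0.1
ATTENUATION_AMPLITUDE_MV = 40.0

PROPERTY_NAMES = (
    "membrane_resistance",
    "membrane_decay_tau",
    "sag",
    "rebound_spikes",
    "max_firing_rate",
    "ap_threshold",
    "ap_amplitude",
    "ap_halfwidth",
    "ahp_magnitude",
    "ahp_latency",
    "delta_ahp",
    "latency_first_ap",
    "fr_adaptation",
    "ap_broadening",
    "ap_amplitude_adaptation",
)


@dataclass
class ApEvent:
    """One action potential with threshold, peak, halfwidth and AHP."""

    threshold_t: float  # s
    threshold_v: float  # mV
    peak_t: float  # s
    peak_v: float  # mV
    halfwidth: float = math.nan  # ms
    ahp_magnitude: float = math.nan  # mV, trough - threshold (<= 0)
    ahp_latency: float = math.nan  # ms, threshold to trough
    ahp_truncated: bool = False

    @property
    def amplitude(self) -> float:
        return self.peak_v - self.threshold_v


@dataclass
class PhasePlot:
    """dV/dt (V/s) against V (mV) for the mean rheobase AP."""

    v: np.ndarray
    dvdt: np.ndarray

    def __post_init__(self) -> None:
        if len(self.v) != len(self.dvdt):
            raise ValueError("v and dvdt must have equal length")


@dataclass
class StimulusResponse:
    aps_per_stimulus: float
    v_rest: float  # mV
    subthreshold_epsp_amplitudes: list[float] = field(default_factory=list)


@dataclass
class DrugTimecourse:
    binned_vm: np.ndarray  # mV, 30 s bins
    delta_vm: float  # mV, last-3-min mean minus 3-min baseline mean
    bin_s: float = 30.0


@dataclass
class MembranePropertyVector:
    """The 15 per-neuron intrinsic membrane properties.

    Missing values are NaN (never silently imputed); ``provenance`` maps
    property names to the sweep indices they came from.
    """

    membrane_resistance: float = math.nan  # MOhm
    membrane_decay_tau: float = math.nan  # ms
    sag: float = math.nan  # %
    rebound_spikes: float = math.nan  # count
    max_firing_rate: float = math.nan  # Hz
    ap_threshold: float = math.nan  # mV
    ap_amplitude: float = math.nan  # mV
    ap_halfwidth: float = math.nan  # ms
    ahp_magnitude: float = math.nan  # mV
    ahp_latency: float = math.nan  # ms
    delta_ahp: float = math.nan  # mV
    latency_first_ap: float = math.nan  # ms
    fr_adaptation: float = math.nan  # ratio
    ap_broadening: float = math.nan  # ratio
    ap_amplitude_adaptation: float = math.nan  # ratio
    provenance: dict = field(default_factory=dict, compare=False)

    def to_series(self) -> pd.Series:
        return pd.Series({n: getattr(self, n) for n in PROPERTY_NAMES})

    @property
    def missing(self) -> tuple[str, ...]:
        return tuple(n for n in PROPERTY_NAMES if math.isnan(getattr(self, n)))


assert tuple(f.name for f in fields(MembranePropertyVector))[:15] == PROPERTY_NAMES


# ---------------------------------------------------------------------------
# AP detection
# ---------------------------------------------------------------------------


def detect_aps(
    sweep: Sweep, min_amplitude: float = 1.0, ahp_bound_t: float | None = None
) -> list[ApEvent]:
    """Segment APs at upward 20 V/s crossings of dV/dt.

    The crossing is linearly interpolated between samples; the peak is the
    voltage maximum before dV/dt returns below zero.  The AHP trough is
    searched within 100 ms of threshold, bounded by the next AP's threshold
    and, for APs before ``ahp_bound_t`` (e.g. the step offset), by that time.
    """
    if sweep.signal_kind != "voltage":
        raise ValueError("AP detection requires a voltage sweep")
    v, fs = sweep.samples, sweep.sampling_rate
    d = dvdt(v, fs)
    above = d >= AP_DVDT_THRESHOLD
    crossings = np.nonzero(~above[:-1] & above[1:])[0] + 1

    events: list[ApEvent] = []
    last_peak = -1
    for i in crossings:
        if i <= last_peak:
            continue
        frac = (
            (AP_DVDT_THRESHOLD - d[i - 1]) / (d[i] - d[i - 1])
            if d[i] != d[i - 1]
            else 0.0
        )
        thr_t = (i - 1 + frac) / fs
        thr_v = v[i - 1] + frac * (v[i] - v[i - 1])
        # peak: local max before dv/dt turns negative (within 10 ms)
        stop = min(v.size, i + int(0.01 * fs))
        neg = np.nonzero(d[i:stop] < 0)[0]
        p_end = i + (neg[0] + 1 if neg.size else stop - i)
        p = i + int(np.argmax(v[i:p_end]))
        if v[p] - thr_v < min_amplitude:
            continue
        events.append(
            ApEvent(threshold_t=thr_t, threshold_v=thr_v, peak_t=p / fs, peak_v=v[p])
        )
        last_peak = p

    for k, ap in enumerate(events):
        nxt = events[k + 1].threshold_t if k + 1 < len(events) else None
        if ahp_bound_t is not None and ap.threshold_t < ahp_bound_t:
            nxt = ahp_bound_t if nxt is None else min(nxt, ahp_bound_t)
        _fill_waveform_features(ap, v, fs, next_threshold_t=nxt)
    return events


def _fill_waveform_features(
    ap: ApEvent, v: np.ndarray, fs: float, next_threshold_t: float | None
) -> None:
    p = int(round(ap.peak_t * fs))
    half = ap.threshold_v + ap.amplitude / 2.0
    # upslope half-amplitude crossing
    i0 = max(0, int(ap.threshold_t * fs) - 1)
    t_up = _upcross(v, i0, p, half, fs)
    # downslope crossing
    stop = min(v.size - 1, p + int(0.01 * fs))
    t_down = _downcross(v, p, stop, half, fs)
    if t_up is not None and t_down is not None:
        ap.halfwidth = (t_down - t_up) * 1e3

    end_t = ap.threshold_t + AHP_WINDOW_S
    if next_threshold_t is not None:
        end_t = min(end_t, next_threshold_t)
    end = int(end_t * fs)
    ap.ahp_truncated = end >= v.size
    end = min(end, v.size)
    if end > p + 1:
        seg = v[p + 1 : end]
        trough = p + 1 + int(np.argmin(seg))
        ap.ahp_magnitude = min(0.0, float(v[trough] - ap.threshold_v))
        ap.ahp_latency = (trough / fs - ap.threshold_t) * 1e3


def _upcross(v, lo, hi, level, fs):
    seg = v[lo : hi + 1]
    below = np.nonzero(seg < level)[0]
    if below.size == 0 or below[-1] + 1 >= seg.size:
        return None
    i = below[-1]
    frac = (level - seg[i]) / (seg[i + 1] - seg[i]) if seg[i + 1] != seg[i] else 0.0
    return (lo + i + frac) / fs


def _downcross(v, lo, hi, level, fs):
    seg = v[lo : hi + 1]
    below = np.nonzero(seg < level)[0]
    if below.size == 0:
        return None
    i = below[0]
    if i == 0:
        return lo / fs
    frac = (seg[i - 1] - level) / (seg[i - 1] - seg[i]) if seg[i - 1] != seg[i] else 0.0
    return (lo + i - 1 + frac) / fs


def phase_plot(sweep: Sweep, aps: Sequence[ApEvent], pre_ms=2.0, post_ms=5.0) -> PhasePlot:
    """Phase plot (dV/dt vs V) of the cell's mean AP, aligned by threshold."""
    if not aps:
        raise ValueError("no APs")
    fs = sweep.sampling_rate
    segs = []
    for ap in aps:
        lo = int((ap.threshold_t - pre_ms * 1e-3) * fs)
        hi = int((ap.threshold_t + post_ms * 1e-3) * fs)
        if lo < 0 or hi > sweep.n_samples:
            continue
        segs.append(sweep.samples[lo:hi])
    mean_ap = align_average(segs, mode="ap_threshold", sampling_rate=fs)
    return PhasePlot(v=mean_ap, dvdt=dvdt(mean_ap, fs))


# ---------------------------------------------------------------------------
# Step-series helpers
# ---------------------------------------------------------------------------


def _step_window(sweepset: SweepSet) -> tuple[float, float]:
    onset = sweepset.protocol.step_onset
    return onset, onset + sweepset.protocol.step_duration


def _aps_by_sweep(sweepset: SweepSet) -> list[list[ApEvent]]:
    onset, offset = _step_window(sweepset)
    out = []
    for sweep in sweepset:
        aps = [
            a
            for a in detect_aps(sweep, ahp_bound_t=offset)
            if onset <= a.peak_t < offset
        ]
        out.append(aps)
    return out


def rheobase_index(
    sweepset: SweepSet, aps_by_sweep: list[list[ApEvent]] | None = None
) -> int | None:
    """Index of the lowest-current step with at least one AP, else None."""
    aps_by_sweep = aps_by_sweep if aps_by_sweep is not None else _aps_by_sweep(sweepset)
    currents = [s.step_current for s in sweepset]
    order = np.argsort(currents)
    for i in order:
        if aps_by_sweep[i]:
            return int(i)
    return None


def passive_features(
    fine: SweepSet, coarse: SweepSet | None = None
) -> dict[str, float]:
    """Membrane resistance, decay τ, sag and rebound spikes.

    R_m is the least-squares slope of the I–V plot over the fine-series
    (10 pA interval) steps below rheobase; ΔV per step is the 50–150 ms
    post-onset mean minus the 100 ms pre-onset mean.  Decay τ comes from a
    single-exponential fit to the −100 pA response.  Sag and rebound use
    the −200 pA step of the coarse series.
    """
    out = {
        "membrane_resistance": math.nan,
        "membrane_decay_tau": math.nan,
        "sag": math.nan,
        "rebound_spikes": math.nan,
    }
    onset, offset = _step_window(fine)
    aps = _aps_by_sweep(fine)
    rheo = rheobase_index(fine, aps)
    rheo_current = fine[rheo].step_current if rheo is not None else math.inf

    currents, deltas = [], []
    for sweep, sweep_aps in zip(fine, aps):
        i_inj = sweep.step_current
        if i_inj is None or i_inj >= rheo_current or sweep_aps:
            continue
        v = sweep.samples
        bl = np.mean(v[sweep.window_slice(onset - 0.1, onset)])
        resp = np.mean(v[sweep.window_slice(onset + 0.05, onset + 0.15)])
        currents.append(i_inj)
        deltas.append(resp - bl)
    if len(currents) >= 2:
        slope = np.polyfit(currents, deltas, 1)[0]  # mV / pA = GOhm
        out["membrane_resistance"] = float(slope * 1e3)  # MOhm

    m100 = _sweep_at(fine, -100.0)
    if m100 is not None:
        out["membrane_decay_tau"] = _charging_tau(m100, onset)

    sag_set = coarse if coarse is not None else fine
    s_onset, s_offset = _step_window(sag_set)
    m200 = _sweep_at(sag_set, -200.0)
    if m200 is not None:
        v = m200.samples
        v_bl = np.mean(v[m200.window_slice(s_onset - 0.1, s_onset)])
        step = v[m200.window_slice(s_onset, s_offset)]
        v_min = float(np.min(step))
        v_ss = np.mean(v[m200.window_slice(s_offset - 0.2, s_offset)])
        if not np.isclose(v_min, v_bl):
            out["sag"] = float((v_min - v_ss) / (v_min - v_bl) * 100.0)
        rebound = [
            a
            for a in detect_aps(m200)
            if s_offset <= a.peak_t < s_offset + 0.5
        ]
        out["rebound_spikes"] = float(len(rebound))
    return out


def _sweep_at(sweepset: SweepSet, current: float) -> Sweep | None:
    for sweep in sweepset:
        if sweep.step_current is not None and np.isclose(sweep.step_current, current):
            return sweep
    return None


def _charging_tau(sweep: Sweep, onset: float, fit_s: float = 0.3) -> float:
    """τ (ms) of V(t) = V_ss + A·e^(−t/τ) from step onset."""
    fs = sweep.sampling_rate
    sl = sweep.window_slice(onset, onset + fit_s)
    y = sweep.samples[sl]
    t = np.arange(y.size) / fs * 1e3  # ms
    a0 = y[0] - y[-1]
    tau0 = max(1.0, t[-1] / 10)

    def model(tt, v_ss, a, tau):
        return v_ss + a * np.exp(-tt / tau)

    try:
        p, _ = curve_fit(
            model, t, y, p0=[y[-1], a0, tau0],
            bounds=([-np.inf, -np.inf, 1e-3], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError:
        return math.nan
    return float(p[2])


def train_features(
    coarse: SweepSet, max_fr_isi: str = "min"
) -> dict[str, float]:
    """Firing-train measures from the 25 pA-interval series.

    Max firing rate is the inverse of the (minimum, by default) ISI in the
    first 200 ms of the most depolarizing step before attenuation of AP
    firing; attenuation is the first step whose AP count drops below the
    previous step's or where any AP amplitude falls below 40 mV.  Latency
    to first AP is measured at rheobase; the adaptation measures (FR
    adaptation, broadening, amplitude adaptation, ΔAHP) at rheobase+50 pA.
    ISIs are peak-to-peak.
    """
    out = {
        "max_firing_rate": math.nan,
        "latency_first_ap": math.nan,
        "fr_adaptation": math.nan,
        "delta_ahp": math.nan,
        "ap_broadening": math.nan,
        "ap_amplitude_adaptation": math.nan,
        "ap_threshold": math.nan,
        "ap_amplitude": math.nan,
        "ap_halfwidth": math.nan,
        "ahp_magnitude": math.nan,
        "ahp_latency": math.nan,
    }
    onset, _ = _step_window(coarse)
    aps = _aps_by_sweep(coarse)
    rheo = rheobase_index(coarse, aps)
    if rheo is None:
        return out
    rheo_current = coarse[rheo].step_current

    # rheobase AP waveform measures (first AP of the rheobase sweep)
    first = aps[rheo][0]
    out["ap_threshold"] = first.threshold_v
    out["ap_amplitude"] = first.amplitude
    out["ap_halfwidth"] = first.halfwidth
    out["ahp_magnitude"] = first.ahp_magnitude
    out["ahp_latency"] = first.ahp_latency
    out["latency_first_ap"] = (first.peak_t - onset) * 1e3

    # max firing rate: scan depolarizing steps in current order
    order = [
        i
        for i in np.argsort([s.step_current for s in coarse])
        if coarse[i].step_current >= rheo_current
    ]
    chosen = order[0]
    prev_count = len(aps[order[0]])
    for i in order[1:]:
        count = len(aps[i])
        attenuated = count < prev_count or any(
            a.amplitude < ATTENUATION_AMPLITUDE_MV for a in aps[i]
        )
        if attenuated:
            break
        chosen = i
        prev_count = count
    early = [a.peak_t for a in aps[chosen] if a.peak_t < onset + 0.2]
    if len(early) >= 2:
        isis = np.diff(sorted(early))
        isi = np.min(isis) if max_fr_isi == "min" else np.mean(isis)
        out["max_firing_rate"] = float(1.0 / isi)

    # adaptation measures at rheobase + 50 pA
    plus50 = _sweep_index_at(coarse, rheo_current + 50.0)
    if plus50 is not None:
        train = aps[plus50]
        if len(train) >= 3:
            isis = np.diff([a.peak_t for a in train])
            out["fr_adaptation"] = float(isis[0] / np.mean(isis[-2:]))
            amps = [a.amplitude for a in train]
            out["ap_amplitude_adaptation"] = float(np.mean(amps[-3:]) / amps[0])
            out["delta_ahp"] = float(
                train[-1].ahp_magnitude - train[0].ahp_magnitude
            )
            if train[0].halfwidth > 0 and train[1].halfwidth > 0:
                out["ap_broadening"] = float(train[1].halfwidth / train[0].halfwidth)
    return out


def _sweep_index_at(sweepset: SweepSet, current: float) -> int | None:
    for i, sweep in enumerate(sweepset):
        if sweep.step_current is not None and np.isclose(sweep.step_current, current):
            return i
    return None


# ---------------------------------------------------------------------------
# Stimulus-response and drug-timecourse measures
# ---------------------------------------------------------------------------


def stimulus_response_features(
    sweepset: SweepSet,
    ap_window_s: float = 0.05,
    epsp_window_s: float = 0.04,
    artifact_ms: float = 2.0,
) -> StimulusResponse:
    """APs per stimulus, V_rest and subthreshold EPSP amplitudes.

    APs are counted within 50 ms of each stimulus; the subthreshold EPSP
    amplitude is the maximal non-artifact voltage deflection within 40 ms
    of a stimulus (stimuli with an AP in that window contribute no EPSP).
    V_rest is the mean of the 500 ms baseline before the first stimulus.
    """
    counts, epsps, v_rests = [], [], []
    for sweep in sweepset:
        if not sweep.stimulus_times:
            raise ValueError("stimulus metadata missing")
        aps = detect_aps(sweep)
        first = sweep.stimulus_times[0]
        v_rests.append(np.mean(sweep.samples[sweep.window_slice(max(0, first - 0.5), first)]))
        for stim in sweep.stimulus_times:
            n_aps = sum(stim <= a.peak_t < stim + ap_window_s for a in aps)
            counts.append(n_aps)
            if any(stim <= a.peak_t < stim + epsp_window_s for a in aps):
                continue
            art_end = stim + artifact_ms * 1e-3
            bl = np.mean(sweep.samples[sweep.window_slice(max(0, stim - 0.01), stim)])
            seg = sweep.samples[sweep.window_slice(art_end, stim + epsp_window_s)]
            if seg.size:
                epsps.append(float(np.max(seg) - bl))
    return StimulusResponse(
        aps_per_stimulus=float(np.mean(counts)),
        v_rest=float(np.mean(v_rests)),
        subthreshold_epsp_amplitudes=epsps,
    )


def drug_timecourse(
    vm: Sweep, drug_onset: float, baseline_s: float = 180.0, final_s: float = 180.0
) -> DrugTimecourse:
    """ΔV_m = mean of the last 3 min minus the 3 min pre-drug baseline."""
    if drug_onset < baseline_s:
        raise ValueError("need >= 3 min of baseline before drug onset")
    if vm.duration - drug_onset < 600.0:
        raise ValueError("need >= 10 min after drug onset")
    fs = vm.sampling_rate
    n_bin = int(round(30.0 * fs))
    n_full = vm.n_samples // n_bin
    binned = vm.samples[: n_full * n_bin].reshape(n_full, n_bin).mean(axis=1)
    base = np.mean(vm.samples[vm.window_slice(drug_onset - baseline_s, drug_onset)])
    last = np.mean(vm.samples[vm.window_slice(vm.duration - final_s, vm.duration)])
    return DrugTimecourse(binned_vm=binned, delta_vm=float(last - base))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_feature_vector(
    fine: SweepSet | None, coarse: SweepSet | None
) -> MembranePropertyVector:
    """Assemble the 15-property vector from the two step series.

    Properties whose source sweeps are missing stay NaN and are listed in
    ``vector.missing``; provenance records which series fed each property.
    """
    vec = MembranePropertyVector()
    if fine is not None:
        for name, value in passive_features(fine, coarse).items():
            setattr(vec, name, value)
            vec.provenance[name] = "fine_series" if name in (
                "membrane_resistance", "membrane_decay_tau"
            ) else "coarse_series"
    if coarse is not None:
        for name, value in train_features(coarse).items():
            setattr(vec, name, value)
            vec.provenance[name] = "coarse_series"
        if fine is None:
            # sag/rebound can come from the coarse series' -200 pA step
            for name, value in passive_features(coarse, coarse).items():
                if name in ("sag", "rebound_spikes") and not math.isnan(value):
                    setattr(vec, name, value)
                    vec.provenance[name] = "coarse_series"
    return vec
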