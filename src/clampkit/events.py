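"""Postsynaptic-current detection and kinetics.

Three detector families:

* evoked EPSC/IPSCs — median-peak-window procedure with a 6×MAD baseline
  threshold (EPSCs are negative deflections at V_hold = −70 mV, IPSCs
  positive at 0 mV);
* paired-recording unitary EPSCs — 6×MAD threshold within 3 ms of the
  presynaptic AP peak;
* spontaneous EPSCs — combined template + 5×MAD rolling-baseline threshold
  with a normalized charge-integral cutoff.

Plus the per-event kinetics measures (20–80% risetime, latency, jitter,
single/weighted-double exponential decay).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from clampkit.core import (
    Sweep,
    SweepSet,
    align_average,
    baseline_stats,
    savgol_smooth,
)

EPSC = -1  # negative deflections, V_hold = -70 mV
IPSC = +1  # positive deflections, V_hold = 0 mV

#: polarity-specific half-width of the evoked detection window (ms)
HALF_WIDTH_MS = {EPSC: 5.0, IPSC: 7.5}


@dataclass
class PscEvent:
    """One detected (or failed) postsynaptic current."""

    sweep_index: int
    success: bool
    amplitude: float  # pA, peak minus baseline mean (signed)
    peak_time: float  # s
    polarity: int = EPSC
    rise_20_80: float = math.nan  # ms
    latency: float = math.nan  # ms, reference to 20% rise
    tau_decay: float = math.nan  # ms

    def __post_init__(self) -> None:
        if self.polarity not in (EPSC, IPSC):
            raise ValueError("polarity must be EPSC (-1) or IPSC (+1)")
        if not math.isnan(self.rise_20_80) and self.rise_20_80 <= 0:
            raise ValueError("rise_20_80 must be > 0 when defined")


@dataclass(frozen=True)
class DetectionWindow:
    """Search window for evoked events, centered on the median peak time."""

    center: float  # s
    half_width_ms: float
    search_limit_ms: float = 20.0

    def bounds(self, artifact_end: float, duration: float) -> tuple[float, float]:
        lo = max(self.center - self.half_width_ms * 1e-3, artifact_end)
        hi = min(
            self.center + self.half_width_ms * 1e-3,
            artifact_end + self.search_limit_ms * 1e-3,
            duration,
        )
        return lo, hi


@dataclass
class CellEventSummary:
    """Per-cell evoked-event summary (successes only where noted)."""

    mean_amplitude: float
    success_rate: float  # %
    mean_latency: float = math.nan  # ms
    jitter: float = math.nan  # ms (SD of latencies)
    mean_rise: float = math.nan  # ms
    tau_decay: float = math.nan  # ms, from the mean trace
    ie_balance: float | None = None


@dataclass
class SepscTemplate:
    """Mean spontaneous-EPSC waveform, 20%-rise point through peak + τ."""

    waveform: np.ndarray  # baseline-subtracted, peak negative
    peak_index: int
    tau_ms: float
    source_fraction: float = 0.10

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform[self.peak_index] >= 0:
            raise ValueError("template peak must be negative")


# ---------------------------------------------------------------------------
# Evoked detection
# ---------------------------------------------------------------------------


def _artifact_end(sweep: Sweep, artifact_ms: float = 2.0) -> float:
    """End of the stimulus artifact (annotated window, else stim + width)."""
    if sweep.artifact_windows:
        return sweep.artifact_windows[0][1]
    if not sweep.stimulus_times:
        raise ValueError("sweep has no stimulus metadata")
    return sweep.stimulus_times[0] + artifact_ms * 1e-3


def _extremum(x: np.ndarray, sl: slice, polarity: int) -> int:
    seg = x[sl]
    if seg.size == 0:
        raise ValueError("empty search window")
    off = int(np.argmin(seg)) if polarity == EPSC else int(np.argmax(seg))
    return sl.start + off


def subsample_count(n_sweeps: int) -> int:
    """Sweeps to subsample for window selection: 25%, or 5 if fewer than 20."""
    if n_sweeps < 1:
        raise ValueError("no sweeps")
    return int(round(0.25 * n_sweeps)) if n_sweeps >= 20 else min(5, n_sweeps)


def select_event_window(
    sweepset: SweepSet,
    polarity: int = EPSC,
    rng: np.random.Generator | None = None,
    artifact_ms: float = 2.0,
    search_limit_ms: float = 20.0,
    half_width_ms: float | None = None,
) -> DetectionWindow:
    """Subsample sweeps and center the detection window on their median peak.

    25% of the sweeps are subsampled (5 sweeps if the experiment has < 20);
    in each, the maximal correct-polarity deflection within ``search_limit``
    after the artifact end locates a peak, and the window is centered at the
    median of those peak times with the polarity-specific half-width.
    """
    n = len(sweepset)
    k = subsample_count(n)
    rng = rng or np.random.default_rng()
    chosen = sorted(rng.choice(n, size=k, replace=False))
    peak_times = []
    for i in chosen:
        sweep = sweepset[i]
        end = _artifact_end(sweep, artifact_ms)
        sl = sweep.window_slice(end, end + search_limit_ms * 1e-3)
        p = _extremum(sweep.samples, sl, polarity)
        peak_times.append(p / sweep.sampling_rate)
    return DetectionWindow(
        center=float(np.median(peak_times)),
        half_width_ms=(
            half_width_ms if half_width_ms is not None else HALF_WIDTH_MS[polarity]
        ),
        search_limit_ms=search_limit_ms,
    )


def detect_evoked_psc(
    sweepset: SweepSet,
    window: DetectionWindow,
    polarity: int = EPSC,
    mad_multiplier: float = 6.0,
    baseline_s: float = 0.5,
    artifact_ms: float = 2.0,
    mad_scale: float = 1.0,
) -> tuple[list[PscEvent], CellEventSummary]:
    """Classify each sweep as success/failure and summarize the cell.

    A success is a correct-polarity deflection exceeding the mean baseline
    current (500 ms before stimulation) by more than ``mad_multiplier`` ×
    its raw MAD, inside the detection window.  Amplitude is peak minus
    baseline mean.  Failure amplitudes are the extremal correct-polarity
    deflection within ±5 ms of the cell's mean success-peak time; if every
    sweep fails, the cell amplitude falls back to the extremum of the mean
    trace within the post-artifact search limit.
    """
    events: list[PscEvent] = []
    baselines: list[float] = []
    for i, sweep in enumerate(sweepset):
        stim = sweep.stimulus_times[0] if sweep.stimulus_times else None
        if stim is None:
            raise ValueError("evoked detection requires stimulus metadata")
        bs = baseline_stats(sweep, (max(0.0, stim - baseline_s), stim), mad_scale)
        baselines.append(bs.mean)
        art_end = _artifact_end(sweep, artifact_ms)
        lo, hi = window.bounds(art_end, sweep.duration)
        if hi <= lo:
            raise ValueError("detection window extends past sweep end")
        p = _extremum(sweep.samples, sweep.window_slice(lo, hi), polarity)
        deflection = polarity * (sweep.samples[p] - bs.mean)
        success = deflection > mad_multiplier * bs.mad
        events.append(
            PscEvent(
                sweep_index=i,
                success=bool(success),
                amplitude=float(sweep.samples[p] - bs.mean),
                peak_time=p / sweep.sampling_rate,
                polarity=polarity,
            )
        )

    successes = [e for e in events if e.success]
    if successes:
        mean_peak_t = float(np.mean([e.peak_time for e in successes]))
        for e in events:
            if e.success:
                continue
            sweep = sweepset[e.sweep_index]
            sl = sweep.window_slice(mean_peak_t - 5e-3, mean_peak_t + 5e-3)
            p = _extremum(sweep.samples, sl, polarity)
            e.amplitude = float(sweep.samples[p] - baselines[e.sweep_index])
            e.peak_time = p / sweep.sampling_rate
        mean_amplitude = float(np.mean([e.amplitude for e in successes]))
    else:
        # all-failure fallback: extremum of the mean trace after the artifact
        ref = sweepset[0]
        art_end = _artifact_end(ref, artifact_ms)
        mean_trace = np.mean([s.samples for s in sweepset], axis=0)
        sl = ref.window_slice(art_end, art_end + window.search_limit_ms * 1e-3)
        p = _extremum(mean_trace, sl, polarity)
        mean_amplitude = float(mean_trace[p] - np.mean(baselines))

    refs = [
        _artifact_end(sweepset[e.sweep_index], artifact_ms) for e in events
    ]
    mean_lat, jitter, mean_rise = psc_kinetics(sweepset, events, refs, baselines)
    tau = math.nan
    if successes:
        tau = _mean_trace_tau(sweepset, successes, baselines, polarity)
    summary = CellEventSummary(
        mean_amplitude=mean_amplitude,
        success_rate=success_rate(events),
        mean_latency=mean_lat,
        jitter=jitter,
        mean_rise=mean_rise,
        tau_decay=tau,
    )
    return events, summary


def success_rate(events: Sequence[PscEvent]) -> float:
    """100 × n_successes / n_total."""
    if not events:
        raise ValueError("no events")
    return 100.0 * sum(e.success for e in events) / len(events)


def ie_balance(ipsc_amplitude: float, epsc_amplitude: float) -> float:
    """Ratio of IPSC to EPSC amplitude recorded in the same neuron."""
    return abs(ipsc_amplitude) / abs(epsc_amplitude)


def _rise_crossings(
    x: np.ndarray,
    peak: int,
    base: float,
    polarity: int,
    sampling_rate: float,
    search_back_s: float = 0.05,
) -> tuple[float, float] | None:
    """Times (s) of the 20% and 80% points on the rising phase, or None."""
    d = polarity * (x - base)
    amp = d[peak]
    if amp <= 0:
        return None
    lo = max(0, peak - int(round(search_back_s * sampling_rate)))
    t80 = _last_upcross(d, lo, peak, 0.8 * amp, sampling_rate)
    if t80 is None:
        return None
    t20 = _last_upcross(d, lo, int(t80 * sampling_rate) + 1, 0.2 * amp, sampling_rate)
    if t20 is None or t20 > t80:
        return None
    return t20, t80


def _last_upcross(
    d: np.ndarray, lo: int, hi: int, level: float, fs: float
) -> float | None:
    seg = d[lo : hi + 1]
    below = np.nonzero(seg < level)[0]
    if below.size == 0 or below[-1] + 1 >= seg.size:
        return None
    i = below[-1]
    y0, y1 = seg[i], seg[i + 1]
    frac = (level - y0) / (y1 - y0) if y1 != y0 else 0.0
    return (lo + i + frac) / fs


def psc_kinetics(
    sweepset: SweepSet,
    events: Sequence[PscEvent],
    reference_times: Sequence[float],
    baseline_means: Sequence[float],
) -> tuple[float, float, float]:
    """Fill per-event 20–80% risetime and latency; return cell statistics.

    Latency is the reference time (stimulus-artifact end, or presynaptic AP
    peak for paired recordings) to the 20% rise point.  The cell latency is
    the mean and the jitter the sample SD of the success latencies.  Events
    whose rising phase is not bracketed stay NaN.
    """
    lats, rises = [], []
    for e, ref in zip(events, reference_times):
        if not e.success:
            continue
        sweep = sweepset[e.sweep_index]
        peak = int(round(e.peak_time * sweep.sampling_rate))
        res = _rise_crossings(
            sweep.samples, peak, baseline_means[e.sweep_index], e.polarity,
            sweep.sampling_rate,
        )
        if res is None:
            continue
        t20, t80 = res
        e.rise_20_80 = (t80 - t20) * 1e3
        e.latency = (t20 - ref) * 1e3
        lats.append(e.latency)
        rises.append(e.rise_20_80)
    if not lats:
        return math.nan, math.nan, math.nan
    jitter = float(np.std(lats, ddof=1)) if len(lats) > 1 else 0.0
    return float(np.mean(lats)), jitter, float(np.mean(rises))


# ---------------------------------------------------------------------------
# Decay fitting
# ---------------------------------------------------------------------------


def weighted_tau(a1: float, tau1: float, a2: float, tau2: float) -> float:
    """τ_weighted = (τ1·A1 + τ2·A2) / (A1 + A2)."""
    return (tau1 * a1 + tau2 * a2) / (a1 + a2)


def fit_decay(
    decay: np.ndarray,
    sampling_rate: float,
    model: str = "single",
) -> float:
    """Fit the decay phase (peak onward, positive-deflection) and return τ in ms.

    ``model="single"``: f(t) = A·e^(−t/τ).  ``model="double_weighted"``:
    f(t) = A1·e^(−t/τ1) + A2·e^(−t/τ2) with τ_w = (τ1A1 + τ2A2)/(A1 + A2);
    initialized from the single fit with τ2 = 10·τ1 and an 80/20 amplitude
    split, bounded to τ > 0 and A ≥ 0.
    """
    y = np.asarray(decay, dtype=float)
    if y.size < 4 or y[0] <= 0:
        raise ValueError("decay segment must start at a positive peak")
    t = np.arange(y.size) / sampling_rate * 1e3  # ms

    a0 = y[0]
    below = np.nonzero(y < a0 / math.e)[0]
    tau0 = t[below[0]] if below.size else t[-1] / 2
    tau0 = max(tau0, t[1])

    def single(tt, a, tau):
        return a * np.exp(-tt / tau)

    p_single, _ = curve_fit(
        single, t, y, p0=[a0, tau0],
        bounds=([0, 1e-6], [np.inf, np.inf]), maxfev=10_000,
    )
    if model == "single":
        return float(p_single[1])
    if model != "double_weighted":
        raise ValueError(f"unknown decay model {model!r}")

    def double(tt, a1, tau1, a2, tau2):
        return a1 * np.exp(-tt / tau1) + a2 * np.exp(-tt / tau2)

    a, tau1 = p_single
    p, _ = curve_fit(
        double, t, y, p0=[0.8 * a, tau1, 0.2 * a, 10 * tau1],
        bounds=([0, 1e-6, 0, 1e-6], [np.inf, np.inf, np.inf, np.inf]),
        maxfev=20_000,
    )
    a1, t1, a2, t2 = p
    if a1 + a2 <= 0:
        raise RuntimeError("degenerate double-exponential fit")
    return float(weighted_tau(a1, t1, a2, t2))


def _mean_trace_tau(
    sweepset: SweepSet,
    successes: Sequence[PscEvent],
    baselines: Sequence[float],
    polarity: int,
    post_s: float = 0.1,
    pre_s: float = 0.005,
) -> float:
    """τ_decay from the aligned mean success trace (single exp for EPSCs,
    weighted double for IPSCs, per the cell-summary convention)."""
    fs = sweepset.sampling_rate
    segs = []
    for e in successes:
        sweep = sweepset[e.sweep_index]
        p = int(round(e.peak_time * fs))
        lo = max(0, p - int(pre_s * fs))
        hi = min(sweep.n_samples, p + int(post_s * fs))
        segs.append(polarity * (sweep.samples[lo:hi] - baselines[e.sweep_index]))
    mean_seg = align_average(segs, mode="max_rise", sampling_rate=fs)
    peak = int(np.argmax(mean_seg))
    decay = mean_seg[peak:]
    model = "single" if polarity == EPSC else "double_weighted"
    try:
        return fit_decay(decay, fs, model=model)
    except (ValueError, RuntimeError):
        return math.nan


# ---------------------------------------------------------------------------
# Paired-recording unitary EPSCs
# ---------------------------------------------------------------------------


def detect_paired_uepsc(
    in_sweep: Sweep,
    ap_peak_time: float,
    window_ms: float = 3.0,
    mad_multiplier: float = 6.0,
    baseline_s: float = 0.1,
    mad_scale: float = 1.0,
) -> PscEvent:
    """Detect a unitary EPSC within ``window_ms`` after the presynaptic AP peak.

    The baseline is the ``baseline_s`` of current ending 5 ms before the AP
    peak.  Latency is measured from the AP peak to the 20% rise point.
    """
    if not 0.0 <= ap_peak_time < in_sweep.duration:
        raise ValueError("AP peak time outside sweep")
    b_end = max(1e-3, ap_peak_time - 5e-3)
    bs = baseline_stats(in_sweep, (max(0.0, b_end - baseline_s), b_end), mad_scale)
    sl = in_sweep.window_slice(ap_peak_time, ap_peak_time + window_ms * 1e-3)
    p = _extremum(in_sweep.samples, sl, EPSC)
    deflection = bs.mean - in_sweep.samples[p]
    event = PscEvent(
        sweep_index=0,
        success=bool(deflection > mad_multiplier * bs.mad),
        amplitude=float(in_sweep.samples[p] - bs.mean),
        peak_time=p / in_sweep.sampling_rate,
        polarity=EPSC,
    )
    if event.success:
        res = _rise_crossings(
            in_sweep.samples, p, bs.mean, EPSC, in_sweep.sampling_rate
        )
        if res is not None:
            t20, t80 = res
            event.rise_20_80 = (t80 - t20) * 1e3
            event.latency = (t20 - ap_peak_time) * 1e3
    return event


# ---------------------------------------------------------------------------
# Spontaneous EPSCs (combined template + threshold)
# ---------------------------------------------------------------------------


def _prior_window_stats(
    x: np.ndarray, i: int, n_base: int, assigned: np.ndarray
) -> tuple[float, float] | None:
    lo = i - n_base
    if lo < 0:
        return None
    seg = x[lo:i]
    keep = ~assigned[lo:i]
    if keep.sum() < n_base // 4:
        return None
    seg = seg[keep]
    med = np.median(seg)
    return float(np.mean(seg)), float(np.median(np.abs(seg - med)))


def _candidate_peaks(
    x: np.ndarray,
    fs: float,
    mad_multiplier: float,
    baseline_s: float,
    refractory_ms: float,
) -> np.ndarray:
    """Local negative peaks exceeding the rolling-baseline MAD threshold.

    A cheap global-MAD prefilter trims the local-minima pool before the
    exact per-candidate prior-window statistics are evaluated (the two-stage
    form is an optimization only; the accepted set is defined by the exact
    per-candidate test in the caller).
    """
    n_base = int(round(baseline_s * fs))
    c = np.concatenate([[0.0], np.cumsum(x)])
    m = np.full(x.size, np.nan)
    # prior-window mean: mean of x[i-n_base:i]
    m[n_base:] = (c[n_base:-1] - c[: x.size - n_base]) / n_base
    resid = x - m
    valid = ~np.isnan(m)
    gmad = np.median(np.abs(resid[valid] - np.median(resid[valid])))
    distance = max(1, int(round(refractory_ms * 1e-3 * fs)))
    peaks, _ = find_peaks(-x, distance=distance)
    peaks = peaks[peaks >= n_base]
    keep = resid[peaks] < -0.7 * mad_multiplier * gmad
    return peaks[keep]


def build_sepsc_template(
    trace: Sweep,
    rng: np.random.Generator | None = None,
    mad_multiplier: float = 5.0,
    baseline_s: float = 0.05,
    source_fraction: float = 0.10,
    refractory_ms: float = 2.0,
    pre_ms: float = 5.0,
    post_ms: float = 30.0,
    smooth: bool = True,
    decay_spans: float = 1.0,
) -> SepscTemplate:
    """Build the mean-event template for spontaneous-EPSC detection.

    10% of the local negative peaks exceeding 5×MAD of the 50 ms-prior
    rolling baseline are subsampled, aligned at their point of maximal
    rise and averaged; the mean waveform is truncated from its 20% rise
    point through ``decay_spans``·τ after the peak (τ from a single-
    exponential fit to the mean decay).
    """
    sweep = savgol_smooth(trace) if smooth else trace
    x, fs = sweep.samples, sweep.sampling_rate
    rng = rng or np.random.default_rng()
    n_base = int(round(baseline_s * fs))
    assigned = np.zeros(x.size, dtype=bool)

    raw = []
    for p in _candidate_peaks(x, fs, mad_multiplier, baseline_s, refractory_ms):
        stats = _prior_window_stats(x, p, n_base, assigned)
        if stats is None:
            continue
        mean, mad = stats
        if mean - x[p] > mad_multiplier * mad:
            raw.append((p, mean, mean - x[p]))
    # keep only locally dominant peaks: a candidate on the decay tail of a
    # larger event within 10 ms would otherwise contaminate the template
    dom = int(round(10e-3 * fs))
    candidates = [
        (p, mean)
        for i, (p, mean, d) in enumerate(raw)
        if not any(
            abs(q - p) <= dom and dq > d for q, _, dq in raw[max(0, i - 5) : i + 6]
        )
    ]
    if len(candidates) < 10:
        raise ValueError(
            f"only {len(candidates)} candidate peaks; need >= 10 for a template"
        )

    k = max(1, int(round(source_fraction * len(candidates))))
    chosen = rng.choice(len(candidates), size=k, replace=False)
    pre = int(round(pre_ms * 1e-3 * fs))
    post = int(round(post_ms * 1e-3 * fs))
    segs = []
    for j in chosen:
        p, mean = candidates[j]
        if p - pre < 0 or p + post > x.size:
            continue
        segs.append(x[p - pre : p + post] - mean)
    if not segs:
        raise ValueError("no usable candidate segments")
    # anchor search confined to just before the candidate peak so that
    # neighboring events inside a segment cannot hijack the alignment
    mean_seg = align_average(
        segs, mode="max_rise", sampling_rate=fs,
        anchor_window=(max(0, pre - int(2e-3 * fs)), pre + 2),
    )

    peak = int(np.argmin(mean_seg))
    res = _rise_crossings(mean_seg, peak, 0.0, EPSC, fs)
    start = int(math.floor(res[0] * fs)) if res is not None else max(0, peak - pre)
    tau_ms = fit_decay(-mean_seg[peak:], fs, model="single")
    stop = min(mean_seg.size, peak + int(round(decay_spans * tau_ms * 1e-3 * fs)) + 1)
    return SepscTemplate(
        waveform=mean_seg[start:stop],
        peak_index=peak - start,
        tau_ms=tau_ms,
        source_fraction=source_fraction,
    )


def detect_sepsc(
    trace: Sweep,
    template: SepscTemplate,
    nci_cutoff: float = 0.5,
    mad_multiplier: float = 5.0,
    baseline_s: float = 0.05,
    refractory_ms: float = 2.0,
    smooth: bool = True,
    scaling: str = "peak",
) -> list[PscEvent]:
    """Detect spontaneous EPSCs by combined template + threshold.

    Local negative peaks exceeding 5×MAD of the rolling 50 ms-prior
    baseline are candidates; the template is scaled to each candidate
    (``scaling="peak"``: matched at the peak deflection, the default;
    ``"lstsq"``: least-squares amplitude fit) and the candidate's
    rectified negative-going charge integral over the template support,
    normalized to the scaled template's, must reach ``nci_cutoff``.
    Amplitude is the peak minus the candidate's rolling baseline.
    Samples of accepted events are excluded from later candidates'
    baselines.
    """
    if template is None:
        raise ValueError("template required")
    sweep = savgol_smooth(trace) if smooth else trace
    x, fs = sweep.samples.copy(), sweep.sampling_rate
    n_base = int(round(baseline_s * fs))
    tw = template.waveform
    t_norm = float(np.dot(tw, tw))
    t_integral = float(np.sum(np.abs(tw)))
    t_peak = abs(float(tw[template.peak_index]))
    # template extended with its exponential tail, for subtracting accepted
    # events so their decay cannot re-trigger detection
    tau_n = template.tau_ms * 1e-3 * fs
    tail = tw[-1] * np.exp(-np.arange(1, int(round(5 * tau_n)) + 1) / tau_n)
    extended = np.concatenate([tw, tail])
    assigned = np.zeros(x.size, dtype=bool)
    events: list[PscEvent] = []

    for p in _candidate_peaks(x, fs, mad_multiplier, baseline_s, refractory_ms):
        stats = _prior_window_stats(x, p, n_base, assigned)
        if stats is None:
            continue
        mean, mad = stats
        if not (mean - x[p] > mad_multiplier * mad):
            continue
        lo = p - template.peak_index
        hi = lo + tw.size
        if lo < 0 or hi > x.size:
            continue
        seg = x[lo:hi] - mean
        if scaling == "peak":
            scale = (mean - x[p]) / t_peak
        elif scaling == "lstsq":
            scale = float(np.dot(seg, tw)) / t_norm
        else:
            raise ValueError(f"unknown scaling {scaling!r}")
        if scale <= 0:
            continue
        charge = float(np.sum(np.clip(-seg, 0.0, None)))
        nci = charge / (scale * t_integral)
        if nci < nci_cutoff:
            continue
        events.append(
            PscEvent(
                sweep_index=0,
                success=True,
                amplitude=float(x[p] - mean),
                peak_time=p / fs,
                polarity=EPSC,
            )
        )
        m = min(extended.size, x.size - lo)
        x[lo : lo + m] -= scale * extended[:m]
        assigned[lo:hi] = True
    return events


def sepsc_stats(events: Sequence[PscEvent]) -> tuple[float, float]:
    """Cell medians: (|amplitude| in pA, instantaneous frequency in Hz).

    Per-event frequency is the inverse of the interevent interval; the
    frequency is NaN with fewer than two events.
    """
    if not events:
        raise ValueError("no events")
    amps = np.abs([e.amplitude for e in events])
    med_amp = float(np.median(amps))
    if len(events) < 2:
        return med_amp, math.nan
    times = np.sort([e.peak_time for e in events])
    freqs = 1.0 / np.diff(times)
    return med_amp, float(np.median(freqs))
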