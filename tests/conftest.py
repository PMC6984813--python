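import numpy as np
import pytest

from clampkit.core import CURRENT, VOLTAGE, ProtocolMetadata, Sweep, SweepSet

FS = 10_000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_sweep(samples, kind=CURRENT, fs=FS, **kw):
    return Sweep(samples=np.asarray(samples, float), sampling_rate=fs,
                 signal_kind=kind, **kw)


def make_evoked_sweep(
    n_s=1.0,
    stim=0.6,
    event_amp=0.0,
    event_latency_ms=5.0,
    noise_sd=0.0,
    tau_ms=3.0,
    rise_ms=0.5,
    rng=None,
    fs=FS,
):
    """Voltage-clamp current sweep with an optional planted PSC."""
    n = int(n_s * fs)
    y = np.zeros(n) if rng is None else rng.normal(0.0, noise_sd, n)
    art_end = stim + 2e-3
    if event_amp != 0.0:
        i0 = int(round((art_end + event_latency_ms * 1e-3) * fs))
        t = np.arange(n - i0) / fs * 1e3
        k = np.exp(-t / tau_ms) - np.exp(-t / rise_ms)
        y[i0:] += event_amp * k / k.max()
    return make_sweep(
        y, stimulus_times=[stim], artifact_windows=[(stim, art_end)], holding=-70.0
    )


def make_evoked_set(sweeps):
    return SweepSet(
        sweeps=list(sweeps),
        protocol=ProtocolMetadata(protocol_kind="evoked_vc", stim_count=1),
    )


def make_step_sweepset(build_sweep, currents, onset=0.2, duration=0.6):
    """Current-clamp SweepSet from a per-current sweep builder callable."""
    sweeps = []
    for c in currents:
        s = build_sweep(float(c))
        s.step_current = float(c)
        sweeps.append(s)
    return SweepSet(
        sweeps=sweeps,
        protocol=ProtocolMetadata(
            protocol_kind="current_steps_cc",
            step_currents=tuple(float(c) for c in currents),
            step_duration=duration,
            step_onset=onset,
        ),
    )
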