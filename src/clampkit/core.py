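"""Neutral data model for patch-clamp sweeps plus shared signal primitives.

Units and conventions: current in pA, voltage in mV, time in seconds with
t = 0 at sweep start; all windows are half-open ``[start, end)``.  The
nominal sampling rate is 10 kHz.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import savgol_filter

CURRENT = "current"
VOLTAGE = "voltage"

#: The two square current-injection series (pA), 600 ms steps.
FINE_STEP_CURRENTS = tuple(range(-100, 101, 10))
COARSE_STEP_CURRENTS = tuple(range(-200, 401, 25))

PROTOCOL_KINDS = (
    "evoked_vc",
    "paired_vc",
    "spontaneous_vc",
    "current_steps_cc",
    "evoked_cc",
    "drug_timecourse_cc",
)


@dataclass
class ProtocolMetadata:
    """Acquisition-protocol description attached to a SweepSet."""

    protocol_kind: str
    step_currents: tuple[float, ...] = ()
    step_duration: float = 0.6
    step_onset: float = 0.2
    stim_frequency: float | None = None
    stim_count: int | None = None
    stimulation_charge: float | None = None  # nC

    def __post_init__(self) -> None:
        if self.protocol_kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol_kind {self.protocol_kind!r}")
        self.step_currents = tuple(float(c) for c in self.step_currents)

    def to_dict(self) -> dict:
        return {
            "protocol_kind": self.protocol_kind,
            "step_currents": list(self.step_currents),
            "step_duration": self.step_duration,
            "step_onset": self.step_onset,
            "stim_frequency": self.stim_frequency,
            "stim_count": self.stim_count,
            "stimulation_charge": self.stimulation_charge,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolMetadata":
        return cls(**d)


@dataclass
class Sweep:
    """One uniformly sampled trace (current in pA or voltage in mV)."""

    samples: np.ndarray
    sampling_rate: float = 10_000.0
    signal_kind: str = CURRENT
    t0: float = 0.0
    stimulus_times: list[float] = field(default_factory=list)
    artifact_windows: list[tuple[float, float]] = field(default_factory=list)
    holding: float | None = None
    step_current: float | None = None  # pA, for current-step sweeps

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if self.signal_kind not in (CURRENT, VOLTAGE):
            raise ValueError(f"signal_kind must be {CURRENT!r} or {VOLTAGE!r}")
        for start, end in self.artifact_windows:
            if not (0.0 <= start < end <= self.duration + 1e-12):
                raise ValueError(
                    f"artifact window ({start}, {end}) outside sweep span "
                    f"[0, {self.duration})"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def index_of(self, t: float) -> int:
        """Sample index of time ``t`` (floor; clipped to the sweep)."""
        return int(np.clip(np.floor(t * self.sampling_rate), 0, self.n_samples - 1))

    def window_slice(self, start: float, end: float) -> slice:
        """Index slice for the half-open time window ``[start, end)``."""
        i0 = max(0, int(np.ceil(start * self.sampling_rate - 1e-9)))
        i1 = min(self.n_samples, int(np.ceil(end * self.sampling_rate - 1e-9)))
        return slice(i0, i1)

    def with_samples(self, samples: np.ndarray) -> "Sweep":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class SweepSet:
    """Ordered collection of sweeps from one cell under one protocol."""

    sweeps: list[Sweep]
    protocol: ProtocolMetadata
    cell_id: str = "cell"
    animal_id: str = "animal"

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ValueError("SweepSet needs at least one sweep")
        rates = {s.sampling_rate for s in self.sweeps}
        kinds = {s.signal_kind for s in self.sweeps}
        if len(rates) != 1:
            raise ValueError("all sweeps must share a sampling rate")
        if len(kinds) != 1:
            raise ValueError("all sweeps must share a signal kind")
        expected = _expected_signal_kind(self.protocol.protocol_kind)
        if expected is not None and kinds != {expected}:
            raise ValueError(
                f"protocol {self.protocol.protocol_kind!r} expects "
                f"{expected} sweeps, got {kinds.pop()}"
            )

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    def __getitem__(self, i: int) -> Sweep:
        return self.sweeps[i]

    @property
    def sampling_rate(self) -> float:
        return self.sweeps[0].sampling_rate

    @property
    def signal_kind(self) -> str:
        return self.sweeps[0].signal_kind


def _expected_signal_kind(protocol_kind: str) -> str | None:
    if protocol_kind.endswith("_vc"):
        return CURRENT
    if protocol_kind.endswith("_cc"):
        return VOLTAGE
    return None


@dataclass(frozen=True)
class BaselineStats:
    """Mean and raw median absolute deviation over a baseline window."""

    mean: float
    mad: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.mad < 0:
            raise ValueError("mad must be >= 0")


# ---------------------------------------------------------------------------
# Interchange I/O
# ---------------------------------------------------------------------------
#
# Neutral format: <stem>.csv holds the sample matrix (one column per sweep,
# header sweep_0..sweep_{n-1}); <stem>.json holds everything else.


def write_recording(sweepset: SweepSet, path: str | Path) -> Path:
    """Write a SweepSet as CSV matrix + JSON sidecar; returns the CSV path."""
    stem = _strip_ext(Path(path))
    lengths = {s.n_samples for s in sweepset}
    if len(lengths) != 1:
        raise ValueError("interchange format requires equal-length sweeps")
    mat = np.column_stack([s.samples for s in sweepset])
    header = ",".join(f"sweep_{i}" for i in range(len(sweepset)))
    csv_path = stem.with_suffix(".csv")
    np.savetxt(csv_path, mat, delimiter=",", header=header, comments="", fmt="%.9g")
    meta = {
        "sampling_rate": sweepset.sampling_rate,
        "signal_kind": sweepset.signal_kind,
        "units": "pA" if sweepset.signal_kind == CURRENT else "mV",
        "cell_id": sweepset.cell_id,
        "animal_id": sweepset.animal_id,
        "protocol": sweepset.protocol.to_dict(),
        "sweeps": [
            {
                "t0": s.t0,
                "stimulus_times": list(s.stimulus_times),
                "artifact_windows": [list(w) for w in s.artifact_windows],
                "holding": s.holding,
                "step_current": s.step_current,
            }
            for s in sweepset
        ],
    }
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return csv_path


def read_recording(path: str | Path, format_hint: str | None = None) -> SweepSet:
    """Read a recording (neutral interchange or ABF) into a SweepSet.

    ``format_hint`` may be ``"interchange"`` or ``"abf"``; by default the
    file extension decides.  ABF support requires the optional ``pyabf``
    dependency and a sidecar ``<stem>.json`` for protocol metadata.
    """
    path = Path(path)
    fmt = format_hint or ("abf" if path.suffix.lower() == ".abf" else "interchange")
    if fmt == "abf":
        return _read_abf(path)
    if fmt != "interchange":
        raise ValueError(f"unknown format {fmt!r}")

    stem = _strip_ext(path)
    csv_path, json_path = stem.with_suffix(".csv"), stem.with_suffix(".json")
    if not csv_path.exists() or not json_path.exists():
        raise FileNotFoundError(f"interchange pair {stem}.csv/.json not found")
    meta = json.loads(json_path.read_text())
    for key in ("sampling_rate", "signal_kind"):
        if key not in meta or meta[key] in (None, 0):
            raise ValueError(f"sidecar missing required field {key!r}")
    if meta.get("units") not in ("pA", "mV", None):
        raise ValueError(f"unknown units {meta.get('units')!r}")
    mat = np.loadtxt(csv_path, delimiter=",", skiprows=1, ndmin=2)
    sweep_meta = meta.get("sweeps") or [{} for _ in range(mat.shape[1])]
    if len(sweep_meta) != mat.shape[1]:
        raise ValueError("sidecar sweep count does not match CSV columns")
    sweeps = [
        Sweep(
            samples=mat[:, i],
            sampling_rate=float(meta["sampling_rate"]),
            signal_kind=meta["signal_kind"],
            t0=sm.get("t0", 0.0),
            stimulus_times=list(sm.get("stimulus_times", [])),
            artifact_windows=[tuple(w) for w in sm.get("artifact_windows", [])],
            holding=sm.get("holding"),
            step_current=sm.get("step_current"),
        )
        for i, sm in enumerate(sweep_meta)
    ]
    return SweepSet(
        sweeps=sweeps,
        protocol=ProtocolMetadata.from_dict(meta["protocol"]),
        cell_id=meta.get("cell_id", "cell"),
        animal_id=meta.get("animal_id", "animal"),
    )


def _read_abf(path: Path) -> SweepSet:
    try:
        import pyabf  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading ABF files requires the optional 'pyabf' package "
            "(pip install clampkit[abf])"
        ) from exc
    abf = pyabf.ABF(str(path))  # pragma: no cover - exercised only with pyabf
    sidecar = _strip_ext(path).with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"ABF files need a protocol sidecar at {sidecar} "
            "(acquisition files do not carry the analysis metadata)"
        )
    meta = json.loads(sidecar.read_text())
    units = abf.adcUnits[0].strip()
    kind = {"pA": CURRENT, "mV": VOLTAGE}.get(units)
    if kind is None:
        raise ValueError(f"unknown ABF units {units!r}")
    sweeps = []
    for i in abf.sweepList:
        abf.setSweep(i)
        sm = (meta.get("sweeps") or [{}] * abf.sweepCount)[i]
        sweeps.append(
            Sweep(
                samples=np.asarray(abf.sweepY, dtype=float),
                sampling_rate=float(abf.dataRate),
                signal_kind=kind,
                stimulus_times=list(sm.get("stimulus_times", [])),
                artifact_windows=[tuple(w) for w in sm.get("artifact_windows", [])],
                holding=sm.get("holding"),
                step_current=sm.get("step_current"),
            )
        )
    return SweepSet(
        sweeps=sweeps,
        protocol=ProtocolMetadata.from_dict(meta["protocol"]),
        cell_id=meta.get("cell_id", path.stem),
        animal_id=meta.get("animal_id", "animal"),
    )


def _strip_ext(path: Path) -> Path:
    return path.with_suffix("") if path.suffix in (".csv", ".json", ".abf") else path


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------


def savgol_smooth(
    sweep: Sweep,
    half_window_ms: float = 0.5,
    polyorder: int = 3,
    force: bool = False,
) -> Sweep:
    """3rd-order Savitzky-Golay filter with a ±0.5 ms window.

    Applied to current sweeps (voltage data are left unfiltered upstream);
    pass ``force=True`` to override the signal-kind check.
    """
    if sweep.signal_kind != CURRENT and not force:
        raise ValueError("savgol_smooth is defined for current sweeps")
    half = max(1, int(round(half_window_ms * 1e-3 * sweep.sampling_rate)))
    window = 2 * half + 1
    if sweep.n_samples < window:
        raise ValueError(f"sweep shorter than filter window ({window} samples)")
    return sweep.with_samples(savgol_filter(sweep.samples, window, polyorder))


def savgol_weights(
    sampling_rate: float = 10_000.0, half_window_ms: float = 0.5, polyorder: int = 3
) -> np.ndarray:
    """Central-point convolution weights of the smoothing filter."""
    from scipy.signal import savgol_coeffs

    half = max(1, int(round(half_window_ms * 1e-3 * sampling_rate)))
    return savgol_coeffs(2 * half + 1, polyorder)


def baseline_stats(
    sweep: Sweep, window: tuple[float, float], mad_scale: float = 1.0
) -> BaselineStats:
    """Mean and raw MAD of the samples in ``[start, end)``.

    Samples inside the sweep's artifact windows are excluded.  ``mad_scale``
    defaults to 1.0 (raw MAD, not the 1.4826 normal-consistency factor).
    """
    start, end = window
    sl = sweep.window_slice(start, end)
    if sl.stop <= sl.start:
        raise ValueError("empty baseline window")
    idx = np.arange(sl.start, sl.stop)
    t = idx / sweep.sampling_rate
    keep = np.ones(idx.size, dtype=bool)
    for a_start, a_end in sweep.artifact_windows:
        keep &= ~((t >= a_start) & (t < a_end))
    if not keep.any():
        raise ValueError("baseline window empty after artifact exclusion")
    x = sweep.samples[idx[keep]]
    med = np.median(x)
    return BaselineStats(
        mean=float(np.mean(x)),
        mad=float(mad_scale * np.median(np.abs(x - med))),
        window=(start, end),
    )


def blank_artifacts(sweep: Sweep, width_ms: float | None = None) -> Sweep:
    """Blank stimulus artifacts by linear interpolation.

    Interpolates over each artifact window; if ``width_ms`` is given,
    windows of that width starting at each stimulus time are used instead
    of the annotated ``artifact_windows``.
    """
    windows = sweep.artifact_windows
    if width_ms is not None:
        windows = [
            (t, min(t + width_ms * 1e-3, sweep.duration)) for t in sweep.stimulus_times
        ]
    if not windows:
        return sweep.with_samples(sweep.samples.copy())
    y = sweep.samples.copy()
    for start, end in windows:
        sl = sweep.window_slice(start, end)
        i0, i1 = sl.start, sl.stop
        if i1 <= i0:
            continue
        left = y[i0 - 1] if i0 > 0 else y[i1] if i1 < y.size else y[0]
        right = y[i1] if i1 < y.size else left
        y[i0:i1] = np.linspace(left, right, i1 - i0 + 2)[1:-1]
    return sweep.with_samples(y)


def dvdt(samples_mv: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Centered-difference derivative of a voltage trace, in V/s."""
    return np.gradient(np.asarray(samples_mv, dtype=float)) * sampling_rate / 1000.0


def _alignment_index(seg: np.ndarray, mode: str, sampling_rate: float) -> int:
    if mode == "max_rise":
        # steepest slope of the event (either polarity)
        return int(np.argmax(np.abs(np.gradient(seg))))
    if mode == "ap_threshold":
        d = dvdt(seg, sampling_rate)
        above = np.nonzero(d >= 20.0)[0]
        return int(above[0]) if above.size else int(np.argmax(d))
    raise ValueError(f"unknown alignment mode {mode!r}")


def align_average(
    traces: Sequence[np.ndarray] | Iterable[np.ndarray],
    mode: str = "max_rise",
    sampling_rate: float = 10_000.0,
    anchor_window: tuple[int, int] | None = None,
) -> np.ndarray:
    """Pointwise mean of event segments after alignment.

    ``mode="max_rise"`` aligns segments at their point of maximal rise,
    ``mode="ap_threshold"`` at the first 20 V/s crossing, ``mode="none"``
    averages as-is (used for subthreshold EPSPs, which are not aligned).
    ``anchor_window`` restricts the alignment-point search to an index
    range (useful when segments may contain neighboring events).
    Segments are cropped to the common support around the alignment point.
    """
    segs = [np.asarray(t, dtype=float) for t in traces]
    if not segs:
        raise ValueError("align_average needs at least one segment")
    if mode == "none":
        n = min(s.size for s in segs)
        return np.mean([s[:n] for s in segs], axis=0)
    if anchor_window is not None:
        lo, hi = anchor_window
        anchors = [
            lo + _alignment_index(s[lo : min(hi, s.size)], mode, sampling_rate)
            for s in segs
        ]
    else:
        anchors = [_alignment_index(s, mode, sampling_rate) for s in segs]
    left = min(anchors)
    right = min(s.size - a for s, a in zip(segs, anchors))
    return np.mean([s[a - left : a + right] for s, a in zip(segs, anchors)], axis=0)
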