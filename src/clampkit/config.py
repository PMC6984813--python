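"""Pipeline configuration: every protocol constant surfaced, none hard-coded.

Defaults are the study's values (6× / 5× MAD detection thresholds, 5/7.5 ms
evoked windows, 3 ms unitary window, 20 ms search limit, 40/50 ms
stimulus-response windows, 500 ms evoked baseline, 50 ms rolling baseline,
10,000 forest trees, 500 tree bootstraps, 20 forest CV runs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # detection thresholds and windows
    evoked_mad_multiplier: float = 6.0
    sepsc_mad_multiplier: float = 5.0
    epsc_half_width_ms: float = 5.0
    ipsc_half_width_ms: float = 7.5
    uepsc_window_ms: float = 3.0
    evoked_search_limit_ms: float = 20.0
    epsp_window_ms: float = 40.0
    ap_count_window_ms: float = 50.0
    sepsc_baseline_ms: float = 50.0
    evoked_baseline_ms: float = 500.0
    artifact_blank_ms: float = 2.0
    nci_cutoff: float = 0.5
    mad_scale: float = 1.0
    # smoothing (current sweeps only; voltage is left unfiltered)
    savgol_half_window_ms: float = 0.5
    savgol_polyorder: int = 3
    savgol_on_load: bool = True
    template_decay_spans: float = 1.0
    # intrinsic properties
    ap_dvdt_threshold: float = 20.0  # V/s
    max_fr_isi: str = "min"
    # classifiers
    n_trees: int = 10_000
    tree_bootstraps: int = 500
    forest_cv_runs: int = 20
    tree_min_samples_split: int = 5
    tree_cv_folds: int = 10
    # run control
    seed: int = 0
    output_dir: str = "out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
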