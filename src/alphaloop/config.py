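"""Experiment configuration: every protocol constant in one place.

The defaults encode the study design this package simulates: 256 Hz
16-channel acquisition band-passed 2-30 Hz; real-time spectra from 2 s
Hann windows zero-padded to 8 s (0.125 Hz resolution) updated every 100 ms;
a feedback threshold starting 0.1 Hz below the baseline IAF with 0.1-0.3 Hz
block-wise adaptation; two days of five 3 x 1-min training blocks (30 min
of feedback total); offline spectra at 0.01 Hz resolution.

Configurations round-trip losslessly through JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .montage import MONTAGE_16, OCCIPITOPARIETAL


@dataclass
class AcquisitionConfig:
    fs: float = 256.0
    band: tuple[float, float] = (2.0, 30.0)
    montage: tuple[str, ...] = MONTAGE_16


@dataclass
class RealtimeConfig:
    window_len_s: float = 2.0
    pad_total_s: float = 8.0           # 2 s window + 6 s zero padding
    step_s: float = 0.1
    sg_window_bins: int = 11
    sg_order: int = 3
    gate_min_prominence: float = 6.0
    gate_min_alpha_ratio: float = 0.45
    channel_set: tuple[str, ...] = OCCIPITOPARIETAL
    average_mode: str = "peaks"


@dataclass
class ControllerConfig:
    init_offset_hz: float = 0.1
    adapt_trigger: float = 0.7
    adapt_steps: tuple[float, float, float] = (0.1, 0.2, 0.3)
    accum_window_s: float = 0.5
    clamp: tuple[float, float] = (6.5, 13.5)


@dataclass
class ProtocolConfig:
    days: int = 2
    baseline_epochs: int = 4
    baseline_epoch_s: float = 30.0
    baseline_rest_s: float = 10.0
    blocks_per_day: int = 5
    epochs_per_block: int = 3
    epoch_s: float = 60.0
    epoch_rest_s: float = 10.0


@dataclass
class GeneratorConfig:
    baseline_peak_mean: float = 10.0
    baseline_peak_sd: float = 0.8
    alpha_snr: float = 60.0
    bg_rms_uv: float = 10.0
    noise_exponent: float = 1.0
    bandwidth_hz: float = 0.5
    responsiveness: float = 0.004
    excitability_sd: float = 0.2
    excitability_tau_s: float = 5.0
    drift_jitter: float = 0.002
    relax_rate: float = 1e-3
    ceiling_offset: float = 1.5


@dataclass
class TaskConfig:
    mr_trials: int = 15
    mr_blocks: int = 2
    mr_match_prob: float = 0.5
    nback1_trials: int = 28
    nback3_trials: int = 30
    nback3_blocks: int = 2
    nback_target_prob: float = 1 / 3


@dataclass
class StatsConfig:
    alpha: float = 0.05
    behavior_coupling: float = 5.0
    behavior_metric_noise: float = 1.0


@dataclass
class ExperimentConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    realtime: RealtimeConfig = field(default_factory=RealtimeConfig)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    tasks: TaskConfig = field(default_factory=TaskConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    n_subjects_per_arm: int = 16
    store_recordings: str = "none"     # "none" | "baselines" | "all"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        def build(tp, val):
            kwargs = {}
            for f in dataclasses.fields(tp):
                if f.name not in val:
                    continue
                v = val[f.name]
                if dataclasses.is_dataclass(f.type) or f.name in _SUB:
                    v = build(_SUB[f.name], v)
                elif isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
            return tp(**kwargs)

        _SUB = {"acquisition": AcquisitionConfig, "realtime": RealtimeConfig,
                "controller": ControllerConfig, "protocol": ProtocolConfig,
                "generator": GeneratorConfig, "tasks": TaskConfig,
                "stats": StatsConfig}
        return build(cls, d)

    @classmethod
    def from_json(cls, source: str | Path) -> "ExperimentConfig":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls.from_dict(json.loads(text))

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
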