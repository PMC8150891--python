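"""Run configuration: protocol, preprocessing, model and roster defaults.

Defaults reproduce the study conditions: 500 Hz sampling, 10-sample input
window over 3 channels, 300-sample smoothing, x1e5 amplification, 10 hidden
neurons, and a 29-file roster (P1 and P2 with 10 files, P10 with 2, P3-P9
with one each), each file 300-400 s long.  Round-trips losslessly through
YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .model_lm import TrainConfig
from .preprocess import FilterSpec

__all__ = ["RunConfig", "DEFAULT_ROSTER"]

#: participant -> number of files, as in the original study
DEFAULT_ROSTER: dict[str, int] = {
    "P1": 10,
    "P2": 10,
    "P3": 1,
    "P4": 1,
    "P5": 1,
    "P6": 1,
    "P7": 1,
    "P8": 1,
    "P9": 1,
    "P10": 2,
}


@dataclass
class RunConfig:
    fs: float = 500.0
    lag: int = 10
    smooth_window: int = 300
    gain: float = 1.0e5
    reaction_lag_s: float = 0.25
    session_length_range_s: tuple[float, float] = (300.0, 400.0)
    noise_sd: float = 4.0e-6
    line_amp: float = 1.0e-5
    drift_amp: float = 2.0e-5
    filter: FilterSpec = field(default_factory=FilterSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    roster: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ROSTER))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.lag < 1 or self.smooth_window < 1:
            raise ValueError("fs, lag and smooth_window must be positive")
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        lo, hi = self.session_length_range_s
        if not 30 <= lo <= hi:
            raise ValueError("session_length_range_s must satisfy 30 <= lo <= hi")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["session_length_range_s"] = list(self.session_length_range_s)
        d["filter"]["stop_band"] = list(self.filter.stop_band)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "filter" in d:
            f = dict(d["filter"])
            f["stop_band"] = tuple(f["stop_band"])
            d["filter"] = FilterSpec(**f)
        if "training" in d:
            d["training"] = TrainConfig(**d["training"])
        if "session_length_range_s" in d:
            d["session_length_range_s"] = tuple(d["session_length_range_s"])
        return cls(**d)
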