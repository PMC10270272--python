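"""Run configuration: nested defaults, YAML round trip, strict key checking."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PreprocessConfig:
    notch_hz: float = 50.0
    bandpass_lo_hz: float = 0.5
    bandpass_hi_hz: float = 45.0
    order: int = 4
    notch_q: float = 30.0


@dataclass
class VcgConfig:
    matrix_file: str | None = None  # CSV 3x8, rows X,Y,Z; cols I,II,V1..V6


@dataclass
class FiducialConfig:
    detector_lead: str = "magnitude"  # or x/y/z/auto
    loop_points: int = 100
    min_beats: int = 8


@dataclass
class RbfConfig:
    spacing: float | None = None   # mV; None = bounding-box extent / 5
    width_factor: float = 1.5
    gain_a: float = 0.5
    gamma: float = 0.5
    sigma: float = 1e-4
    epochs: int = 20


@dataclass
class ShiConfig:
    step_k: int = 10
    theiler: int | None = None  # None = one loop length


@dataclass
class ThiConfig:
    grid_max: int | None = None  # None = N // 2
    spectrum_mode: str = "norm"


@dataclass
class ClassifierConfig:
    model: str = "paper-2023"  # version tag or path to a JSON classifier


@dataclass
class EvaluateConfig:
    standard: int = 1
    ci: str = "delong"


@dataclass
class RunConfig:
    """Complete pipeline configuration with full defaults."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    vcg: VcgConfig = field(default_factory=VcgConfig)
    fiducials: FiducialConfig = field(default_factory=FiducialConfig)
    rbf: RbfConfig = field(default_factory=RbfConfig)
    shi: ShiConfig = field(default_factory=ShiConfig)
    thi: ThiConfig = field(default_factory=ThiConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    version: str = "cdgram-0.1"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name: f for f in fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, f in known.items():
            if name not in data:
                continue
            sub = data[name]
            if name == "version":
                kwargs[name] = sub
                continue
            sub_cls = f.default_factory().__class__
            sub_known = {sf.name for sf in fields(sub_cls)}
            bad = set(sub) - sub_known
            if bad:
                raise ValueError(f"unknown keys in {name!r}: {sorted(bad)}")
            kwargs[name] = sub_cls(**sub)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def hash(self) -> str:
        """Stable short hash of the canonical configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
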