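"""Run configuration: one object (or TOML file) covering every stage."""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .angles import HoughParams
from .detect import DEFAULT_SCALES
from .fusion import FusionConfig
from .preprocess import FilterParams

__all__ = ["DetectConfig", "PipelineConfig"]


@dataclass(frozen=True)
class DetectConfig:
    """Template-matching options.

    scales
        Scale factors swept over each template.
    normalize
        Zero-mean the window and template before scoring (for real
        images whose brightness differs from the references).
    extent_factor
        Femur ROI height as a multiple of the prosthesis ROI height.
    femur_exclusion_deg
        Prosthesis-ROI lines within this many degrees of the femur
        median orientation are attributed to the shaft and dropped
        (0 disables the filter).
    """

    scales: tuple = DEFAULT_SCALES
    normalize: bool = False
    extent_factor: float = 2.0
    femur_exclusion_deg: float = 15.0

    def __post_init__(self):
        if not self.scales or min(self.scales) <= 0:
            raise ValueError("scales must be positive")
        if self.extent_factor <= 0:
            raise ValueError("extent_factor must be positive")
        if self.femur_exclusion_deg < 0:
            raise ValueError("femur_exclusion_deg must be non-negative")


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved settings for a cohort run."""

    preprocess: FilterParams = field(default_factory=FilterParams)
    hough: HoughParams = field(default_factory=HoughParams)
    detect: DetectConfig = field(default_factory=DetectConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    seed: int = 0

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        """Build a config from a TOML file with per-stage sections.

        Recognised sections: ``[preprocess]``, ``[hough]``,
        ``[detect]``, ``[fusion]``; a top-level ``seed`` key sets the
        run seed.  Unknown keys are rejected.
        """
        data = tomllib.loads(Path(path).read_text())
        kwargs = {}
        sections = {
            "preprocess": FilterParams,
            "hough": HoughParams,
            "detect": DetectConfig,
            "fusion": FusionConfig,
        }
        for name, klass in sections.items():
            if name in data:
                section = dict(data.pop(name))
                if name == "detect" and "scales" in section:
                    section["scales"] = tuple(section["scales"])
                valid = {f.name for f in dataclasses.fields(klass)}
                unknown = set(section) - valid
                if unknown:
                    raise ValueError(f"unknown [{name}] keys: {sorted(unknown)}")
                kwargs[name] = klass(**section)
        seed = data.pop("seed", 0)
        if data:
            raise ValueError(f"unknown top-level config keys: {sorted(data)}")
        return cls(seed=int(seed), **kwargs)

    def to_json(self) -> str:
        """Resolved config as JSON (written next to run outputs)."""

        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, tuple):
                return list(obj)
            raise TypeError(f"cannot encode {type(obj)}")

        return json.dumps(dataclasses.asdict(self), default=encode, indent=2, sort_keys=True)
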