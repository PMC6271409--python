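"""Run configuration: HU windows, conventions, toggles.

One plain-text (YAML) config drives the whole pipeline so every report can
embed the exact settings it was produced under.  Defaults encode the
standard densitometry windows: segmentation band [-1024, -200] HU,
high-attenuation band [-600, -250] HU, fibrotic band [-1024, -700] HU.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .survival import DEFAULT_DIRECTIONS


@dataclass
class RunConfig:
    seg_band: tuple[float, float] = (-1024.0, -200.0)
    seed_max_hu: float = -500.0
    haa_band: tuple[float, float] = (-600.0, -250.0)
    fa_band: tuple[float, float] = (-1024.0, -700.0)
    kurtosis_convention: str = "excess"
    remove_airways: bool = False
    airway_max_area_cm2: float = 3.0
    airway_min_slices: int = 5
    min_lung_volume_ml: float = 500.0
    directions: dict = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        lo, hi = self.seg_band
        if not (-1024.0 <= lo < hi <= -200.0):
            raise ValueError(
                f"segmentation band {self.seg_band} must be ordered and within [-1024, -200]"
            )
        for name in ("haa_band", "fa_band"):
            blo, bhi = sorted(getattr(self, name))
            if not (-1400.0 <= blo < bhi <= 3200.0):
                raise ValueError(f"{name}={getattr(self, name)} outside plausible CT range")
            setattr(self, name, (blo, bhi))
        if self.kurtosis_convention not in ("excess", "pearson"):
            raise ValueError(f"unknown kurtosis convention {self.kurtosis_convention!r}")
        for var, d in self.directions.items():
            if d not in ("le", "ge", "auto"):
                raise ValueError(f"direction for {var!r} must be le/ge/auto, got {d!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for name in ("seg_band", "haa_band", "fa_band"):
            d[name] = list(d[name])
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        for name in ("seg_band", "haa_band", "fa_band"):
            if name in raw:
                raw[name] = tuple(raw[name])
        return cls(**raw)

    def segment_kwargs(self) -> dict:
        return {
            "band": self.seg_band,
            "seed_max_hu": self.seed_max_hu,
            "min_volume_ml": self.min_lung_volume_ml,
            "remove_airways": self.remove_airways,
            "airway_max_area_cm2": self.airway_max_area_cm2,
            "airway_min_slices": self.airway_min_slices,
        }

    def index_kwargs(self) -> dict:
        return {
            "haa_band": self.haa_band,
            "fa_band": self.fa_band,
            "kurtosis_convention": self.kurtosis_convention,
        }

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path
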