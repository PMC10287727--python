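"""Run configuration and manifests for reproducible pipeline runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import yaml


@dataclass
class RunConfig:
    """All tunable parameters of the analysis stages.

    Defaults follow the experimental conventions: 10-min median bins,
    8:30–9:30 p.m. peak window, 20% threshold, 10-px entropy window, 20-px
    smoothing width, centre-50% crop, 1st/99th percentiles, 2-μm
    peri-junctional zone, lights off at 7 p.m.
    """

    seed: int = 0
    lights_off_clock_h: float = 19.0
    bin_min: float = 10.0
    peak_window_clock_h: Tuple[float, float] = (20.5, 21.5)
    fraction: float = 0.2
    sustained_bins: int = 3
    entropy_width_px: int = 10
    smooth_width_px: float = 20.0
    background_sigma_px: float = 50.0
    crop_fraction: float = 0.5
    percentiles: Tuple[float, float] = (1.0, 99.0)
    zone_width_um: float = 2.0
    period_range_h: Tuple[float, float] = (16.0, 32.0)
    period_step_h: float = 0.1
    run_photometry: bool = True
    run_focus: bool = True
    run_rhythm: bool = True
    run_em: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("peak_window_clock_h", "percentiles", "period_range_h"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("peak_window_clock_h", "percentiles", "period_range_h"):
            d[key] = list(d[key])
        return d


@dataclass
class RunManifest:
    """Provenance record emitted by every pipeline run."""

    config: dict
    package_version: str
    input_checksums: Dict[str, str] = field(default_factory=dict)
    stage_runtimes_s: Dict[str, float] = field(default_factory=dict)
    output_paths: List[str] = field(default_factory=list)
    output_checksums: Dict[str, str] = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
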