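"""Run configuration: analysis parameters plus instrument provenance.

Amplifier voltages/gains and flow-rate settings from the acquisition are
carried as opaque provenance metadata — they have no computational role.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import yaml


@dataclass
class RunConfig:
    """Parameters shared across the pipeline.

    Attributes
    ----------
    positivity_threshold:
        Linear intensity above which an event counts as positive on a
        fluorescence axis. The negative region is defined as intensity below
        the first log decade, so the default is 10.
    quantiles:
        Percentiles Q (percent) at which the imaging and cytometry size
        distributions are matched.
    area_bounds_um2:
        Soma-area class bounds in um^2: [min small, small/medium, medium/large].
    diameter_bounds_um:
        Imaging area-diameter class bounds in um (small/medium, medium/large).
    hist_bin_um:
        Soma-size histogram bin width in um.
    events_per_sample:
        Events acquired per cytometry sample.
    geomean_floor:
        Intensity floor substituted for zeros before log-domain statistics.
    seed:
        Base seed for any stochastic step.
    instrument:
        Free-form provenance metadata (voltages, gains, flow rate).
    """

    positivity_threshold: float = 10.0
    quantiles: tuple[float, ...] = (5.0, 20.0, 40.0, 60.0, 80.0, 95.0)
    area_bounds_um2: tuple[float, float, float] = (15.0, 70.0, 125.0)
    diameter_bounds_um: tuple[float, float] = (9.4, 12.6)
    hist_bin_um: float = 2.0
    events_per_sample: int = 10_000
    geomean_floor: float = 0.1
    seed: int = 0
    instrument: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = tuple(float(v) for v in self.quantiles)
        if any(not (0 < v < 100) for v in q):
            raise ValueError("quantiles must lie strictly inside (0, 100)")
        if any(b >= a for b, a in zip(q, q[1:])):
            raise ValueError("quantiles must be strictly increasing")
        self.quantiles = q
        ab = tuple(float(v) for v in self.area_bounds_um2)
        if any(b >= a for b, a in zip(ab, ab[1:])):
            raise ValueError("area class bounds must be strictly increasing")
        self.area_bounds_um2 = ab
        db = tuple(float(v) for v in self.diameter_bounds_um)
        if db[0] >= db[1]:
            raise ValueError("diameter class bounds must be strictly increasing")
        self.diameter_bounds_um = db
        if self.hist_bin_um <= 0:
            raise ValueError("histogram bin width must be positive")
        if self.positivity_threshold <= 0:
            raise ValueError("positivity threshold must be positive")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["quantiles"] = list(self.quantiles)
        d["area_bounds_um2"] = list(self.area_bounds_um2)
        d["diameter_bounds_um"] = list(self.diameter_bounds_um)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root in {path} must be a mapping")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
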