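"""Core domain types for cytometry event data.

An :class:`EventTable` holds one acquisition's worth of list-mode events as a
pandas DataFrame with the canonical channel set ``FSC, SSC, FL1, FL2, FL3``.
All fluorescence values are stored linear-scale (log-decade display is a
presentation concern only); FSC/SSC are arbitrary instrument units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

#: Channels every event table must provide.
REQUIRED_CHANNELS = ("FSC", "FL1", "FL2", "FL3")
#: Channels an event table may provide.
OPTIONAL_CHANNELS = ("SSC",)
#: Canonical column order.
CANONICAL_CHANNELS = ("FSC", "SSC", "FL1", "FL2", "FL3")

#: Population labels assigned by gating.
POPULATION_LABELS = (
    "s-RGC", "m-RGC", "l-RGC",
    "s-NR", "m-NR", "l-NR",
    "negative", "unclassified",
)


class MissingChannelError(ValueError):
    """Raised when an input lacks one or more required channels."""

    def __init__(self, missing: Iterable[str]):
        self.missing = tuple(missing)
        super().__init__(
            "event data is missing required channel(s): " + ", ".join(self.missing)
        )


class CompensationStateError(RuntimeError):
    """Raised when spillover compensation is applied twice."""


def normalize_channel_name(name: str) -> str:
    """Map an instrument channel name onto the canonical set.

    ``FSC-H``, ``FSC-A``, ``FL2-H``, ``fl2`` etc. all collapse to their base
    name; the mapping is idempotent. Unknown names are returned upper-cased
    with pulse-metric suffixes stripped, so extra channels survive unharmed.
    """
    base = name.strip().upper()
    for suffix in ("-H", "-A", "-W"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    # FACSCalibur exports sometimes spell scatter channels in full.
    aliases = {"FORWARD SCATTER": "FSC", "SIDE SCATTER": "SSC"}
    return aliases.get(base, base)


@dataclass
class EventTable:
    """Per-event cytometry measurements with raw/compensated state.

    Parameters
    ----------
    data:
        DataFrame with (at least) the required channels as columns. Stored
        with canonical channel ordering; extra columns are preserved after
        the canonical block.
    compensated:
        Whether spillover compensation has been applied.
    labels:
        Optional per-event population labels (present only after gating).
    """

    data: pd.DataFrame
    compensated: bool = False
    labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        rename = {c: normalize_channel_name(str(c)) for c in self.data.columns}
        self.data = self.data.rename(columns=rename)
        missing = [c for c in REQUIRED_CHANNELS if c not in self.data.columns]
        if missing:
            raise MissingChannelError(missing)
        order = [c for c in CANONICAL_CHANNELS if c in self.data.columns]
        extra = [c for c in self.data.columns if c not in order]
        self.data = self.data[order + extra].reset_index(drop=True)
        values = self.data[list(order)].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("event table contains non-finite channel values")
        for fl in ("FL1", "FL2", "FL3"):
            if (self.data[fl] < 0).any():
                raise ValueError(f"{fl} contains negative intensities")
        if self.labels is not None and len(self.labels) != len(self.data):
            raise ValueError("labels length does not match event count")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    def channel(self, name: str) -> np.ndarray:
        """Return one channel as a float array."""
        return self.data[normalize_channel_name(name)].to_numpy(dtype=float)

    def with_data(self, data: pd.DataFrame, *, compensated: Optional[bool] = None,
                  labels: Optional[pd.Series] = None) -> "EventTable":
        """Copy-with-replacement constructor used by pipeline stages."""
        return EventTable(
            data=data,
            compensated=self.compensated if compensated is None else compensated,
            labels=self.labels if labels is None else labels,
        )

    def subset(self, mask: np.ndarray) -> "EventTable":
        """Boolean-mask a table, carrying labels along."""
        sub = self.data.loc[np.asarray(mask, bool)].reset_index(drop=True)
        labels = None
        if self.labels is not None:
            labels = self.labels.loc[np.asarray(mask, bool)].reset_index(drop=True)
        return EventTable(sub, compensated=self.compensated, labels=labels)


@dataclass(frozen=True)
class SpilloverSettings:
    """Pairwise spillover coefficients, in percent of the spilling channel.

    The convention follows the instrument-panel labels: ``fl2_minus_fl1 = 20``
    means "subtract 20% of the raw FL1 signal from FL2". Defaults are the
    CaliBRITE three-colour values used throughout this package.
    """

    fl1_minus_fl2: float = 0.7
    fl2_minus_fl1: float = 20.0
    fl2_minus_fl3: float = 0.0
    fl3_minus_fl2: float = 17.5

    def __post_init__(self) -> None:
        for name in ("fl1_minus_fl2", "fl2_minus_fl1", "fl2_minus_fl3", "fl3_minus_fl2"):
            v = getattr(self, name)
            if not (0 <= v < 100):
                raise ValueError(f"spillover coefficient {name}={v} outside [0, 100)")

    def as_matrix(self) -> np.ndarray:
        """3x3 compensation matrix M such that compensated = M @ raw.

        Row/column order (FL1, FL2, FL3). The forward mixing map used by the
        synthetic generator is the inverse of this matrix.
        """
        a = self.fl1_minus_fl2 / 100.0
        b = self.fl2_minus_fl1 / 100.0
        c = self.fl2_minus_fl3 / 100.0
        d = self.fl3_minus_fl2 / 100.0
        return np.array([[1.0, -a, 0.0], [-b, 1.0, -c], [0.0, -d, 1.0]])


@dataclass
class FlatmountImage:
    """A grayscale flatmount field with physical scale.

    ``scale`` is micrometres per pixel; ``field_um`` is the nominal counted
    field size (the standard sampling field is 200x200 um). ``region`` is
    provenance metadata (central/middle/peripheral) with no computational role.
    """

    pixels: np.ndarray
    scale: float
    region: Optional[str] = None
    field_um: tuple[float, float] = (200.0, 200.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("flatmount image must be a 2-D grayscale grid")
        if self.scale <= 0:
            raise ValueError("scale (um per pixel) must be positive")
        if (self.pixels < 0).any():
            raise ValueError("image intensities must be non-negative")

    @property
    def field_area_mm2(self) -> float:
        """Nominal counted-field area in mm^2."""
        return self.field_um[0] * self.field_um[1] / 1e6

    @property
    def pixel_area_mm2(self) -> float:
        """Actual pixel-grid area in mm^2 (rows x cols x scale^2)."""
        return self.pixels.shape[0] * self.pixels.shape[1] * self.scale ** 2 / 1e6
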