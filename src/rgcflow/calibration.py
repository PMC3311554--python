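"""Size calibration: bead line, quantile bridge, and FSC gate derivation.

The forward-scatter (FSC) signal grows with particle size but its scale is
instrument-specific, so two linear maps anchor it to micrometres:

* the **bead line** — microsphere diameter regressed on mean FSC of bead
  standards of known diameter (d = slope * FSC + intercept);
* the **bridge line** — apparent volume diameter D_v regressed on imaging
  area diameter D_a after matching the two size distributions at the same
  cumulative percentiles Q. Cells and polystyrene beads scatter differently
  (refractive index, shape), so D_v from the bead line is *apparent*; the
  bridge absorbs that systematic offset.

Gates for the small/medium/large soma classes are then the image-side area
bounds pushed through area->D_a->D_v->FSC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .events import EventTable
from .flatmount import area_to_diameter, empirical_percentile

logger = logging.getLogger(__name__)

Role = Literal["bead", "bridge"]


class DegenerateFitError(ValueError):
    """Raised when a straight line cannot be fitted (all x identical / n < 2)."""


@dataclass(frozen=True)
class LinearCalibration:
    """A fitted straight line y = slope * x + intercept with Pearson r.

    ``role`` records which leg of the calibration the line serves:
    ``"bead"`` maps FSC units to micrometres, ``"bridge"`` maps imaging area
    diameter to apparent volume diameter (dimensionless slope).
    """

    slope: float
    intercept: float
    r: float
    role: Role
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be non-zero")
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation r={self.r} outside [-1, 1]")

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept

    def invert(self, y):
        return (np.asarray(y, dtype=float) - self.intercept) / self.slope

    def to_dict(self) -> dict:
        return {"slope": self.slope, "intercept": self.intercept, "r": self.r,
                "role": self.role, "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: Mapping) -> "LinearCalibration":
        return cls(slope=d["slope"], intercept=d["intercept"], r=d["r"],
                   role=d["role"], provenance=d.get("provenance", "fitted"))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LinearCalibration":
        return cls.from_dict(json.loads(Path(path).read_text()))


#: Published 2012 coefficients, usable in place of fitted calibrations.
PAPER_2012_BEAD = LinearCalibration(
    slope=0.027, intercept=2.16, r=0.9883, role="bead", provenance="paper-2012")
PAPER_2012_BRIDGE = LinearCalibration(
    slope=1.61, intercept=-1.94, r=0.9718, role="bridge", provenance="paper-2012")

PRESETS = {"paper-2012": {"bead": PAPER_2012_BEAD, "bridge": PAPER_2012_BRIDGE}}


def fit_line(x, y, role: Role = "bead", provenance: str = "fitted") -> LinearCalibration:
    """Ordinary least-squares line with Pearson correlation.

    Exact on collinear input; raises :class:`DegenerateFitError` when fewer
    than two distinct x values are supplied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2 or np.all(x == x[0]):
        raise DegenerateFitError("need at least two distinct x values to fit a line")
    res = stats.linregress(x, y)
    r = 1.0 if np.ptp(y) == 0 else float(res.rvalue)
    return LinearCalibration(slope=float(res.slope), intercept=float(res.intercept),
                             r=r, role=role, provenance=provenance)


def fit_bead_calibration(
    bead_samples: Mapping[float, EventTable | Sequence[EventTable]],
) -> LinearCalibration:
    """Fit the bead line from FSC measurements of known-diameter microspheres.

    ``bead_samples`` maps bead diameter (um) to one event table or a sequence
    of replicate tables; the mean FSC per bead population is the mean of the
    replicate means. Diameter is regressed on mean FSC so the line reads
    d(um) = slope * FSC + intercept.
    """
    if len(bead_samples) < 2:
        raise DegenerateFitError("bead calibration needs at least two bead sizes")
    diameters, mean_fsc = [], []
    for d, tables in sorted(bead_samples.items()):
        if isinstance(tables, EventTable):
            tables = [tables]
        if not tables or any(t.n_events == 0 for t in tables):
            raise ValueError(f"bead sample for {d} um is empty")
        reps = [float(np.mean(t.channel("FSC"))) for t in tables]
        diameters.append(float(d))
        mean_fsc.append(float(np.mean(reps)))
    cal = fit_line(mean_fsc, diameters, role="bead")
    logger.info("bead calibration from %d sizes: d = %.4g*FSC + %.4g (r=%.4f)",
                len(diameters), cal.slope, cal.intercept, cal.r)
    return cal


def fsc_to_diameter(fsc, cal: LinearCalibration):
    """Apparent diameter (um) from FSC via the bead line."""
    if cal.role != "bead":
        raise ValueError("fsc_to_diameter requires a bead-role calibration")
    out = cal.predict(fsc)
    return out if np.ndim(out) else float(out)


def diameter_to_fsc(d_um, cal: LinearCalibration):
    """Exact inverse of :func:`fsc_to_diameter` (unrounded FSC units)."""
    if cal.role != "bead":
        raise ValueError("diameter_to_fsc requires a bead-role calibration")
    out = cal.invert(d_um)
    return out if np.ndim(out) else float(out)


@dataclass(frozen=True)
class QuantilePairSet:
    """Percentile-matched imaging/cytometry size pairs.

    For each Q: the imaging area percentile and its area diameter D_a_Q, the
    FSC percentile and its apparent volume diameter D_v_Q, and the percentage
    difference (D_v - D_a)/D_a * 100.
    """

    q: np.ndarray
    area_q_um2: np.ndarray
    d_a_q_um: np.ndarray
    fsc_q: np.ndarray
    d_v_q_um: np.ndarray
    difference_pct: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.q)
        for name in ("area_q_um2", "d_a_q_um", "fsc_q", "d_v_q_um", "difference_pct"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match Q list")
        for name in ("d_a_q_um", "d_v_q_um"):
            v = getattr(self, name)
            if np.any(np.diff(v) < -1e-9):
                raise ValueError(f"{name} must be non-decreasing in Q")

    def to_dict(self) -> dict:
        return {k: np.asarray(getattr(self, k)).tolist()
                for k in ("q", "area_q_um2", "d_a_q_um", "fsc_q", "d_v_q_um",
                          "difference_pct")}

    @classmethod
    def from_dict(cls, d: Mapping) -> "QuantilePairSet":
        return cls(**{k: np.asarray(d[k], dtype=float) for k in
                      ("q", "area_q_um2", "d_a_q_um", "fsc_q", "d_v_q_um",
                       "difference_pct")})

    @classmethod
    def from_printed(cls, q, d_a_q_um, d_v_q_um, area_q_um2=None, fsc_q=None
                     ) -> "QuantilePairSet":
        """Assemble a pair set from already-tabulated percentile values."""
        q = np.asarray(q, dtype=float)
        d_a = np.asarray(d_a_q_um, dtype=float)
        d_v = np.asarray(d_v_q_um, dtype=float)
        area = (np.full_like(q, np.nan) if area_q_um2 is None
                else np.asarray(area_q_um2, dtype=float))
        fsc = (np.full_like(q, np.nan) if fsc_q is None
               else np.asarray(fsc_q, dtype=float))
        return cls(q=q, area_q_um2=area, d_a_q_um=d_a, fsc_q=fsc, d_v_q_um=d_v,
                   difference_pct=(d_v - d_a) / d_a * 100.0)


def build_quantile_pairs(areas_um2, fsc_events, q: Sequence[float],
                         bead_cal: LinearCalibration) -> QuantilePairSet:
    """Match imaging and cytometry size distributions at percentiles Q.

    D_a_Q is the area diameter of the Q-th percentile of the imaging soma
    areas; D_v_Q is the bead-line diameter of the Q-th percentile of the FSC
    events. Both distributions run small to large, so matching percentiles
    pairs like-ranked cells across the two modalities.
    """
    areas = np.asarray(areas_um2, dtype=float)
    fsc = (fsc_events.channel("FSC") if isinstance(fsc_events, EventTable)
           else np.asarray(fsc_events, dtype=float))
    if areas.size == 0 or fsc.size == 0:
        raise ValueError("quantile matching needs non-empty samples on both sides")
    q = np.asarray(q, dtype=float)
    area_q = np.atleast_1d(empirical_percentile(areas, q))
    fsc_q = np.atleast_1d(empirical_percentile(fsc, q))
    d_a_q = area_to_diameter(area_q)
    d_v_q = np.asarray(fsc_to_diameter(fsc_q, bead_cal), dtype=float)
    return QuantilePairSet(
        q=q, area_q_um2=area_q, d_a_q_um=np.atleast_1d(d_a_q), fsc_q=fsc_q,
        d_v_q_um=d_v_q, difference_pct=(d_v_q - np.atleast_1d(d_a_q)) /
        np.atleast_1d(d_a_q) * 100.0)


def fit_bridge(pairs: QuantilePairSet) -> LinearCalibration:
    """Fit the D_a -> apparent D_v bridge line over the matched pairs."""
    if len(pairs.q) < 2:
        raise DegenerateFitError("bridge fit needs at least two quantile pairs")
    cal = fit_line(pairs.d_a_q_um, pairs.d_v_q_um, role="bridge")
    logger.info("bridge from %d pairs: Dv = %.4g*Da + %.4g (r=%.4f)",
                len(pairs.q), cal.slope, cal.intercept, cal.r)
    return cal


@dataclass(frozen=True)
class GateInterval:
    """One size class expressed in all four currencies (upper bound may be inf)."""

    area_um2: tuple[float, float]
    d_a_um: tuple[float, float]
    d_v_um: tuple[float, float]
    fsc: tuple[int, float]


@dataclass(frozen=True)
class SizeGateScheme:
    """Contiguous small/medium/large gates in area, D_a, D_v and FSC units."""

    small: GateInterval
    medium: GateInterval
    large: GateInterval

    @property
    def fsc_bounds(self) -> tuple[int, int, int]:
        """(debris/small, small/medium, medium/large) FSC cut points."""
        return (self.small.fsc[0], int(self.medium.fsc[0]), int(self.large.fsc[0]))

    def to_dict(self) -> dict:
        return {name: {
            "area_um2": list(g.area_um2), "d_a_um": list(g.d_a_um),
            "d_v_um": list(g.d_v_um), "fsc": list(g.fsc)}
            for name, g in (("small", self.small), ("medium", self.medium),
                            ("large", self.large))}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SizeGateScheme":
        def gate(g):
            return GateInterval(tuple(g["area_um2"]), tuple(g["d_a_um"]),
                                tuple(g["d_v_um"]), (int(g["fsc"][0]), g["fsc"][1]))
        return cls(small=gate(d["small"]), medium=gate(d["medium"]),
                   large=gate(d["large"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SizeGateScheme":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _round2(x: float) -> float:
    return float(np.round(x, 2))


def derive_fsc_gates(area_bounds_um2: Sequence[float],
                     bridge: LinearCalibration,
                     bead_cal: LinearCalibration,
                     round_intermediates: bool = False,
                     fsc_rounding: Literal["nearest", "truncate"] = "nearest",
                     ) -> SizeGateScheme:
    """Convert soma-area class bounds into FSC gate bounds.

    Each area bound A runs through the chain D_a = 2*sqrt(A/pi), then
    D_v = bridge(D_a), then FSC = bead_cal^-1(D_v). ``area_bounds_um2`` is
    (minimum small area, small/medium bound, medium/large bound); the large
    class is open above.

    By default the chain propagates unrounded intermediates and rounds only
    the final reported values (2 dp for micrometres, nearest integer for
    FSC). ``round_intermediates=True`` instead rounds D_a and D_v to 2 dp
    before each subsequent step — the convention of the published conversion
    table — and ``fsc_rounding="truncate"`` drops the fractional FSC part
    rather than rounding, which that table uses for its lowest bound.
    """
    bounds = [float(b) for b in area_bounds_um2]
    if len(bounds) != 3 or any(b >= a for b, a in zip(bounds, bounds[1:])):
        raise ValueError("area_bounds_um2 must be three strictly increasing values")
    if bridge.role != "bridge" or bead_cal.role != "bead":
        raise ValueError("derive_fsc_gates needs a bridge and a bead calibration")

    d_a, d_v, fsc = [], [], []
    for area in bounds:
        da = area_to_diameter(area)
        if round_intermediates:
            da = _round2(da)
        dv = float(bridge.predict(da))
        if round_intermediates:
            dv = _round2(dv)
        f = float(bead_cal.invert(dv))
        d_a.append(da)
        d_v.append(dv)
        fsc.append(f)
    if any(b >= a for b, a in zip(fsc, fsc[1:])):
        raise ValueError("conversion chain produced non-monotonic FSC bounds")

    if fsc_rounding == "truncate":
        fsc_int = [int(np.trunc(f)) for f in fsc]
    else:
        fsc_int = [int(np.round(f)) for f in fsc]

    inf = float("inf")
    def pair(seq, i):  # class i interval in one currency
        hi = seq[i + 1] if i < 2 else inf
        return (_round2(seq[i]) if np.isfinite(seq[i]) else seq[i],
                _round2(hi) if np.isfinite(hi) else hi)

    scheme = SizeGateScheme(
        small=GateInterval(area_um2=(bounds[0], bounds[1]),
                           d_a_um=pair(d_a, 0), d_v_um=pair(d_v, 0),
                           fsc=(fsc_int[0], fsc_int[1])),
        medium=GateInterval(area_um2=(bounds[1], bounds[2]),
                            d_a_um=pair(d_a, 1), d_v_um=pair(d_v, 1),
                            fsc=(fsc_int[1], fsc_int[2])),
        large=GateInterval(area_um2=(bounds[2], inf),
                           d_a_um=pair(d_a, 2), d_v_um=pair(d_v, 2),
                           fsc=(fsc_int[2], inf)),
    )
    logger.info("derived FSC gates %s from area bounds %s", scheme.fsc_bounds, bounds)
    return scheme
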