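"""Compensation, gating and per-class viability/damage statistics.

The analysis follows the triple-label design: FL1 carries the TUNEL
(apoptosis) signal, FL2 the Fluoro-Gold tracer (retrograde axon transport),
FL3 the thy-1 surface marker. RGCs are the FG+/thy-1+ double-positive
events; single positives are non-RGC (endothelial or secondarily stained)
cells; double negatives below the first log decade are the negative region.
Size classes come from FSC gates derived by the calibration module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .calibration import SizeGateScheme
from .events import CompensationStateError, EventTable, SpilloverSettings

logger = logging.getLogger(__name__)

QUADRANT_LABELS = ("FG+/thy1+", "FG+/thy1-", "FG-/thy1+", "negative")
SIZE_LABELS = ("small", "medium", "large", "unclassified")
POPULATIONS = ("total-RGC", "s-RGC", "m-RGC", "l-RGC", "s-NR", "m-NR", "l-NR")

#: Intensity floor substituted for zeros before log-domain statistics.
DEFAULT_GEOMEAN_FLOOR = 0.1


def apply_compensation(events: EventTable, settings: SpilloverSettings) -> EventTable:
    """Subtract pairwise spillover from the fluorescence channels.

    All corrections are computed simultaneously from the raw values:

    * FL1' = FL1 - (FL1-%FL2)/100 * FL2
    * FL2' = FL2 - (FL2-%FL1)/100 * FL1 - (FL2-%FL3)/100 * FL3
    * FL3' = FL3 - (FL3-%FL2)/100 * FL2

    Negative results are clipped to zero. Compensating twice is a state
    error, not a silent re-subtraction.
    """
    if events.compensated:
        raise CompensationStateError("event table is already compensated")
    raw = np.column_stack([events.channel("FL1"), events.channel("FL2"),
                           events.channel("FL3")])
    comp = raw @ settings.as_matrix().T
    comp = np.clip(comp, 0.0, None)
    data = events.data.copy()
    data[["FL1", "FL2", "FL3"]] = comp
    logger.info("compensated %d events (clipped %d negative values)",
                events.n_events, int((raw @ settings.as_matrix().T < 0).sum()))
    return events.with_data(data, compensated=True)


def gate_quadrants(events: EventTable, threshold: float = 10.0) -> np.ndarray:
    """Quadrant labels on the FG (FL2) x thy-1 (FL3) dot plot.

    Positive means intensity >= threshold; the negative region is both
    intensities strictly below the threshold (below the first log decade at
    the default of 10). Every event receives exactly one label.
    """
    if not events.compensated:
        raise ValueError("quadrant gating requires compensated events")
    fg = events.channel("FL2") >= threshold
    thy = events.channel("FL3") >= threshold
    out = np.full(events.n_events, "negative", dtype=object)
    out[fg & thy] = "FG+/thy1+"
    out[fg & ~thy] = "FG+/thy1-"
    out[~fg & thy] = "FG-/thy1+"
    return out


def gate_size_classes(events: EventTable, gates: SizeGateScheme) -> np.ndarray:
    """Size labels from FSC: half-open [lo, hi) intervals, boundary events up.

    Events below the small gate's lower FSC bound are debris and labelled
    ``unclassified``.
    """
    lo_s, lo_m, lo_l = gates.fsc_bounds
    if not (lo_s < lo_m < lo_l):
        raise ValueError("size gates are not well-ordered")
    fsc = events.channel("FSC")
    out = np.full(events.n_events, "unclassified", dtype=object)
    out[(fsc >= lo_s) & (fsc < lo_m)] = "small"
    out[(fsc >= lo_m) & (fsc < lo_l)] = "medium"
    out[fsc >= lo_l] = "large"
    return out


def label_events(events: EventTable, gates: SizeGateScheme,
                 threshold: float = 10.0) -> EventTable:
    """Combine quadrant and size gates into population labels.

    FG+/thy-1+ events are RGCs and get a size prefix (s/m/l-RGC); single
    positives are non-RGCs (s/m/l-NR); double negatives are ``negative``;
    sub-gate debris stays ``unclassified``.
    """
    quad = gate_quadrants(events, threshold)
    size = gate_size_classes(events, gates)
    prefix = {"small": "s", "medium": "m", "large": "l"}
    out = np.full(events.n_events, "unclassified", dtype=object)
    for i in range(events.n_events):
        if size[i] == "unclassified":
            continue
        if quad[i] == "FG+/thy1+":
            out[i] = f"{prefix[size[i]]}-RGC"
        elif quad[i] == "negative":
            out[i] = "negative"
        else:
            out[i] = f"{prefix[size[i]]}-NR"
    return events.with_data(events.data, labels=pd.Series(out, dtype=object))


def geometric_mean(values, floor: float = DEFAULT_GEOMEAN_FLOOR) -> float:
    """exp(mean(log x)) with zeros floored at ``floor`` for log safety."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty sample")
    if np.any(arr < 0):
        raise ValueError("geometric mean requires non-negative values")
    return float(np.exp(np.mean(np.log(np.maximum(arr, floor)))))


def survival_rate(treated, control) -> float:
    """Treated quantity as a percentage of the control quantity."""
    if control <= 0:
        raise ValueError("control denominator must be positive")
    return float(treated) / float(control) * 100.0


def tunel_positive_fraction(events: EventTable | np.ndarray,
                            threshold: float = 10.0) -> float:
    """Percent of the parent population with TUNEL (FL1) >= threshold."""
    if isinstance(events, EventTable):
        if not events.compensated:
            raise ValueError("TUNEL gating requires compensated events")
        fl1 = events.channel("FL1")
    else:
        fl1 = np.asarray(events, dtype=float)
    if fl1.size == 0:
        raise ValueError("TUNEL fraction of an empty parent population")
    return float(np.mean(fl1 >= threshold) * 100.0)


def two_sample_t_test(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test.

    Returns (t, p). Degenerate when either group has n < 2 or the pooled
    variance is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs at least two observations per group")
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
    if pooled == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


@dataclass
class PopulationReport:
    """Per-class counts, survival, intensity and apoptosis statistics.

    ``frame`` has one row per population (total-RGC, s/m/l-RGC, s/m/l-NR)
    with replicate-averaged values, SEMs (NaN when replicates are missing)
    and pooled-variance t-test p-values for control vs treated comparisons.
    """

    frame: pd.DataFrame
    n_control: int = 1
    n_treated: int = 1
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    def row(self, population: str) -> pd.Series:
        return self.frame.set_index("population").loc[population]


def _replicate_stats(table: EventTable, gates: SizeGateScheme, cfg: RunConfig,
                     exclude_tunel: bool = False
                     ) -> dict[str, dict[str, float]]:
    """Per-population count / geomean / TUNEL statistics for one replicate."""
    labelled = table if table.labels is not None else label_events(
        table, gates, cfg.positivity_threshold)
    labels = labelled.labels.to_numpy()
    fl1 = labelled.channel("FL1")
    fl2 = labelled.channel("FL2")
    fl3 = labelled.channel("FL3")
    # optionally restrict intensity statistics to TUNEL-negative survivors;
    # counts and TUNEL fractions always use the full parent population
    alive = fl1 < cfg.positivity_threshold if exclude_tunel \
        else np.ones_like(fl1, dtype=bool)
    out: dict[str, dict[str, float]] = {}
    rgc_mask = np.isin(labels, ["s-RGC", "m-RGC", "l-RGC"])
    for pop in POPULATIONS:
        mask = rgc_mask if pop == "total-RGC" else labels == pop
        n = int(mask.sum())
        rec = {"count": float(n)}
        if (mask & alive).any():
            rec["fg_geomean"] = geometric_mean(fl2[mask & alive],
                                               cfg.geomean_floor)
            rec["thy1_geomean"] = geometric_mean(fl3[mask & alive],
                                                 cfg.geomean_floor)
        else:
            rec["fg_geomean"] = float("nan")
            rec["thy1_geomean"] = float("nan")
        rec["tunel_pct"] = (tunel_positive_fraction(fl1[mask],
                                                    cfg.positivity_threshold)
                            if n else float("nan"))
        out[pop] = rec
    return out


def _maybe_t_test(a: np.ndarray, b: np.ndarray) -> float:
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return float("nan")
    try:
        return two_sample_t_test(a, b)[1]
    except ValueError:
        return float("nan")


def build_population_report(
    control: EventTable | Sequence[EventTable],
    treated: EventTable | Sequence[EventTable],
    gates: SizeGateScheme,
    config: Optional[RunConfig] = None,
    exclude_tunel: bool = False,
) -> PopulationReport:
    """Assemble the per-class viability and damage report.

    ``control`` and ``treated`` are compensated event tables (one per
    replicate animal; a bare table is treated as a single replicate). For
    every population the report carries mean event counts, normalized
    frequency (percent of the mean control total-RGC count), survival rate
    (treated/control percent), FG and thy-1 geometric means with their
    treated/control percentage, TUNEL-positive percent, SEMs across
    replicates (NaN for a single replicate) and t-test p-values.
    With ``exclude_tunel`` the geometric means are computed over
    TUNEL-negative (surviving) events only; counts and TUNEL fractions
    always use the full population.
    """
    cfg = config or RunConfig()
    ctrl_tables = [control] if isinstance(control, EventTable) else list(control)
    trt_tables = [treated] if isinstance(treated, EventTable) else list(treated)
    if not ctrl_tables or not trt_tables:
        raise ValueError("need at least one replicate per arm")
    for t in ctrl_tables + trt_tables:
        if not t.compensated:
            raise ValueError("all tables must be compensated before reporting")

    ctrl = [_replicate_stats(t, gates, cfg, exclude_tunel) for t in ctrl_tables]
    trt = [_replicate_stats(t, gates, cfg, exclude_tunel) for t in trt_tables]

    def col(stats_list, pop, key):
        return np.array([s[pop][key] for s in stats_list], dtype=float)

    ctrl_total_mean = float(np.mean(col(ctrl, "total-RGC", "count")))
    if ctrl_total_mean == 0:
        raise ValueError("control arm contains no RGC events")

    rows = []
    for pop in POPULATIONS:
        cc = col(ctrl, pop, "count")
        tc = col(trt, pop, "count")
        c_fg, t_fg = col(ctrl, pop, "fg_geomean"), col(trt, pop, "fg_geomean")
        c_th, t_th = col(ctrl, pop, "thy1_geomean"), col(trt, pop, "thy1_geomean")
        c_tu, t_tu = col(ctrl, pop, "tunel_pct"), col(trt, pop, "tunel_pct")
        cc_mean, tc_mean = float(cc.mean()), float(tc.mean())
        row = {
            "population": pop,
            "control_count": cc_mean,
            "control_count_sem": _sem(cc),
            "treated_count": tc_mean,
            "treated_count_sem": _sem(tc),
            "control_norm_freq_pct": cc_mean / ctrl_total_mean * 100.0,
            "treated_norm_freq_pct": tc_mean / ctrl_total_mean * 100.0,
            "survival_pct": (survival_rate(tc_mean, cc_mean)
                             if cc_mean > 0 else float("nan")),
            "survival_sem": (_sem(tc / cc_mean * 100.0)
                             if cc_mean > 0 else float("nan")),
            "count_p": _maybe_t_test(cc, tc),
            "control_fg_geomean": float(np.nanmean(c_fg)) if np.any(~np.isnan(c_fg)) else float("nan"),
            "control_fg_sem": _sem(c_fg[~np.isnan(c_fg)]),
            "treated_fg_geomean": float(np.nanmean(t_fg)) if np.any(~np.isnan(t_fg)) else float("nan"),
            "control_thy1_geomean": float(np.nanmean(c_th)) if np.any(~np.isnan(c_th)) else float("nan"),
            "treated_thy1_geomean": float(np.nanmean(t_th)) if np.any(~np.isnan(t_th)) else float("nan"),
            "control_tunel_pct": float(np.nanmean(c_tu)) if np.any(~np.isnan(c_tu)) else float("nan"),
            "treated_tunel_pct": float(np.nanmean(t_tu)) if np.any(~np.isnan(t_tu)) else float("nan"),
            "fg_p": _maybe_t_test(c_fg, t_fg),
            "thy1_p": _maybe_t_test(c_th, t_th),
            "tunel_p": _maybe_t_test(c_tu, t_tu),
        }
        c_fg_mean = row["control_fg_geomean"]
        c_th_mean = row["control_thy1_geomean"]
        row["fg_ratio_pct"] = (row["treated_fg_geomean"] / c_fg_mean * 100.0
                               if c_fg_mean and np.isfinite(c_fg_mean) else float("nan"))
        row["thy1_ratio_pct"] = (row["treated_thy1_geomean"] / c_th_mean * 100.0
                                 if c_th_mean and np.isfinite(c_th_mean) else float("nan"))
        rows.append(row)

    frame = pd.DataFrame(rows)
    logger.info("population report over %d control / %d treated replicates",
                len(ctrl_tables), len(trt_tables))
    return PopulationReport(frame=frame, n_control=len(ctrl_tables),
                            n_treated=len(trt_tables),
                            meta={"threshold": cfg.positivity_threshold,
                                  "fsc_bounds": list(gates.fsc_bounds)})
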