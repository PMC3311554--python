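"""Synthetic data: bead standards, triple-labelled retinal samples, flatmounts.

The retina generator emulates the measured structure of a dissociated-retina
acquisition: three log-normal RGC soma-size classes plus non-RGC
contaminants, log-normal FG/thy-1 intensities with class-specific geometric
means, forward spillover between the fluorescence channels (the exact
algebraic inverse of the compensation step, so compensation correctness is
testable as inversion), a TUNEL-positive subpopulation, and a treatment arm
with planted per-class survival fractions and intensity attenuations.
FSC values are produced by pushing each soma area through the same
area -> D_a -> D_v -> FSC chain the analysis inverts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import (LinearCalibration, PAPER_2012_BEAD, PAPER_2012_BRIDGE)
from .events import EventTable, FlatmountImage, SpilloverSettings
from .flatmount import area_to_diameter, diameter_to_area

logger = logging.getLogger(__name__)


class PlacementError(RuntimeError):
    """Requested flatmount density cannot be placed without overlap."""


@dataclass(frozen=True)
class RetinaSimConfig:
    """Planted truth for a simulated dissociated-retina acquisition.

    Class-level defaults are the control-condition study values: RGC class
    proportions 83.31 / 10.42 / 6.26 % (small/medium/large), FG geometric
    means 19.39 / 27.40 / 35.44, non-RGC contamination 5.31% of thy-1+ cells
    (FG-/thy1+) and 2.05% of FG+ cells (FG+/thy1-), 10,000 events per
    sample. Distribution shapes (log-sds), thy-1 geometric means, the RGC
    fraction of total events, and the TUNEL fraction are free parameters the
    study does not pin down; defaults are documented in the methods note.
    """

    n_events: int = 10_000
    seed: int = 0
    #: fraction of all acquired events that are RGCs (FG+/thy1+)
    rgc_fraction: float = 0.25
    class_proportions: tuple[float, float, float] = (0.8331, 0.1042, 0.0626)
    fg_geomeans: tuple[float, float, float] = (19.39, 27.40, 35.44)
    thy1_geomeans: tuple[float, float, float] = (24.0, 33.0, 43.0)
    intensity_log_sd: float = 0.25
    #: soma-area class intervals (um^2); large capped for sampling
    area_bounds_um2: tuple[float, float, float] = (15.0, 70.0, 125.0)
    area_max_um2: float = 400.0
    area_log_sd: float = 0.35
    #: contamination rates, as fractions of the positive-axis parents
    thy1_only_rate: float = 0.0531
    fg_only_rate: float = 0.0205
    #: negative-region and off-axis intensity scale
    negative_geomean: float = 2.0
    negative_log_sd: float = 0.5
    tunel_fraction: float = 0.05
    tunel_pos_geomean: float = 50.0
    tunel_pos_log_sd: float = 0.3
    #: FSC measurement noise (coefficient of variation)
    fsc_cv: float = 0.02
    planted_bridge: LinearCalibration = PAPER_2012_BRIDGE
    planted_bead: LinearCalibration = PAPER_2012_BEAD
    spillover: SpilloverSettings = field(default_factory=SpilloverSettings)
    #: treatment block: per-class survival and intensity attenuation factors
    survival: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fg_attenuation: tuple[float, float, float] = (1.0, 1.0, 1.0)
    thy1_attenuation: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.rgc_fraction < 1:
            raise ValueError("rgc_fraction must be in (0, 1)")
        p = np.asarray(self.class_proportions, float)
        if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=5e-3):
            raise ValueError("class proportions must be non-negative and sum to 1")
        for name in ("survival", "fg_attenuation", "thy1_attenuation"):
            v = np.asarray(getattr(self, name), float)
            if np.any(v <= 0) or np.any(v > 1):
                raise ValueError(f"{name} factors must lie in (0, 1]")
        if any(g <= 0 for g in self.fg_geomeans + self.thy1_geomeans):
            raise ValueError("geometric means must be positive")
        if self.fsc_cv < 0:
            raise ValueError("fsc_cv must be non-negative")


def paper_nmda_config(**overrides) -> RetinaSimConfig:
    """The 'paper-NMDA' treated-arm scenario.

    Survival: small 58.74% (stated directly), medium 61.7% (ratio of the
    treated to control medium-class normalized frequencies, 6.43/10.42),
    large 100% (no significant loss). FG attenuation 90.96/69.62/69.68%,
    thy-1 attenuation 91.78/69.07/69.91%.
    """
    base = dict(
        survival=(0.5874, 0.617, 1.0),
        fg_attenuation=(0.9096, 0.6962, 0.6968),
        thy1_attenuation=(0.9178, 0.6907, 0.6991),
    )
    base.update(overrides)
    return RetinaSimConfig(**base)


def _truncated_lognormal(rng: np.random.Generator, median: float, log_sd: float,
                         lo: float, hi: float, n: int) -> np.ndarray:
    """Log-normal(ln median, log_sd) conditioned on [lo, hi) by inverse CDF."""
    from scipy.stats import norm

    a = norm.cdf(np.log(lo / median) / log_sd)
    b = norm.cdf(np.log(hi / median) / log_sd)
    u = rng.uniform(a, b, size=n)
    return median * np.exp(log_sd * norm.ppf(u))


def _forward_spillover(true_fl: np.ndarray, settings: SpilloverSettings) -> np.ndarray:
    """Mix true intensities into raw channel signals.

    Solves M raw = true for the compensation matrix M, so that
    :func:`rgcflow.pipeline.apply_compensation` recovers the true values
    exactly (no clipping occurs for non-negative truths with the default
    coefficients).
    """
    inv = np.linalg.inv(settings.as_matrix())
    return true_fl @ inv.T


def generate_bead_sample(
    diameters_um: Sequence[float] = (6.0, 10.0, 15.0, 20.0),
    bead_cal_true: LinearCalibration = PAPER_2012_BEAD,
    cv: float = 0.03,
    n: int = 10_000,
    seed: int = 0,
    replicates: int = 1,
) -> dict[float, list[EventTable]]:
    """Simulate FSC acquisitions of polystyrene microsphere standards.

    Each bead population's FSC is Normal(mean, cv * mean) truncated at 0,
    with the mean given by inverting the planted bead line at the bead
    diameter. Returns diameter -> list of replicate event tables.
    """
    if cv < 0:
        raise ValueError("bead noise cv must be non-negative")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    out: dict[float, list[EventTable]] = {}
    for d in diameters_um:
        mean = float(bead_cal_true.invert(d))
        reps = []
        for _ in range(replicates):
            fsc = np.maximum(rng.normal(mean, cv * mean, size=n), 0.0) if cv > 0 \
                else np.full(n, mean)
            frame = pd.DataFrame({
                "FSC": fsc, "SSC": np.zeros(n),
                "FL1": np.zeros(n), "FL2": np.zeros(n), "FL3": np.zeros(n)})
            reps.append(EventTable(frame))
        out[float(d)] = reps
    logger.info("generated bead samples for %d diameters (cv=%.3f, n=%d)",
                len(out), cv, n)
    return out


def _sample_class_areas(rng: np.random.Generator, cfg: RetinaSimConfig,
                        cls: np.ndarray) -> np.ndarray:
    lo = list(cfg.area_bounds_um2) + [cfg.area_max_um2]
    areas = np.empty(cls.shape[0], dtype=float)
    for i in range(3):
        mask = cls == i
        if not mask.any():
            continue
        median = float(np.sqrt(lo[i] * lo[i + 1]))
        areas[mask] = _truncated_lognormal(rng, median, cfg.area_log_sd,
                                           lo[i], lo[i + 1], int(mask.sum()))
    return areas


def generate_retina_sample(
    cfg: RetinaSimConfig,
    arm: Literal["control", "treated"] = "control",
    seed: int | None = None,
) -> tuple[EventTable, pd.DataFrame]:
    """Simulate one triple-labelled retinal acquisition.

    Returns the (uncompensated) event table and a ground-truth frame with
    one row per emitted event: planted population label, size class, soma
    area, true (pre-spillover) intensities and TUNEL state. In the treated
    arm each RGC size class is thinned by its survival fraction and its
    intensities are attenuated by the planted factors, so the treated table
    holds fewer events than ``cfg.n_events`` — the acquisition-side
    surrogate for an absolute (hemacytometer-scaled) cell count.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_events
    n_rgc = int(round(n * cfg.rgc_fraction))
    n_thy1_only = int(round(n_rgc * cfg.thy1_only_rate / (1 - cfg.thy1_only_rate)))
    n_fg_only = int(round(n_rgc * cfg.fg_only_rate / (1 - cfg.fg_only_rate)))
    n_negative = n - n_rgc - n_thy1_only - n_fg_only

    props = np.asarray(cfg.class_proportions, float)
    props = props / props.sum()

    records = []

    def emit(population: str, cls_idx: int | None, area: float,
             fg: float, thy1: float, tunel: bool, tunel_int: float) -> None:
        records.append((population, cls_idx, area, fg, thy1, tunel, tunel_int))

    def intensities(geomeans, cls, attenuate) -> np.ndarray:
        g = np.asarray(geomeans, float)[cls]
        if attenuate is not None:
            g = g * np.asarray(attenuate, float)[cls]
        return g * np.exp(rng.normal(0.0, cfg.intensity_log_sd, size=cls.shape[0]))

    def negative_like(size: int) -> np.ndarray:
        return cfg.negative_geomean * np.exp(
            rng.normal(0.0, cfg.negative_log_sd, size=size))

    treated = arm == "treated"
    prefix = {0: "s", 1: "m", 2: "l"}

    # --- RGCs (FG+/thy1+), thinned per class in the treated arm ---
    cls = rng.choice(3, size=n_rgc, p=props)
    if treated:
        keep = rng.random(n_rgc) < np.asarray(cfg.survival, float)[cls]
        cls = cls[keep]
    areas = _sample_class_areas(rng, cfg, cls)
    fg = intensities(cfg.fg_geomeans, cls, cfg.fg_attenuation if treated else None)
    thy1 = intensities(cfg.thy1_geomeans, cls,
                       cfg.thy1_attenuation if treated else None)
    tunel = rng.random(cls.shape[0]) < cfg.tunel_fraction
    tunel_int = np.where(
        tunel,
        cfg.tunel_pos_geomean * np.exp(rng.normal(0, cfg.tunel_pos_log_sd,
                                                  cls.shape[0])),
        negative_like(cls.shape[0]))
    for i in range(cls.shape[0]):
        emit(f"{prefix[int(cls[i])]}-RGC", int(cls[i]), areas[i], fg[i], thy1[i],
             bool(tunel[i]), tunel_int[i])

    # --- non-RGC contaminants: single positives with the same size machinery ---
    for pop_n, pop_kind in ((n_thy1_only, "thy1_only"), (n_fg_only, "fg_only")):
        cls_nr = rng.choice(3, size=pop_n, p=props)
        areas_nr = _sample_class_areas(rng, cfg, cls_nr)
        pos = intensities(cfg.thy1_geomeans if pop_kind == "thy1_only"
                          else cfg.fg_geomeans, cls_nr, None)
        neg = negative_like(pop_n)
        tun = negative_like(pop_n)
        for i in range(pop_n):
            fg_i, thy_i = ((neg[i], pos[i]) if pop_kind == "thy1_only"
                           else (pos[i], neg[i]))
            emit(f"{prefix[int(cls_nr[i])]}-NR", int(cls_nr[i]), areas_nr[i],
                 fg_i, thy_i, False, tun[i])

    # --- negative region: unlabelled retinal cells / debris ---
    areas_neg = 30.0 * np.exp(rng.normal(0.0, cfg.negative_log_sd, n_negative))
    fg_neg, thy_neg, tun_neg = (negative_like(n_negative) for _ in range(3))
    for i in range(n_negative):
        emit("negative", None, areas_neg[i], fg_neg[i], thy_neg[i], False,
             tun_neg[i])

    truth = pd.DataFrame(records, columns=[
        "population", "size_class", "area_um2", "fg_true", "thy1_true",
        "tunel", "tunel_true"])
    # shuffle so event order carries no population information
    truth = truth.sample(frac=1.0, random_state=rng.integers(2**31)
                         ).reset_index(drop=True)

    d_a = area_to_diameter(truth["area_um2"].to_numpy())
    d_v = cfg.planted_bridge.predict(d_a)
    fsc_true = cfg.planted_bead.invert(d_v)
    fsc = fsc_true * (1.0 + rng.normal(0.0, cfg.fsc_cv, len(truth))) \
        if cfg.fsc_cv > 0 else fsc_true
    fsc = np.maximum(fsc, 0.0)

    true_fl = np.column_stack([truth["tunel_true"], truth["fg_true"],
                               truth["thy1_true"]]).astype(float)
    raw_fl = _forward_spillover(true_fl, cfg.spillover)
    frame = pd.DataFrame({
        "FSC": fsc,
        "SSC": fsc * 0.6 * np.exp(rng.normal(0.0, 0.3, len(truth))),
        "FL1": np.maximum(raw_fl[:, 0], 0.0),
        "FL2": np.maximum(raw_fl[:, 1], 0.0),
        "FL3": np.maximum(raw_fl[:, 2], 0.0),
    })
    table = EventTable(frame, compensated=False)
    logger.info("generated %s-arm retina sample: %d events (%d RGC)",
                arm, table.n_events, int(truth["population"].str.endswith("RGC").sum()))
    return table, truth


def generate_flatmount_image(
    density_per_mm2: float = 1866.0,
    diameter_geomean_um: float = 6.2,
    diameter_log_sd: float = 0.35,
    diameter_min_um: float = 3.5,
    field_um: tuple[float, float] = (200.0, 200.0),
    scale_um_per_px: float = 0.5,
    foreground: float = 200.0,
    background_noise_sd: float = 0.0,
    seed: int = 0,
    max_tries_per_cell: int = 200,
) -> tuple[FlatmountImage, pd.DataFrame]:
    """Render one flatmount field of bright, non-overlapping somata.

    The soma count is Poisson at the requested density; diameters are
    log-normal, truncated below at ``diameter_min_um`` (no real soma is
    smaller than a few micrometres, and sub-resolution disks would vanish
    into the detector's noise floor). Somata are rasterised as filled disks of intensity
    ``foreground`` on a zero background (optionally with Gaussian noise,
    clipped at 0). Returns the image and a ground-truth frame with planted
    centroids (um), radii and disk areas.
    """
    if density_per_mm2 < 0:
        raise ValueError("density must be non-negative")
    rng = np.random.default_rng(seed)
    w_px = int(round(field_um[0] / scale_um_per_px))
    h_px = int(round(field_um[1] / scale_um_per_px))
    img = np.zeros((h_px, w_px), dtype=float)
    area_mm2 = field_um[0] * field_um[1] / 1e6
    n = rng.poisson(density_per_mm2 * area_mm2)

    placed: list[tuple[float, float, float]] = []
    truth_rows = []
    for _ in range(n):
        d = 0.0
        while d < diameter_min_um:
            d = diameter_geomean_um * np.exp(rng.normal(0.0, diameter_log_sd))
        r_px = (d / 2.0) / scale_um_per_px
        for _try in range(max_tries_per_cell):
            cx = rng.uniform(r_px, w_px - r_px)
            cy = rng.uniform(r_px, h_px - r_px)
            if all((cx - x) ** 2 + (cy - y) ** 2 > (r_px + r + 1.0) ** 2
                   for x, y, r in placed):
                break
        else:
            raise PlacementError(
                f"could not place soma {len(placed) + 1}/{n} at density "
                f"{density_per_mm2}/mm^2 without overlap")
        placed.append((cx, cy, r_px))
        yy, xx = np.ogrid[:h_px, :w_px]
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px ** 2
        img[disk] = foreground
        truth_rows.append({
            "centroid_x_um": cx * scale_um_per_px,
            "centroid_y_um": cy * scale_um_per_px,
            "radius_um": d / 2.0,
            "area_um2": diameter_to_area(d),
            "pixel_area_um2": int(disk.sum()) * scale_um_per_px ** 2,
        })
    if background_noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, background_noise_sd, img.shape), 0, None)
    truth = pd.DataFrame(truth_rows, columns=[
        "centroid_x_um", "centroid_y_um", "radius_um", "area_um2",
        "pixel_area_um2"])
    image = FlatmountImage(img, scale=scale_um_per_px, field_um=field_um)
    logger.info("rendered flatmount field with %d planted somata", len(truth))
    return image, truth
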