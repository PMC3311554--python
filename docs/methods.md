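# Methods

## Model and assumptions

The package treats RGC sizing as a chain of three monotone maps between
four "currencies": projected soma area *A* (µm², imaging), area diameter
*D_a* = 2√(*A*/π) (µm), apparent volume diameter *D_v* (µm, cytometry) and
forward scatter FSC (instrument units).

* **Bead line** (`role="bead"`): diameter regressed on mean FSC of
  microsphere standards, *d* = slope·FSC + intercept, by ordinary least
  squares with a free intercept. Mean FSC per bead population is the mean
  of replicate means when replicates are supplied. The line is assumed
  valid over the cellular FSC range (extrapolation below the smallest bead
  is accepted; FSC is linear-acquired).
* **Bridge line** (`role="bridge"`): apparent *D_v* regressed on *D_a*
  after matching the two size distributions at the same cumulative
  percentiles Q. The underlying assumptions are (i) dissociation does not
  change the size ordering or distribution of the population, and (ii) the
  bead-vs-cell scattering difference (refractive index, shape) is
  well-approximated as affine over the sizes of interest. No Mie-scatter
  physics is attempted.
* **Percentiles** everywhere are linear interpolation between closest
  ranks (numpy's default, the "type 7" convention). This matters: the
  bridge pairs, and therefore the gates, change slightly under other
  conventions.

Compensation follows the instrument-panel reading of pairwise spillover
labels: "FLi−%FLj: c" subtracts c% of channel j's **raw** signal from
channel i, all four corrections computed simultaneously (a single matrix
multiply), negatives clipped to 0. The synthetic generator's forward
mixing step is the exact algebraic inverse of this matrix, which makes
compensation testable as an inversion rather than against itself.

Statistics mirror standard practice in the field: geometric means for
log-acquired fluorescence (zeros floored at 0.1 intensity units before the
log; configurable), SEM across replicate animals, and the classic
pooled-variance two-sided Student's t-test (not Welch) for control vs
treated comparisons.

## Parameters that matter

| Parameter | Default | Units | Why |
|---|---|---|---|
| positivity threshold | 10 | intensity | the negative region is the first log decade; positive is ≥ threshold (closed) |
| quantiles Q | 5, 20, 40, 60, 80, 95 | % | percentile set used for distribution matching |
| area class bounds | 15, 70, 125 | µm² | minimum soma area and small/medium, medium/large bounds (D_a 9.44 / 12.62 µm) |
| imaging diameter bounds | 9.4, 12.6 | µm | flatmount classification; medium interval closed ([9.4, 12.6]) so boundary ties are never dropped |
| histogram bin width | 2 | µm | soma-size histograms, left-closed bins from 0 |
| events per sample | 10,000 | — | standard acquisition depth |
| spillover | 0.7, 20.0, 0.0, 17.5 | % | FL1−%FL2, FL2−%FL1, FL2−%FL3, FL3−%FL2 (three-colour CaliBRITE values) |
| geomean floor | 0.1 | intensity | log-domain safety for clipped zeros |

## Gate-derivation rounding

`derive_fsc_gates` propagates unrounded intermediates by default and rounds
only final reported values (2 dp for µm, nearest integer for FSC). This is
the canonical behaviour because rounding inside the chain compounds:
e.g. the 125 µm² bound gives FSC 600.42 → 600 unrounded but 601 when D_a
and D_v are first rounded to 2 dp. `round_intermediates=True` reproduces
the 2-dp-rounded convention of the published conversion table (gates
411/601), and `fsc_rounding="truncate"` additionally reproduces its lowest
bound (108 = trunc(108.52)); both are compatibility conventions, not
recommendations. When re-fitting the bridge from 2-dp-rounded pairs the
intercept lands at −1.93 rather than the preset's −1.94 — a pure rounding
artefact of the tabulated inputs, which is why the preset, not a refit, is
the shipped `paper-2012` bridge.

## What the synthetic generator emulates

`generate_retina_sample` draws, per event: a population (RGC fraction 0.25
of events; class proportions 83.31/10.42/6.26% of RGCs; thy-1-only
contaminants at 5.31% of thy-1+ cells and FG-only at 2.05% of FG+ cells;
the remainder negative), a soma area (class-conditional log-normal
truncated to the class's area interval, log-sd 0.35; large class capped at
400 µm²), an FSC value (the planted bead+bridge chain applied to the area,
times 2% multiplicative Gaussian measurement noise), and fluorescence
intensities (log-normal; FG geometric means 19.39/27.40/35.44 by class,
thy-1 24/33/43; log-sd 0.25; off-axis and negative-region channels
log-normal around 2). A TUNEL-positive fraction (default 5%, identical in
both arms) gets FL1 around geometric mean 50. The treated arm thins each
RGC class by its survival fraction and multiplies its FG/thy-1 geometric
means by the attenuation factors; the shipped `paper-nmda` preset plants
survival 58.74/61.7/100% and attenuations 90.96/69.62/69.68% (FG) and
91.78/69.07/69.91% (thy-1). Because the treated table simply contains
fewer events, absolute survival is recoverable from event counts alone —
the generator's stand-in for the hemacytometer total-cell scaling that
absolute densities require in practice.

Free parameters the study conditions do not pin down — the intensity and
area log-sds, thy-1 geometric means, RGC fraction, TUNEL rate, FSC
measurement CV — were fixed once at values realistic for a benchtop
three-colour acquisition of dissociated retina and are documented above;
they are configuration, not fitted quantities.

What the generator does **not** emulate: doublets and debris aggregates,
log-amplifier binning artefacts, autofluorescence spectra, instrument
drift between samples, spatial sampling bias across the retina, and
touching somata in flatmount fields (disks are placed without overlap, and
a minimum soma diameter of 3.5 µm keeps every planted cell above optical
and detector floors). Passing recovery tests therefore demonstrate the
pipeline's correctness on well-behaved data, not robustness to these
real-world effects.

## Numerical choices and degenerate inputs

* Line fits require ≥ 2 distinct x values; all-identical x raises
  `DegenerateFitError`. A perfectly flat y returns r = 1 by convention
  (collinear input).
* Size gates are half-open [lo, hi): boundary events go to the upper
  class. Events below the small gate's lower FSC bound are `unclassified`
  debris and excluded from class statistics.
* The quadrant threshold is closed on the positive side (≥ 10).
* Empty flatmount images yield zero detections (not an error); empty
  percentile/geomean inputs raise.
* Soma detection uses Otsu's global threshold by default (deterministic,
  parameter-free) with an optional fixed 8-bit level; 8-connectivity;
  minimum area 5 µm². No watershed splitting of touching somata — a known
  limitation; merged somata count once with the union area.
* t-tests with zero pooled variance return (0, 1) when the group means
  agree (identical groups) and raise otherwise.
* CSV round trips are bit-exact (shortest-round-trip float formatting on
  write, `round_trip` parsing on read).

## Problem sizes

The test suite runs the full recovery check at the study scale — 6
replicate pairs of 10,000 events — and smaller property checks at
500–5,000 events; the null-treatment calibration check uses 30 seeds at
2,000 events. Flatmount recovery uses 12 simulated 200×200 µm fields at
the control density of 1866 cells/mm².

## Known limitations

* FCS support is read-only and covers the common list-mode subset
  ($DATATYPE F/D/I, $MODE L); dual-laser spectral files and the doubled
  escaped-delimiter convention are rejected explicitly.
* Compensation is the four-coefficient pairwise scheme of a three-colour
  instrument, not a general spectral unmixing.
* The bridge is a population-level affine correction; it cannot correct
  per-cell scattering differences, so single-event diameters remain
  apparent, and only distribution-level (percentile, gate) statements are
  supported.
* Whether TUNEL-positive events should be excluded from the "live RGC"
  intensity statistics is a judgment call; the default excludes nothing,
  and `exclude_tunel` (CLI `--exclude-tunel`) restricts the geometric
  means — but never the counts or TUNEL fractions — to TUNEL-negative
  events.
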