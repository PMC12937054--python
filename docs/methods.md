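# Methods

This note documents the models, conventions and numerical choices
behind `cellogram`, and what the simulation-based validation does and
does not demonstrate.

## The cellogram model

A touch-down direct-infusion acquisition is modelled as an ordered
list of centroided MS1 scans with retention times in minutes.  Each
sampled cell contributes a transient to every endogenous ion's
chronogram: a fast rise (the probe contacts the cell) followed by an
exponential decay (the metabolome is exhaustively extracted), after
which the trace returns to background until the next cell.  Between
cells the spectrometer sees only solvent/contaminant background.

## Event detection

Detection operates on the EIC of a user-chosen, highly abundant
endogenous **cell marker** (e.g. protonated choline at m/z 104.107 in
positive mode).  Parameters:

* `ppm_tol` (default 5 ppm) — EIC extraction tolerance, suitable for
  ~240k-resolution FTMS data.
* `sn_threshold` — trigger threshold on S/N (or on absolute intensity
  in intensity mode).  Too high loses faint cells; too low splits
  peaks, which is countered by a longer refractory period — the two
  are interdependent.
* `refractory_period` (minutes) — minimum spacing between triggers,
  measured from the previous trigger.  At 3 cells/min a value around
  half the cell spacing (0.15 min) is a good default.
* `background_scans` (default 10) — scans before the trigger that form
  the per-cell background window.
* `pre_extension_scans` (default 0) — optional extension of the event
  window to scans preceding the background, for species that rise
  before the marker reaches threshold.

mzML files carry no vendor noise channel, so S/N uses a data-driven
noise scale: `1.4826 × median(|v − median(v)|)` over the EIC values
*below* the EIC median.  For a Gaussian baseline this recovers the
baseline standard deviation exactly (the factor 1.4826 × the
half-normal median 0.674 is 1) while the cell peaks above the median
cannot inflate it.  Degenerate traces (constant, or all zero) fall
back to the smallest positive value observed, or 1.0, so S/N is
always finite.  Because this estimator is not the vendor's, thresholds
optimised on vendor-format data do not transfer numerically.

Window conventions: the extended window of event *k* runs from its
(optionally pre-extended) background start to the start of event
*k+1*'s window, so extended windows tile the run without gaps or
overlap — with pre-extension this means an event's tail is shortened
in favour of its successor's head.  Threshold comparisons are
inclusive (≥) throughout.  Manual edits (adding or deleting triggers)
re-window and renumber with exactly the same rules; an added trigger
inside another trigger's refractory span is rejected to keep the
edited list consistent with the detection rule.

## m/z alignment

Grouping sorts all observations by m/z and walks left to right,
starting a new group when the candidate deviates from the current
group's running intensity-weighted mean by more than `ppm_tol`.
Sorting first makes the partition deterministic and independent of
input order; the weighted mean makes the representative m/z robust to
low-intensity stragglers (an unweighted variant is available).  On
well-separated species this greedy rule provably coincides with
single-linkage clustering cut at the tolerance, which the tests use as
an independent oracle; on overlapping clouds the two can differ — the
greedy rule splits where a chain drifts more than the tolerance from
the running mean.

Alignment is two-stage for speed: within each cellographic peak
(yielding one integrated intensity and m/z per species per cell), then
across the per-cell representatives.  Background-window centroids are
grouped alongside but flagged, so each event-level group knows its
background trace for the fold-change computation.  A cell's table
entry is its summed intensity over the peak window; absent features
are zero-filled (not NaN), because detection frequency downstream
counts FC-passing cells.  Multi-file alignment groups the per-file
representative m/z values and concatenates cells under file-qualified
ids; mixing polarities is refused.

## Filter cascade

Defaults: FC ≥ 3, DF ≥ 33%, isotopologue Δ = 1.003355 Th matched at
10 ppm with a maximum median intensity ratio of 0.6 (covers ~50-carbon
lipids at natural ¹³C abundance 1.1%/carbon; singly charged species
assumed), exclusion lists matched at 5 ppm, mass-defect ranges empty.
The cascade order — FC, DF, deisotoping, IS exclusion, MDF, blank
exclusion — applies the cheap, endogenous-safe filters first.  Design
points:

* When a species is absent from the background window (mean 0), FC
  falls back to the noise floor of the background trace rather than
  returning infinity, keeping FC comparable across species.
* DF counts cells whose FC passes, not mere nonzero detections.
* MDF is opt-in because useful fractional-mass windows are data-set
  specific, and a wrongly chosen window is the one filter that
  readily discards endogenous species.  Ranges are half-open and may
  wrap around 1.0.
* Every step is a pure function of (table, config) and idempotent;
  each step's output feature set is a subset of its input, so
  per-step counts are monotone non-increasing.

With truth labels the cascade reports percent retention per class —
on default simulations endogenous retention is 95–100% while
most background is removed.

## EIC image classification

Chronogram profiles fall into three visual classes: **high S/N**
(sharp event-locked peaks, baseline orders of magnitude below),
**low S/N** (event-locked peaks over an elevated background, less
than one order of magnitude of separation), and **background** (no
correlation with the cells: static, drifting, or spiking once or
twice in a way that mimics a cellographic peak).  The binary mapping
is fixed: high/low S/N → endogenous, otherwise background.

The renderer (version "1") draws the trace as a black 2-px polyline
on a white 224×224 canvas, x = scan index, y linear in [0, max] (max
treated as 1 for an all-zero trace), no axes or text.  Rendering is
byte-deterministic and invariant to intensity scaling — the classifier
sees shape only.  Models record the renderer version and refuse images
from another renderer.  An augmentation restricts an EIC to its first
*n* extended windows (n from 10 to ~100 in steps of 5): few events
render as broad Gaussian-like peaks, many as sharp centroid-like ones.

The reference model is a compact CNN in NumPy —
conv(8, 5×5, stride 2) → maxpool → conv(16, 3×3) → maxpool → fc(64) →
fc(3) on a 112×112 grayscale downsampling — trained with Adam
(lr 1e-3) and mini-batches of 64.  A stratified 30% of the training
data is held out for validation; validation runs every 30 iterations
and training stops early after 5 consecutive checks without a strictly
better validation loss, restoring the best checkpoint.  Anything
implementing the same small interface (`train_step`, `predict_proba`,
`get_state`/`set_state`, `hyperparams`) can be dropped in — e.g. a
transfer-learned backbone — without touching the pipeline.  Class
weighting is off by default (training sets are built near-balanced).
Prediction is argmax with exact ties resolved to background: a
flagged species stays out of the endogenous pool until a human
reviews it, and manual overrides retain the original prediction as
provenance.

## Synthetic cellograms

The generator's defaults encode the typical experiment: 100 cells at
3 cells/min, 2 Hz scans, m/z 75–1000, run length = cells/rate plus a
10% margin.  Species (separated by ≥ 30 ppm so alignment truth is
unambiguous; m/z jittered per scan by a 1.5 ppm Gaussian):

* 30 high-S/N species (the first pinned at m/z 104.107 as the cell
  marker, present in every cell), peak amplitude log-uniform 1e5–1e7,
  baseline 2.5–3.5 decades below the peaks;
* 30 low-S/N species, peak/baseline between 2× and 8× (10^0.3–10^0.9),
  present in 50–90% of cells;
* 15 static, 15 drifting (slow sinusoid plus linear trend) and 10
  spiking (one or two cell-like spikes, 10–100× their level)
  background species, plus 2 internal standards and 3 solvent blanks.
  Background species fluctuate with a per-species lognormal sigma of
  0.2–0.8 — heavy-tailed spray/contaminant behaviour that lets some
  background occasionally pass a fold-change filter, which is what
  makes the coverage/specificity trade-off (and the classifier's
  advantage) visible at all;
* 30% of endogenous species carry a ¹³C M+1 isotopologue at
  +1.003355 Th with ratio 0.011 × carbon count (carbons 5–40).

Cell transients rise over 2 scans and decay with τ = 3–6 scans,
tapering to zero by 10–16 scans (exhaustive extraction); per-cell
amplitudes vary lognormally (σ = 0.5 — biological heterogeneity has
no canonical distribution, so this is a configurable modelling
choice).  Centroids below a 50-count floor are dropped, as
a centroiding step would.  All randomness flows from the single
config seed; identical configs give byte-identical mzML.

What the simulator does **not** emulate: profile-mode peak shapes and
resolution-dependent widths, adducts and charge states > 1, ion
suppression and matrix effects, dopant chemistry, retention-free m/z
correlations among background ions, and real biological covariance
between metabolites.  Passing the simulation-based suites therefore
demonstrates the correctness and robustness of the *algorithms* under
controlled, realistic-scale conditions — not instrument-grade
performance on real data, which additionally depends on labels,
spray stability and species diversity not modelled here.

## Validation sizes and numerical conventions

The test suite and the acceptance script run at desk scale on one
CPU: default runs are 100 cells × ~4400 scans with ~105 species plus
isotopologues; detection recovery uses 10 seeds, pipeline recovery 5;
the classifier suite uses one run with 300 species per class (900
images, held-out 30% evaluation, a few minutes of training).
Reported percentages are computed, never stored.

Miscellaneous conventions: success rates round half-up to integer
percent; retention times are minutes internally whatever the mzML
unit; mzML is written with zlib-compressed 64-bit arrays; EIC
extraction windows are inclusive at both ppm edges; the greedy
grouping clamps a group's representative m/z into its member span to
guard against 1-ulp drift of the weighted mean; exact score ties in
classification go to background; quantification assumes a response
factor of 1 unless a measured per-target factor is supplied, and is
invariant to global intensity calibration.

## Known limitations

* Only centroided mzML is read; vendor formats must be converted
  (instrument noise/baseline channels are lost in conversion, hence
  the data-driven S/N).
* Optimised thresholds from vendor-format workflows do not transfer
  numerically to the MAD-based S/N.
* Deisotoping handles M+1 of singly charged species only.
* The greedy grouping is not claimed bit-identical to other
  ppm-alignment implementations on overlapping clusters; it is
  oracle-checked on separated data.
* The compact CNN is a desk-scale reference, not a tuned
  state-of-the-art backbone; on real instrument data a
  transfer-learned model behind the same interface is the expected
  upgrade path.
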