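# Methods

This note documents the models, parameter choices and numerical decisions
behind `photoloc`, and what the synthetic-data validation does and does not
establish about real recordings.

## Photometry normalization

The chain is fixed as: deinterleave → zero-phase Butterworth lowpass →
LOWESS detrend → robust z-score (each channel independently) → Huber
regression of the standardized isosbestic onto the standardized signal →
subtraction. Re-ordering is deliberately not offered; every stage logs its
parameters into the trace's processing log.

Parameter defaults and rationale:

| parameter | default | notes |
|---|---|---|
| filter order / cutoff | 4 / 5 Hz | lowpass smoothing of ~26 Hz channels; cutoff must stay below Nyquist |
| filter phase | zero-phase (filtfilt) | a causal filter would shift peri-event latencies by tens of ms; applied forward-backward, so the effective magnitude response is the squared Butterworth response |
| LOWESS span / iterations | 2/3, 3 | the classic lowess defaults; the baseline only needs to absorb bleaching and drift, which are much slower than the span |
| LOWESS delta | 1% of the time range | evaluation thinning; makes detrending O(n) in practice without visible change to the fit |
| MAD scale | 1.4826 | consistency with the standard deviation under normality; overridable |
| Huber tuning constant | 1.345 | 95% efficiency at the normal; IRLS, convergence on max coefficient change < 1e-8 or 50 iterations, scale by MAD of residuals |

Two consequences worth knowing:

* **Reference alignment.** Interleaved channels are sampled 1/78 s apart.
  The standardized reference is linearly interpolated onto the signal
  channel's timestamps before the fit; without this, motion bumps with
  ~50 ms rise times leave a visible residual (the shared artifact is
  evaluated at different instants in the two channels).
* **Session-mean absorption.** The LOWESS baseline and the median
  subtraction together remove the session-average activity level. Quantities
  built from z(dF/F) are therefore *relative*: compartment AUC/s contrasts
  are preserved (and that is what the discrimination ratio uses), but the
  absolute per-compartment AUC level is not meaningful on its own.

Non-finite input samples raise immediately; constant traces (MAD = 0)
raise a degenerate-input error rather than returning infinities.

## Behavior and peri-event quantification

* Compartment boundaries are half-open toward the center chamber: a point
  exactly on a side/center boundary is "center".
* Occupancy runs are debounced at 2 frames (single-frame tracking jitter
  does not create or destroy visits); override to 1 to disable. Unknown
  labels break runs, so a transition through "unknown" is never a full
  transition — the conservative reading.
* Entry time t0 is the first frame inside the destination.
* An entry is a *full transition* iff the run immediately before is center
  and the run before that is the opposite side. Only full transitions are
  admitted to peri-event extraction by default.
* Peri-event windows default to (−5 s, +5 s) with baseline (−5, 0) s —
  configurable; rows are linearly interpolated onto a uniform grid at the
  trace's native rate, and rows whose window exceeds the trace are dropped
  and counted, never padded.
* AUC is the trapezoidal integral of the linearly interpolated trace, with
  off-grid endpoints interpolated; it is exact for piecewise-linear
  signals with breakpoints on sample times. Negative AUCs are legitimate
  (z(dF/F) is signed); nothing is rectified.
* The Coc/Sal AUC Ratio divides per-second-normalized AUCs so that unequal
  occupancy cannot masquerade as a signal change. Raw (non-normalized)
  totals are returned alongside. The ratio is flagged invalid — not an
  exception — when either side is unoccupied or the saline-side AUC/s
  magnitude falls below a configurable floor (default 1e-3 z·units).
* Trace/track synchronization is a nearest-timestamp join; skew beyond one
  photometry sample period is an error (the acquisition systems are
  TTL-locked, so larger skew means a broken export).
* Stimulation bookkeeping windows open at side entry and close at
  min(entry + 300 s, exit); no entry, no window.

## Histology pipeline

Pixel convention: 0-based indices, pixel centers at integer coordinates,
polygons in continuous (x = column, y = row) units, interior membership by
pixel-center-in-polygon.

* Calibration resamples to 0.3785 µm/pixel (bilinear, output dims rounded).
* Preprocessing: white top-hat with a radius-10 disc, then 3×3 median with
  replicated borders, conceptually producing the 8-bit working images.
* The builtin segmenter thresholds (Otsu unless given), labels connected
  components, discards components under 30 px, and extracts sub-pixel
  contours. Touching cells can merge — a documented limitation; the
  Cellpose adapter is the production backend where available and is called,
  never re-implemented.
* Morphometrics are analytic on the polygon: shoelace area, arc-length
  perimeter, circularity 4πA/P², solidity A/A_hull, and aspect ratio from
  the eigenvalues of the polygon's exact second-moment covariance (the
  best-fit-ellipse axis ratio; a bounding-box variant would conflate
  orientation with elongation).
* Intensity: interior pixels vs a 3-px outward contour band. The band
  excludes the interiors of all other candidate ROIs by default, so a
  touching neighbor does not inflate the background estimate (switchable).
* QC comparisons are strict (>, <) for circularity, aspect ratio, solidity
  and the intensity rules; the area window [80, 1000] px is inclusive
  ("between" carries no strict operator). "Signal above background" is
  interior mean minus band mean by default, with a median variant behind a
  switch. Each rejection records the first failing rule in a fixed
  evaluation order, which makes the cascade auditable; the keep set itself
  is order-independent.
* Double-positive: strict frac(FOS in GFP) > 0.80; a FOS ROI matching
  several GFP ROIs counts once, attached to the maximal-overlap GFP ROI
  (prevents double counting in proportions).

## Region masks

Processing order: label (input label values are preserved when the mask is
already labeled; plain binary masks are connected-component labeled) →
optional concave-hull boundary fill (shapely `concave_hull`, ratio 0.3, on
boundary pixels; non-critical, it only pre-claims pixels inside a region's
outer outline) → nearest-label propagation → artifact floor.

Propagation assigns every unlabeled pixel within 100 px of an
*input-labeled* pixel the label of its nearest labeled pixel, using exact
Euclidean distances (a per-label distance transform) with ties going to the
lowest label id for determinism. Pixels farther than the cap stay
unlabeled. Because distances are measured from the drawn labels only, the
fill is a single pass: it is idempotent on masks whose unlabeled pixels are
either within the cap or beyond it by more than the cap again (the typical
drawing-seam geometry); on a mask with background at intermediate
distances, a second application would creep outward, which is why the cap
is always measured from the drawn mask.

The 2000 µm² artifact floor is likewise judged on the *drawn* area of each
region, then the region (including any gap pixels it claimed) is cleared —
otherwise a small artifact could rescue itself by annexing nearby gap
pixels. Densities use post-processing region areas; µm² conversion is
pixel_size² with the 0.3785 default.

ROI-to-region assignment is centroid lookup in the label raster; centroids
on background or outside the raster are "unassigned" and reported as such
in the tallies, so class counts always partition the ROI total.

## Synthetic data: what it emulates, and what it does not

* **Photometry.** F470(t) = B(t)·(1 + a·c(t) + m·g(t)) + ε and
  F415(t) = B′(t)·(1 + m·g(t)) + ε′, with exponential bleach envelopes
  (optionally different time constants per channel), instant-rise
  exponential-decay transients (decay 0.5 s) only at 470 nm, and shared
  biexponential motion bumps (rise 50 ms, decay 300 ms). Frames are emitted
  in the 470/560/415 cycle; the 560 slot carries an inert bleach trace.
  This forward model exercises the correction chain; it is a stand-in, not
  a claim about the true artifact physics, and it omits hemodynamic
  contamination, indicator nonlinearity and cross-talk.
* **Behavior.** A semi-Markov walk saline ↔ center ↔ cocaine with
  exponential dwells (floored at 2 frames) and a side-choice bias on
  leaving the center; direct side-to-side jumps never occur by
  construction, so glitch handling is tested with hand-built sequences.
* **Coupled sessions.** Transients arrive as a Poisson process (0.5 Hz in
  the validation runs) with amplitude scaled by the compartment at onset.
  Validation sessions are 20 minutes — the length of real pre/post tests —
  with a slow bleach constant (3000 s) appropriate to that duration and
  0.2% multiplicative noise.
* **Histology.** Disc-shaped cells (radius 9 px, area ≈ 254 px, inside the
  QC window) at ≥ 10 px separation; a seed-fixed round(n·fraction) subset
  of GFP cells receives a concentric smaller FOS disc (fully contained);
  FOS-only cells are placed clear of all GFP cells. Real tissue has
  touching cells, intensity gradients and non-disc morphologies; the
  noiseless recovery results bound the pipeline's bookkeeping correctness,
  not its segmentation performance on tissue.

All generators draw from a single seeded `numpy.random.Generator` per call:
identical configs and seeds are bit-identical.

## Validation problem sizes

The validation suite (and `scripts/acceptance.py`) uses: 20 photometry
sessions of 60 s for the normalization checks; 1,000 random label sequences
for the entry rule; 200 random polygon pairs at 10× supersampling for the
overlap oracle; one 512×512 histology image with 50 GFP cells for the
end-to-end recovery; and 100 seeds of paired 20-minute pre/post sessions
for the directional discrimination check. These sizes give each Monte-Carlo
check comfortable statistical power while keeping a full run in the
minutes range.

## Known limitations

* The builtin segmenter merges touching cells; use the Cellpose adapter for
  real tissue.
* The discrimination ratio inherits the relative-scale caveat above; its
  absolute magnitude depends on the session-mean absorption and should be
  compared within, not across, normalization settings.
* Region propagation semantics (single pass from drawn labels, k = 1
  nearest neighbor, lowest-label ties) are one concrete choice among the
  family of "kNN gap filling" procedures; alternatives with voting over
  k > 1 would differ only at near-equidistant seam pixels.
* The ImageJ ROI codec writes polygon-type ROIs with integer vertices; ROI
  types beyond polygons are rejected on read.
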