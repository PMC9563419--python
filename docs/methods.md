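# Methods

## Signal model

The analysis treats a high-speed laryngoscopy recording as a stack of T
RGB frames at frame rate `fps` (typically 2400 or 3200 fps). The
quantity analyzed is per-pixel *brightness over time* in the red
channel, which carries the strongest contrast between fold tissue and
the dark glottal gap; the blue channel serves only to flag specular
glare from the light source. During phonation a pixel on vibrating
mucosa shows an approximately periodic brightness function at the
fundamental frequency F0; a pixel on stiff (infiltrated) tissue shows
no harmonic component.

Spectra are one-sided DFTs of the mean-removed brightness function,
amplitudes scaled by `2/T` so a sinusoid of amplitude A at a bin center
reads as A. No taper window is applied by default (an optional Hann
window is available via `window="hann"`; amplitudes are then scaled by
`2/sum(w)`). Frequency resolution is `fps/T` (5 Hz at the default desk
scale of 2400 fps / 480 frames); peak positions are read at bin
resolution with no interpolation, so a bin-centered F0 is recovered
exactly and an off-bin F0 within half a bin.

## Pipeline

1. **Channels.** Red → analysis stack; blue → glare mask. A pixel is
   glare-flagged when its blue value is ≥ 250 in ≥ 50% of frames; the
   blue channel's role is established but no published rule exists, so
   this conservative, testable criterion was chosen. Flagged pixels are
   excluded from spectral analysis and the amplitude normalization.
2. **Registration.** Whole-frame integer translations between
   consecutive frames are estimated by normalized cross-correlation:
   the central template of the later frame (margins = `search_radius`,
   default 15 px) is matched at every placement within ±radius, with
   the NCC numerator computed by FFT and per-placement patch statistics
   by integral images. Plain circular FFT correlation was rejected: on
   scenes whose vibration pattern changes between frames it
   mis-registers by ~1 px, whereas overlap-normalized NCC recovers
   planted integer shifts exactly. Zero shift wins exact score ties, so
   featureless or identical frames register as unmoved. Cumulative
   offsets are removed by integer translation with zero-filled borders.
   Subpixel registration was deliberately left out: reported clinical
   jitter is "up to a dozen pixels" and integer correction suffices for
   bin-resolution spectra.
3. **Reference frame.** The maximum-opening frame is the one maximizing
   the count of dark pixels (below the stack's 25th intensity
   percentile) in the central half of the image — a proxy for glottal
   area that avoids full glottis segmentation. Ties take the smallest
   index. A landmark file may override the choice.
4. **Rotation.** The glottal axis is given by two marked endpoints;
   its inclination from the image vertical (counterclockwise positive,
   (−90°, 90°]) is removed by rotating every frame about the image
   center with bilinear interpolation and zero fill. Landmark nodes and
   the glare mask are transformed with the same rotation.
5. **ROI.** A periodic (closed) cubic B-spline with chord-length
   parameterization interpolates the up-to-20 marked fold-edge nodes;
   the densely sampled curve is rasterized by an even-odd scanline test
   at pixel centers, and the ROI is split at the axis column (centers
   left of or on the axis go left). Interpolation — the curve passes
   through the nodes — was chosen over control-point approximation
   because the nodes are marked *on* the fold edges. A consequence is
   that node influence is not strictly local: moving one node perturbs
   distant spans by a few percent of the perturbation (exponentially
   decaying plus a small global chord-length re-parameterization term).
6. **Maps and index.** The global F0 is the amplitude-weighted mode of
   per-pixel spectral peaks over the ROI within the analysis band
   (default 70–400 Hz, covering observed phonation F0 of 90–370 Hz);
   pixels whose peak amplitude is below `peak_floor` (default 1.0
   intensity unit) abstain — they carry no harmonic. Amplitude and
   phase maps are read at the bin nearest the global F0; amplitudes are
   normalized by their maximum over *analyzed ROI pixels* (not the
   whole frame, which would let glare or background corrupt the
   denominator). The vibrating mask collects pixels with normalized
   amplitude ≥ `amp_threshold` (default 0.1, the published cutoff). An
   optional strict mode additionally requires the pixel's own peak to
   lie within one bin of the global F0 (`f0_map` carries the per-pixel
   peaks for this purpose).
7. **SAI.** `SAI = 1 − (AVF_F0/AVF)/(NAVF_F0/NAVF)` from the fold and
   vibrating masks. The affected side is the clinically known lesion
   side when declared; `auto` picks the fold with the smaller vibrating
   fraction, which bounds SAI to [0, 1]. Declaring the wrong side can
   produce negative values, which are flagged rather than clipped. A
   non-affected fold with zero vibrating area makes the ratio
   undefined (bilateral non-vibration is outside the index's domain)
   and raises a degenerate-input error.
8. **Cross-check.** The glottal width waveform is the length of the
   dark-pixel run containing the axis column at the ROI-centroid row,
   per frame; its spectral peak (same estimator, floor 0.5 px) is an
   F0 estimate independent of the per-pixel route. On noiseless
   synthetic scenes the two agree within one bin across 90–370 Hz.
   This simplified dark-run kymogram exists purely as a cross-check,
   not as a clinical kymography replacement.
9. **Statistics.** Group comparisons use the two-sided Mann-Whitney U
   test: exact null distribution for groups of ≤ 20 (tied ranks
   enumerated as distinct, matching exhaustive-enumeration oracles),
   normal approximation with tie correction beyond. No multiple-testing
   correction is applied. Summaries report mean, sample SD, and range.

Every stage is a pure function of its inputs; a run is deterministic,
and identical inputs produce bit-identical numeric exports.

## Synthetic scenes

The generator renders what the method observes rather than simulating
tissue mechanics: two mirrored elliptical folds (red-channel baseline
150) flanking a dark glottal gap (intensity 10) on a mid-gray background
(70), imaged at 2400 fps. A *medial vibrating band* covering a
configurable fraction of each fold's area oscillates sinusoidally
(default amplitude 50 intensity units) at the common F0; that fraction
is the single knob controlling the expected SAI, and the returned ground
truth computes the expectation from the actual rasterized masks. The
medial edge of each vibrating fold excurses sinusoidally into the gap
(default 2 px), so the glottal width itself oscillates at F0 for the
kymographic route; the edge pixels that toggle between fold and gap
brightness are counted in that fold's vibrating area, keeping the index
bookkeeping exact. Static gap-core pixels split evenly by the axis and
cancel out of the vibrating-fraction ratio when fold areas are equal.
Optional nuisances: saturated glare spots, additive Gaussian noise,
axis tilt, and translation jitter modeled as a bounded random walk
(small per-frame steps, cumulative bound = configured magnitude) — like
slow camera drift, and guaranteeing consecutive-frame displacements stay
within the registration search window. Landmark nodes are placed
automatically a small margin outside the fold-region outline along 16
rays from its centroid.

The default desk scale — 128×128 px, 480 frames, 2400 fps, F0 150 Hz —
gives 5 Hz bins and seconds-level runtimes. Synthetic cohorts draw each
subject's target SAI from per-group Beta distributions moment-matched to
clinical summary statistics (normophonic 0.10 ± 0.07, benign
0.16 ± 0.13, malignant 0.65 ± 0.18), set the non-affected fraction
uniform in [0.85, 1], and derive the affected fraction from the index
definition. `sample_cohort_sai` realizes the same draws directly as
mask-level scenes for many-replicate statistical studies where rendering
video adds nothing.

What the phantom does *not* emulate: tissue deformation and mucosal-wave
propagation (vibration is brightness modulation in place), specular
highlights other than fixed saturated disks, endoscope rotation or
scale change, non-stationary phonation, and anatomical texture. Passing
recovery tests therefore demonstrates the correctness of the numerical
chain — registration, geometry, spectral estimation, index algebra — on
signals with the right structure and scale, not clinical validity on
real larynges.

## Numerical choices and degenerate inputs

- Ties in every argmax (registration scores, opening-frame counts,
  spectral peaks, weighted F0 votes) resolve to the smallest index /
  lowest frequency for determinism.
- Axis-split tie rule: pixel centers exactly on the axis column count
  as left.
- Rotation uses bilinear interpolation; a zero-angle axis bypasses
  interpolation entirely.
- Uniform stacks, static scenes (no spectral peak above the floor), and
  all-zero amplitude maps raise degenerate-input errors instead of
  returning empty results; a static scene has no defined F0, so the
  pipeline refuses rather than guesses.
- CSV grids are row-major, origin top-left, full precision, NaN for
  pixels outside the analyzed region; phase is written in radians.
  Summaries round SAI to 2 decimals; CSV keeps full precision.

## Known limitations

- Statistical power at clinical sample sizes: with 10 subjects per
  group, the exact Mann-Whitney test's discreteness alone rejects ~4–5%
  of identical-distribution comparisons, and any true benign/normal
  difference of the magnitude the group summaries imply is detected in
  a further ~5–10% of cohorts. Benign-vs-normophonic nonsignificance
  therefore holds in roughly 90% of simulated cohorts, not more — an
  intrinsic property of the design, not of the implementation.
- The simplified kymogram measures width at one row only (multi-row
  averaging is available behind a flag) and assumes a dark, roughly
  centered gap.
- Lossy video input is accepted but discouraged: compression perturbs
  per-pixel spectra; all quantitative tests use lossless frame
  directories.
- Left/right refer to image coordinates after vertical alignment;
  mapping to anatomical sides (endoscopic mirror inversion) is the
  caller's responsibility.
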