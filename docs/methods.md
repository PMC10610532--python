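# Methods

## Signal model and acquisition

The package models an ion-trap LC-MS/MS acquisition in which each
chromatographic time segment monitors one isomer group (one precursor
*m/z*) with two alternating MS/MS events: a low-excitation event whose
spectrum contains the surviving precursor (the reference ion, Ri) and a
high-excitation event containing the product-ion spectrum (Pis). The
bundled acquisition config uses two segments on the fast gradient —
precursor 353 (Ri scan 300–365 at ExA 15 a.u., Pis scan 95–250 at
25 a.u.) over 0–3 min for the mono-acyl isomers, and precursor 515
(450–530 at 10 a.u., 140–365 at 30 a.u.) over 3–7.5 min for the di-acyl
isomers, with isolation width 3 *m/z*, q 0.25 and excitation time 50 ms.
Event kind is classified by matching a scan's excitation amplitude to
its segment's two configured amplitudes after rounding to 0.1 a.u.,
rather than by scan order, so a dropped scan cannot desynchronize the
alternation.

Because the two events sample the eluting peak at different instants,
every product-ion scan is paired with a reference-ion abundance
*interpolated linearly* between the bracketing low-energy scans (nearest
value at segment edges). The interpolation error is
O((scan gap / peak σ)²): negligible for the broad peaks of a slow
gradient, and a deliberate, quantified approximation (up to ~1–2% per
scan at peak tails) for narrow fast-gradient peaks. Tests and the
characteristic-ratio workflow account for this explicitly (below).

All m/z matching sums peak abundances within a ±0.5 Th window
(unit-resolution trap); the reference-ion abundance is the summed
cluster signal in that window, since a monoisotopic-only reading is not
distinguishable at unit resolution.

## Breakdown curves

For an energy-resolved series (stepwise ExA ramp), survival yield and
product-ion formation are complementary fractions of the detected ion
current; grid points with zero total current are flagged and excluded,
never imputed. The pre-activation precursor level is the mean precursor
abundance over grid points with SY ≥ 95% — a quantitative proxy for
"before any fragmentation channel opens"; product-ion yield divides the
summed product abundances by that level and therefore exposes ion losses
(precursor ejection, products below the trap's low-mass cut-off).
`SY_ExA50` is the first downward 50% crossing of the survival curve,
linearly interpolated between grid points; `ExA_max` is reported on the
sampled grid (no interpolation), with ties broken toward the lower
amplitude — the same yield at less energy.

Note that the plateau mean sits slightly below the true pre-activation
level because the plateau includes points with up to 5% fragmentation;
on the default synthetic ramp this biases `PiY_max` upward by ≈0.4
percentage points, which the parameter-recovery tests bound.

## Deconvolution

Product ions enter the linear system only if their characteristic ratio
reaches the 2% threshold for at least one isomer; weaker ratios are
inside their own run-to-run variability (the shipped table's SDs are
±0.01) and would only add noise. Measured ratios are *not* thresholded —
the filter applies to the fingerprint, not the data. The resulting
system must remain overdetermined (rows ≥ isomers) or assembly fails.

The solver is active-set non-negative least squares without a sum-to-one
constraint: signal from unknown co-eluting species with the same
precursor and product ions must be representable, so an unexplained
remainder is reported as `unassigned` rather than forced onto the known
isomers. Under noise the fraction sum can overshoot 1; it is then
renormalized to 1 and flagged, while undershoot goes to the residual.
An optional 1/SD row weighting (from the fingerprint SDs) is available
but off by default, matching the unweighted form of the mixture
equation. Designs with condition number above 1e6 get a collinearity
flag; NNLS still returns a valid (minimum-residual) solution.

Scan-by-scan deconvolution apportions each paired point's Ri abundance
by the solved fractions, producing one reconstructed trace per isomer
plus a residual trace; the three always sum to the Ri trace exactly,
pointwise. Points whose Ri falls below 1% of the run's maximum are
treated as baseline: they are not solved (noise-only ratio vectors would
assign arbitrary fractions) and their Ri goes entirely to the residual,
preserving conservation. Peak-mode deconvolution integrates Pi and Ri
traces trapezoidally over a window and solves the vector of area ratios;
on noiseless data this equals the Ri-weighted mean of the scanwise
fractions (the solve is linear when all fractions are interior).

## Quantification

Peak areas on the reconstructed Ri traces are integrated trapezoidally
over configured per-isomer windows (no automatic peak detection: the
windows are method parameters, as in routine targeted analysis). One
shared 5-CQA external calibration curve converts areas to
working-solution concentrations for all six analytes — isomers ionize
with near-identical efficiency in ESI, making a single response factor a
reasonable compromise; per-analyte curves are supported but off by
default. The curve is an ordinary least-squares line over all replicate
points at the five levels 1.0–20.0 mg/L; LOD and LOQ use the
SE-of-intercept approach with factors 3.3 and 10. Concentrations below
zero after intercept subtraction are reported as 0 with a below-LOD
flag, never negative. Extract concentrations multiply by the dilution
factor (default 20, from 50 µL diluted to 1 mL); replicate SDs are
sample SDs across repeated analyses.

## Synthetic data

The run generator is the package's testing ground: Gaussian elution
peaks (optionally exponentially modified via a `tau` parameter, with
identical area, to stress integration), alternating events at a fixed
cadence of 0.6 s (≥15 paired points across a 0.2-min peak), per-isomer
product abundances equal to the isomer's Ri contribution times its
characteristic ratio, and independent multiplicative lognormal noise
with configurable CV on every recorded abundance — chosen because the
measured fingerprint SDs are roughly constant *relative* scatter across
signal levels. Generators are pure functions of (scenario, seed).

The ERMS generator uses a logistic survival curve (default midpoint
21 a.u., steepness 1/a.u., grid 0–50 in unit steps — matching observed
transitions from ~95% to ~5% survival over roughly 10 a.u.) with a
configurable ion-loss fraction removed from the fragmented signal before
splitting it across product ions.

Two reference scenarios ship with the package. `pure_isomer_scenario`
emulates the slow conventional-gradient measurement of a fingerprint:
one broad peak (σ 0.5 min) centered in its segment, evaluated over an
apex ± 1σ window, where the Ri interpolation bias is ~1e-4 relative —
this is the configuration under which characteristic-ratio round trips
reproduce the generating table to 1e-4 absolute. `acmella_like_scenario`
is a six-isomer fast-gradient run with narrow peaks (σ 0.05 min), 5%
noise, a 500-count baseline on the Ri channel, and the 4-CQA peak
co-eluting under a much larger 5-CQA peak.

What the generator does *not* emulate: isotope patterns, chromatographic
retention physics, ESI ionization/matrix effects, detector saturation,
and spectral interference from unrelated compounds. Passing tests
therefore demonstrate the correctness and noise behaviour of the
*algorithmic chain* (pairing → ratios → unmixing → reconstruction →
calibration), not robustness to real-matrix artefacts.

## Numerical choices and problem sizes

- m/z tolerance ±0.5 Th; ExA matching after rounding to 0.1 a.u.;
  retention times in minutes throughout; 0-based scan indexing.
- Internal run format: one CSV row per peak with scan metadata columns;
  scans without peaks keep a single blank-peak row so runs round-trip
  exactly (reads use round-trip float parsing).
- The mzML reader covers centroided MS2 spectra with 32/64-bit float
  arrays, plain or zlib-compressed, reading retention time, the
  isolation-window target (selected-ion m/z as fallback) and the
  activation collision energy; it is read-only.
- Monte-Carlo test sizes: 100 seeds for the 10:1 co-elution study,
  200 draws for fraction-error medians, 1,000 mixtures for the
  NNLS-vs-grid-search comparison at 0.001 simplex resolution; these
  sizes give stable statistics in seconds on one core.
- The exhaustive simplex search used to validate NNLS precomputes the
  design's image of all 501,501 grid compositions, making each query a
  single matrix-vector product.

## Known limitations

- Attribution follows the supplied ratio table; the method cannot
  discover an isomer absent from the table (its signal lands in the
  residual), and strongly collinear fingerprints limit resolution — the
  collinearity flag warns but cannot fix this.
- Per-scan ratio bias from Ri interpolation grows quadratically as peaks
  narrow relative to the scan cadence; with the default cadence, peaks
  narrower than ~3 s σ will show percent-level area biases.
- The calibration assumes equal response factors across isomers; a
  systematic ionization difference translates directly into a
  proportional concentration bias.
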