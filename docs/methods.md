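# Methods

This note records the models, parameter choices and numerical decisions
behind `myoelast`, and what the synthetic-data tests do and do not
demonstrate about real recordings.

## Forward model of an approach curve

A pixel is characterized by its true Young's modulus E and its surface
height, stored as the piezo position z₀ at tip–sample contact (larger =
taller; piezo extension increases toward the sample, positive deflection is
repulsive). The tip is an ideal rigid cone of half-opening angle α = 45°;
the sample is an incompressible (ν = 0.5) elastic half-space, so the load
is F = (2/π)·tanα·E/(1−ν²)·δ². Past contact the piezo travel splits between
indentation and cantilever deflection, z − z₀ = δ + F(δ)/k, a quadratic in
δ solved with the cancellation-stable root δ = 2s/(1 + √(1 + 4(c/k)s)).
The deflection record is F/k plus an optional linear drift
(`baseline_tilt_nm_per_um`) and additive Gaussian noise; the ramp is
truncated one sample after F first exceeds the trigger force, so the peak
simulated force never exceeds the trigger by more than one sample
increment. Retract segments are not modelled; all analysis uses the
approach. Hydrodynamic drag and viscoelasticity are not modelled (the
emulated acquisition uses a slow 1.2 Hz ramp precisely to suppress them);
the linear tilt stands in for residual drift. The ~30 nm tip radius is
ignored because typical indentations (hundreds of nm) are much larger —
a known limitation for the very first nanometres of contact.

Default acquisition parameters (all configurable): 25 × 100 grid over
10 × 80 µm, k = 30 pN/nm, 500 pN trigger, 3 µm ramp, 7 µm/s loading speed,
1024 samples per curve, 0.3 nm deflection noise, 305.15 K. The per-curve
sample count and noise level are simulator choices of realistic bench
values, not measured quantities. The approach window starts 500 nm before
contact, which leaves 2.5 µm of post-contact travel — enough to reach the
trigger at the softest modulus of interest (100 Pa).

## Phantoms and cohorts

A phantom is a half-cylinder tube (h(y) = √(r² − (y−y₀)²), axis along the
scan's long direction) on a flat substrate at height 0. Cell pixels draw
their moduli i.i.d. from a two-component Gaussian mixture
(w₁, μ₁, σ₁, μ₂, σ₂), left-truncated at 50 Pa by redrawing so every modulus
stays physical; substrate pixels take a stiff constant, default 100 kPa
(a collagen film). Default mixture (0.5, 557, 80, 1200, 150) Pa represents
a soft (myosin-rich) and a stiff (actin-rich) population at the scales of
thin wildtype myotubes. Cohorts draw one tube diameter per map from a
normal distribution (default mean 5.19 µm, sd 1 µm, floor 1.7 µm) and use
half of it as the tube radius, so the thin/wide width classification is
tied to simulated geometry. What the phantoms do **not** emulate: real cell
topography (ridges, nuclei), spatially correlated moduli, finite cell
thickness over the substrate (bottom effect), adhesion, and drift beyond a
linear tilt — parameter-recovery passes therefore validate the estimator
chain, not the realism of any particular biological claim.

## Per-curve analysis

1. **Baseline.** A straight line fitted by least squares to a pre-contact
   prefix is subtracted from the whole deflection record. The prefix length
   is chosen adaptively: candidate prefixes (≥ 32 samples) are scanned and
   the longest whose residual sd stays within 35% of a robust
   high-frequency noise estimate (MAD of first differences) is used — a
   prefix reaching into contact inflates its residual sd and is rejected.
   After a provisional contact is found, the baseline is re-fitted on the
   strictly pre-contact samples and the chain re-run once; this second pass
   removes the residual bias on very soft curves where contact sits early
   in the ramp.
2. **Contact detection.** Default: first index whose deflection exceeds
   n_σ × baseline sd (n_σ = 3) for ≥ 5 consecutive samples, with z₀
   interpolated at the threshold crossing. Alternative: sliding
   variance-ratio — the split maximizing the ratio of second moments about
   the corrected baseline level in w = 25-sample windows after/before; the
   second moment is taken about the baseline (not the window mean) so a
   step plateau still scores as signal.
3. **Force–indentation.** F = k(d − d₀), δ = (z − z₀) − (d − d₀), keeping
   δ ≥ 0. d₀ is zero by construction after baseline correction but remains
   explicit for externally corrected curves.
4. **Sneddon fit.** With contact fixed, E is the closed-form LS slope of F
   on δ² inside a relative force window (default 10–90% of peak force),
   rescaled by π(1−ν²)/(2 tanα). With refinement on (default), the contact
   offset is found by coarse grid search plus bounded scalar minimization
   of the **full-range** force RMSE — the pre-contact samples are what make
   the contact position identifiable — and E is re-estimated at the
   optimum. The refinement window is asymmetric (800 nm back, 100 nm
   forward of the detected crossing) because threshold detection on soft
   material fires well past true contact: at 557 Pa the deflection reaches
   3σ ≈ 0.9 nm only ~240 nm into the indentation.
5. **QC statuses.** `ok`, `low_indentation` (< 8 usable points or < 20 nm
   depth), `poor_fit` (non-positive slope, or force RMSE above
   max(5 pN, 2·k·baseline sd) — the cap tracks each curve's own noise),
   `no_contact`, and `excluded` (fitted modulus above the 100 kPa ceiling,
   marking substrate/collagen pixels). Automation replaces one-by-one
   manual curation; every decision is a flagged, auditable status.

**Precision.** Noiseless round trips recover E to < 10⁻⁵ relative across
0.1–100 kPa. At 0.3 nm noise the median modulus error is 1–3% per curve.
The contact position, however, has an intrinsic floor: the Fisher
information of a quadratic contact law with ~3 nm sample spacing and 9 pN
force noise bounds the per-curve contact sd at ≈ 0.8 nm on the stiff
substrate and several nm on soft (≤ 1 kPa) pixels. Topography is therefore
accurate to ~1–2 nm RMSE on stiff flat regions but ~10 nm per soft pixel,
and the *maximum* of a topography raster is biased upward by the max
statistic of those errors (a few tens of nm over a 100-pixel tube crest,
i.e. ~1% of a 2 µm tube).

## Maps and statistics

Topography is the per-pixel contact height re-zeroed so its 5th percentile
(the substrate) is 0 — the datum is configurable because the height scale
of a reconstruction from contact points has no absolute zero. Rasters are
row-major with pixel centers at (i + 0.5)·pitch. ROIs (cell body vs
projection) are explicit pixel sets supplied by configuration; no automatic
segmentation is attempted.

The per-map elasticity histogram uses Freedman–Diaconis binning by default
(fixed width optional) on values clipped to [0, 10 kPa] — out-of-range
values are counted separately, not silently dropped; bin edges follow the
occupied range so empty bins do not dilute the fit. The six-parameter
double Gaussian is fitted by bounded nonlinear least squares
(trust-region, tolerance 10⁻⁸, 500 iterations), seeded from a 25th/75th
percentile quantile split (2-means seeding optional); components are
re-ordered so μ₁ < μ₂. A binning-free EM fit on the raw sample
(two-component Gaussian mixture) is available as a cross-check. Fits with
overlapping components (|μ₂ − μ₁| smaller than the wider σ), a vanishing
weight (< 2%), or a collapsed σ (< 1 Pa) are flagged `degenerate` rather
than reported as bimodal. Histogram least squares is the default because it
matches how per-map distributions are conventionally summarized; its
binning sensitivity is exactly why the EM route exists.

Peaks aggregate across maps as mean ± SEM (n−1 variance); non-converged
maps are dropped with a logged count. Group comparisons use the two-sided
Mann–Whitney U test: full enumeration of rank assignments (midranks for
ties) when n₁ + n₂ ≤ 20, otherwise the tie-corrected normal approximation
with continuity correction; U = min(U₁, U₂) and the exact two-sided p is
the null probability that min(U₁, U₂) is at most the observed value.
Significance stars at 0.05/0.01/0.001; a comparison is flagged significant
when either peak differs. No multiple-testing correction is applied; the
comparison count is reported. The mean-comparison route runs an F-test for
equal variances first and selects the pooled or Welch t-test at α = 0.05.

Myotube widths get a per-group single-Gaussian histogram fit and a
thin/wide classification at the pooled median (per-group medians
optional); ties go to "thin" (≤ rule), which is what makes the split an
equal grouping.

## Reproducibility and problem sizes

All randomness flows from integer seeds through `numpy` SeedSequence
spawning (one stream per pixel/map), so identical (config, seed) give
identical arrays and byte-identical text outputs; HDF5 files are written
with `track_times=False`. The test suite and the acceptance script run
desk-scale problems — single curves, 25 × 100 maps (2500 curves), 200-curve
noise ensembles, 50–100 replicate statistical simulations — which are the
sizes at which the estimators' error floors are already visible and
stable.

## Known limitations

- Pure cone tip (no blunted-cone correction for the 30 nm apex radius).
- No bottom-effect correction for finite cell thickness over the stiff
  substrate; soft-pixel moduli over thin regions would be biased up on
  real cells.
- No adhesion/retract analysis and no viscoelastic (rate-dependent)
  modelling.
- Thermal spring-constant calibration implements the equipartition
  estimate only (configurable optical-lever correction factor, default 1.0,
  documented option 0.817); hydrodynamic (Sader-type) calibration is out of
  scope.
- Contact-point precision on soft material is physics-limited (see above):
  topography of sub-kPa regions carries ~10 nm per-pixel noise at the
  default acquisition settings.
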