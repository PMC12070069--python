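# Methods

## Measurement model

The pipeline's unit of measurement is an intensity line profile: per-channel
pixel values sampled along a user-defined segment across a banded expression
pattern, oriented medial→lateral.  Sampling is bilinear with a unit step:
positions run 0, 1, …, round(L) from the medial endpoint (L the Euclidean
segment length), and each sample may be the mean of `linewidth` bilinear
interpolations taken perpendicular to the segment (default `linewidth=1`,
a single-pixel line).  Bilinear interpolation is exact on locally linear
intensity fields; on curved fields (e.g. a Gaussian band of width σ sampled
at an angle to the pixel grid) it carries an O(curvature) error of order
`A/σ²` per pixel step, which the tests bound at ~1% of amplitude for σ ≈ 9.

Each profile is min–max normalized per channel over its own samples,
`v = (I − min)/(max − min)`, so replicate embryos imaged at different gains
and laser powers become comparable.  Normalization is per profile — not per
image — because the quantity of interest is the *shape* of the intensity
curve along one measured line; the (min, max) pair used is recorded in
`norm_params` so the choice is auditable.  A constant channel raises an
error naming the channel rather than silently emitting zeros: 0/0 has no
defensible default and almost always indicates a misplaced line.

## Alignment

Replicates cannot be averaged directly because each embryo's domain peaks
land at arbitrary positions along its measured line.  Per image, the
reference channel (averaged position-wise over that image's lines) is fitted
with a peaked curve

    v(x) = baseline + amplitude · exp(−(x − center)² / (2·width²))

by bounded least squares (`scipy.optimize.curve_fit`, trust-region
reflective).  Initialization is deterministic: baseline = min, amplitude =
max − min, center = position of the first maximum (smallest position wins
ties), width = ¼ of the sampled range; the center is constrained inside the
sampled range.  If the optimizer fails the argmax initialization is returned
with `converged=False`.  A Lorentzian peak is available through
`peak_model="lorentzian"` for heavier-tailed bands; the Gaussian default is
the natural peaked-exponential form for band-shaped domains.

The fitted center is rounded to the nearest integer pixel and subtracted
from all positions of all of that image's profiles, keeping every profile on
a shared integer lattice; the common grid is then the exact set intersection
of the shifted position sets, trimmed by construction to its own range.  A
sub-pixel mode (`subpixel=True`) shifts by the exact center and linearly
resamples onto the integer lattice instead; it is off by default because
integer shifting preserves raw sample values and makes end-to-end runs
byte-reproducible.

The average profile is, per channel and grid point, the mean over profiles
and its standard error `sd(ddof=1)/√n`.  With 5 replicates, jitter sd 3 px
and noise sd 0.02 (the shipped conditions) the fitted reference center is
recovered to ≲1 px, which is the resolution claim the acceptance tests
check.  Note the *raw argmax* of a broad, flat-topped mean profile is a
noisier statistic than the fitted center and can sit 1–2 px from 0.

## Domain metrics

The reference domain is the FWHM interval of the reference mean profile
around 0: the maximal contiguous run containing 0 where the
baseline-subtracted mean (baseline = grid minimum, consistent with the
min-based normalization upstream) is at least half its maximum, with
endpoints interpolated linearly between grid points.  FWHM is scale-free and
standard; for a Gaussian band it equals 2√(2 ln 2)·σ ≈ 2.355σ.

Query domains are the local maxima of the query mean with topographic
prominence ≥ `min_prominence` (default 0.1 normalized units, via
`scipy.signal.find_peaks`); standard topographic prominence measures a peak
against the *higher* of its two flanking minima and is therefore the more
conservative convention.

The overlap coefficient is the fraction of baseline-subtracted query signal
mass (floored at 0) inside the reference FWHM.  It is invariant to rescaling
the query amplitude and decreases monotonically as query bands move outward.
A query identical to the reference scores ≈0.761 (the mass of a Gaussian
inside its own FWHM).  The categorical call uses two explicit thresholds:
`overlapping` at coefficient ≥ t_hi (default 0.5), `flanking` at ≤ t_lo
(default 0.2) *and* query modes on both sides of 0 outside the FWHM,
otherwise `partial`.  The defaults separate the two shipped presets with a
wide margin (≈0.66 vs ≈0.01); the call is a geometric statement about
averaged 1-D profiles, never a claim about regulation, and the thresholds
are recorded in every output.

## Synthetic scenes

A scene renders each channel as `background + Σ_k A_k·exp(−(d−c_k)²/2w_k²)`
where `d` is the signed distance of a pixel along the medial–lateral axis
(bands are constant perpendicular to it, so ground truth stays analytic).
Per replicate, one rigid jitter shift ~ N(0, jitter_sd) moves all band
centers of all channels (embryo-to-embryo placement variation that preserves
within-embryo geometry); per z-slice, additive Gaussian noise ~ N(0,
noise_sd) truncated at 0 is applied independently.  All randomness flows
from one `numpy` Generator seeded by the config, so identical configs are
bit-identical.

Defaults: 96×200 px, 3 z-slices, 5 replicates, jitter sd 3 px, noise sd
0.02 with O(1) amplitudes (a small cohort of high-SNR confocal
projections).  The `stage13` preset pairs a reference stripe (center 100,
σ 14) with a broadly overlapping query (center 98, σ 16); `stage17` pairs a
narrow reference stripe (center 100, σ 8; FWHM half-width 9.4 px) with
query bands at 70 and 132 (σ 7), strictly outside the reference FWHM.

What the generator does *not* emulate: point-spread-function blur, photon
shot noise, bleaching, curved or tapering domains, segmentation error in
line placement, and biological amplitude variation beyond rigid jitter.
Passing tests therefore demonstrate that the measurement chain is correct
and well-calibrated under its stated model, not that the model captures
every property of real embryos.

## Statistics

* **Scoring**: percent affected is exact rational arithmetic before
  rounding; the confidence interval is Wilson's score interval (robust at
  the extreme proportions typical of scoring data, where the Wald interval
  degenerates), clipped to [0, 100] against floating-point overshoot.
* **ΔΔCt**: per replicate, ΔCt = Ct(gene) − Ct(reference gene); ΔΔCt is the
  difference of group means (treated − control); fold = 2^(−ΔΔCt) — the
  standard Livak formulation.  Adding a constant to all Ct values of a
  replicate cancels in the reference subtraction.
* **Fold-change test**: fold change of group means plus Welch's unpaired
  two-tailed *t*-test (the safer default when variances may differ; it
  reduces toward Student's under equal variances).  When both groups have
  zero variance the p-value is reported as exactly 0 (different means) or 1
  (equal means) with a `zero_variance` flag, rather than NaN.  Caveat:
  Welch's approximation is *conservative* at very small samples — at n = 3
  per group its true size at α = 0.05 is ≈0.035, not 0.05 (the package's
  null-simulation test documents this); Student's test is exact there when
  variances are equal, at the cost of robustness.

## Numerical and degenerate-input choices

* Argmax ties break toward the smallest position (determinism).
* Zero-length lines, endpoints outside the image, constant channels,
  profiles with <5 samples, empty common grids and missing reference
  channels/genes are all hard errors with the offending input named.
* CSV outputs are written with `%.17g` and read with round-trip float
  parsing, so every table survives a write/read cycle losslessly; TIFF
  stacks are float32 CZYX with a JSON sidecar declaring axes and labels.
* The run manifest records sha256 checksums of every data output;
  determinism is asserted on those checksums (the manifest itself carries
  timestamps, and the log file embeds paths).

## Problem sizes

The shipped test and acceptance workloads use 96×200×3 scenes, 5 replicates
per condition, 10-point offset sweeps, 8-point band-distance sweeps, 200
noisy peak-fit replicates and a 10,000-replicate null simulation — sizes at
which every check's sampling error is well below its decision margin.
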