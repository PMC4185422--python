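# Methods

## Scene model

`vesiflux.scenes.SceneSpec` describes a single-cell confocal field on an
anisotropic voxel grid, default (z, y, x) = (150, 25, 25) nm. Coordinates
are 0-based array order (z, y, x) with voxel centers at integers.

Vesicles are rendered as isotropic Gaussian spots in physical units
(σ = vesicle_radius/2, default radius 100 nm, so the FWHM roughly matches
the vesicle diameter) resampled to the voxel grid; each spot is normalised
so its voxel sum equals the drawn load exactly, which makes total-intensity
conservation testable to floating-point precision when PSF and noise are
disabled. The PSF is a per-axis Gaussian (default σ = (200, 80, 80) nm,
a high-NA confocal approximation); optics-accurate PSFs, spectral
bleed-through and time series are out of scope. Noise is scaled-Poisson
photon noise (`s · Poisson(I/s)`, default s = 2) followed by additive
Gaussian read noise (default SD 5) — the standard confocal approximation.
Residual plasma-membrane background is a constant intensity on the lateral
boundary shell of the elliptical cell mask. Macropinosomes are hollow
spherical shells (> 0.5 µm diameter, membrane label only, no cargo) drawn
at a Poisson rate of 0.02 per scene.

Per-vesicle loads: the defining channel draws N(60000, 8000) (clipped at
5% of the mean); cargo-positive vesicles draw N(30000, 6000) (clipped at
0), cargo-negative vesicles carry exactly zero cargo. The load Gaussian's
CV of 0.2 keeps the positive population well clear of zero, matching a
unimodal cargo-load histogram with a small separate cargo-negative peak.
The defining-channel brightness and cargo load are drawn independently, so
ground-truth scenes carry no brightness–cargo association.

Randomness uses one `SeedSequence` per scene with deterministically
spawned sub-streams (placement, defining loads, cargo draws,
macropinosomes, per-channel noise); forcing the cargo-positive fraction to
zero therefore leaves the defining channel bit-identical, which the
null-scene generator relies on.

A density guard warns (or errors, configurable) when the expected
nearest-neighbour spacing of vesicles, 0.554·ρ^(−1/3), falls below twice
the largest PSF sigma; beyond that point spot merging degrades
object-level ground truth.

### What the generator does and does not emulate

It reproduces the features the quantification machinery is sensitive to:
diffraction-limited puncta, anisotropic sampling, a Gaussian cargo-load
distribution with a cargo-free subpopulation, realistic photon/read noise,
membrane background and oversized macropinosomes. It does not emulate
vesicle motion, out-of-focus haze from deeper cell layers, detector gain
drift, or spatially varying background — so passing recovery tests shows
the pipeline is correct under the stated imaging model, not that it is
robust to every artefact of real microscopes.

## Pixel-mask co-localisation

Both channels are blurred with a Gaussian of σ = 0.7 px. "Base of the
histogram" is formalised as: take the histogram of the (blurred) channel
(1024 bins over the data range), find the modal (background) bin, scan
upward and return the left edge of the first bin whose count falls below
10⁻³ of the modal count. This reproduces the manual contrast-floor setting
with one continuous parameter and is scale-equivariant; both the fraction
and bin count are configurable, and the flat-histogram case returns the
constant value with a warning. The mask is the thresholded channel dilated
with a square structuring element (default radius 1 px; for synthetic
scenes at 25 nm pixels, where the PSF spans several pixels, a radius of
~4 px covers the spot tails — the radius should scale with the PSF width
in pixels). Percentages are computed on the black-level-zeroed signal:
percent = 100 · Σ signal[mask ∧ roi] / Σ signal[roi].

The chance-overlap control translates the *mask* by
round(500 nm / pixel size) pixels along +x after mask construction (black
level estimated on the unshifted channel, so the zero-filled edge cannot
distort the histogram); columns without shifted data are dropped from the
ROI, never wrapped. Per-cell uptake subtracts a scalar background (mean
over 4 °C-control cells) from each cell's mean and normalises the
reference group to 1; negative values are retained, as cell-to-cell
variability legitimately puts some cells below background.

The per-cell chance overlap of sparse puncta with a sparse mask is a
high-variance statistic (a handful of coincidences per cell), so
offset-vs-in-register comparisons are made on means over several cell
regions, mirroring per-cell quantification with mean ± SD bars.

## Object pipeline

Region growing is formalised as: seeds are local maxima above a threshold
(default: median + 10 robust SD of the channel, since vesicles occupy a
tiny voxel fraction) within a `seed_footprint` neighbourhood sized to the
expected spot extent (default 5×13×13 voxels, suppressing secondary maxima
in a spot's own noise halo — the analogue of a spot-size parameter in
commercial spot detectors); each seed, processed brightest-first, floods
the connected set (26-connectivity default) of unclaimed voxels with
intensity ≥ growing_tolerance × seed intensity (default 0.5). A seed
falling inside a claimed region merges into it; objects outside
[min_voxels, max_voxels] (default [10, 2000]) are discarded, which also
removes macropinosome-sized structures. On noise-free stacks with the
tolerance matched to the threshold this reduces exactly to
connected-components-above-threshold, which is the oracle the tests use;
the acceptance surface is ground-truth recovery, not equality with any
proprietary implementation. Mean, center (intensity at the rounded
intensity-weighted centroid), max and SD are recorded per channel over
exactly the stored voxel set.

The offset null translates each object's voxel set +20 voxels along x
(≈ 500 nm at 25 nm pixels; direction +x, no wrap) and re-samples the cargo
channel; objects whose translated set leaves the image are excluded rather
than padded, and fewer than 20 retained objects is an error (the
percentile would be unstable). The cutoff is the 95th percentile with
linear interpolation between closest ranks. A load exactly at the cutoff
is negative — the cutoff defines the cargo-negative class.

### Calibration behaviour of the null

For zero-cargo scenes the in-register and offset samples are exchangeable
draws from the same noise mixture, so the expected positive fraction is
0.05. At high object density a second-order effect appears: offset voxel
sets overlap neighbouring objects' in-register sets, coupling the
background sample to the loads and biasing the measured fraction slightly
low (≈ 0.045 at ~1 object/µm³ over 50 replicates). The null is therefore
marginally conservative in dense fields and exact in sparse ones; the
calibration tests bound the mean over replicates to [0.04, 0.06].

### Study regimes

Two preset scene specs pin the analysis regimes:

- `null_calibration_spec` — 3300 vesicles in a 24×1152×1152 field
  (≈ 1 µm⁻³), yielding ~2000 detected objects per scene with a pure-noise
  cargo channel; density does not matter for cutoff calibration, so
  merging is tolerated and the density guard is off.
- `recovery_spec` — 48×1280×1280 field at ≈ 0.3 µm⁻³ (mean spacing
  ≈ 0.8 µm), the sparse regime in which the 95th-percentile cutoff sits at
  the extreme low tail of the cargo-load Gaussian. Scenes generated at
  positive fractions 0.96 (n = 2350) and 0.92 (n = 2387) are recovered
  within ±3 percentage points; residual bias comes from ~5% of
  cargo-negative vesicles crossing the cutoff (by construction) and from
  occasional spot merging, which removes a few negatives by absorbing them
  into positive objects. These problem sizes keep a full calibration run
  (50 null scenes + 2 recovery scenes) around a quarter hour on one CPU.

The Gaussian load fit is a least-squares fit of A·exp(−(x−μ)²/2σ²) to the
histogram (default 50 bins), initialised at sample moments; non-convergent
or degenerate fits are returned flagged with the moment estimates. The
brightness diagnostic reports Spearman's ρ between defining-channel mean
and the negative-call indicator (undefined and flagged for constant
brightness); two-condition comparisons report both below-cutoff fractions
and a Wald two-proportion confidence interval (statsmodels).

## Calibration module

Serial dilutions are geometric, so the standard curve is a least-squares
line in log(signal) vs log(fraction); blot saturation is out of scope (the
generator produces linear-range signals). At least three standards
spanning two decades, monotone in fraction, are required. A treated signal
inside the standard range is inverted exactly (round trip to 10⁻⁶); below
the lowest standard, the lowest standard fraction is returned as an upper
bound with `bound_flag` set ("more than X% removed") — the bound can only
understate removal, never overstate it. Both behaviours are implemented
and labelled because printed removal figures of this kind may be either
interpolations or bounds. Line profiles are sampled bilinearly, aligned on
their intensity peak (the membrane signal) rather than by membrane
coordinates, and averaged; removal per channel is 1 − treated/control peak.

## Proteome statistics

PMA is computed only over plasma-membrane-annotated rows and sums to 100
by construction; detection is an input flag, not a model — the package
does not simulate mass-spectrometer sampling. SILAC ratios are analysed on
the log2 scale by default (ratio distributions are multiplicative); linear
mode is provided for comparability and gives a different band, which is
intentional and documented. The control band is mean ± 2 SD (sample SD,
ddof = 1) of the non-biotinylated rows (≥ 20 required); biotinylated rows
above/below/inside the band are accumulated/depleted/unchanged, control
rows are never classified. Under normality, control-distributed rows leak
out of the band at the two-sided 2 SD rate (≈ 4.6%).

## Numerical choices and degenerate inputs

- Percentile interpolation: linear between closest ranks throughout.
- Ties at the cutoff: negative.
- Empty detections, empty ROIs, flat histograms, zero control peaks and
  degenerate (zero-spread) bands are all either warnings with flagged NaN
  results or explicit errors, as listed per function.
- Images are rendered in float32; conservation tests compare sums in
  float64 at relative tolerance 2×10⁻⁶.
- Reports are CSV + JSON with sorted keys and no timestamps, so a run is
  reproducible byte-for-byte from its echoed config and seed.

## Known limitations

- Dense fields merge adjacent vesicles into single objects; the detected
  object count undershoots the true vesicle count and merged objects bias
  the brightness diagnostic (merged objects are bright and almost always
  cargo-positive). The density guard flags this regime.
- The black-level rule assumes a dominant background mode in the
  histogram; images that are mostly foreground would need an explicit
  black level.
- The offset null assumes the offset lands on statistically equivalent
  background; structured backgrounds violating this (e.g. strong gradients
  along x) would bias the cutoff.
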