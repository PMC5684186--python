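# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `nitramap`, in the order data flows through the pipeline.

## Reflectance calibration and cube handling

Cubes are stored rows × cols × bands with a strictly increasing wavelength
axis in nm (nominally 256 bands from 913 nm at a 6.2 nm step; 156 µm square
pixels). ENVI-style I/O supports BSQ and BIL interleaves with uint16 or
little-endian float32 payloads, matching push-broom line-scan instruments;
the wavelength block is mandatory in the header so a cube can never be
separated from its axis.

Relative reflectance is R = (S − B)/(W − B) per pixel and band. White and
dark references are single line scans (cols × bands) replicated down-track,
because a push-broom reference is one scan line of a white plate and of the
capped lens; full reference cubes are also accepted. Where W = B the sensor
region is dead: those pixels become NaN, are excluded from every downstream
statistic, and never propagate as ±∞.

Wavelength cropping uses a closed interval; the calibration default is
932.1–2,217.8 nm, dropping the noisy extremes of the detector range.

**Leaf segmentation** thresholds reflectance at the 1,450 nm water
absorption band (default threshold 0.5, leaf = below, since a hydrated leaf
is dark there against a dry background), keeps the largest 8-connected
component, and fills holes. This is a deliberately simple, reproducible
stand-in: how the original imaging experiments separated leaf from
background is not documented anywhere we could follow, so the band, the
threshold, and the comparison direction are all configurable.

## Destriping

A fixed pattern of per-column detector gains g(c) multiplies the scene, so
its Fourier energy concentrates on the stripe line — the zero-frequency
line of the along-stripe axis. `destripe_fft` attenuates a cosine-tapered
band of half-width 2 bins around that line (attenuation 0, i.e. full
suppression at the line center) and leaves everything else untouched.

The **DC guard** spans 8 bins of the across-stripe frequency axis. The
stripe line also carries the scene's own profile averaged along the stripe
axis; a guard of a single bin lets the filter delete that profile, which in
testing smeared bright background into thin structures lying along the
stripe direction (a leaf petiole) and biased their concentrations by ~8%.
Eight bins protect scene structure wider than ~1/8 of the image while
detector-gain stripes — short-period, hence far from DC — are still fully
removed. The guard includes the (0, 0) bin, so the image mean is preserved
exactly. `stripe_energy` measures energy in exactly the region the filter
attenuates, normalized by total non-DC energy, and is the before/after
metric throughout.

Invalid (NaN) pixels are inpainted with a Gaussian-weighted local mean
(σ = 3 px) before the transform and restored afterwards; the FFT needs a
complete grid but invalid markers must survive the round trip. Destriped
raw-count cubes are clipped at zero, since counts are physical.

The map-level "stripe smoothing filter" is a masked directional moving
average across the stripe axis (odd window; background pixels are neither
read nor written). It is applied to the finished concentration map, not to
spectra.

## Spectral pretreatment

* **SNV** centers each spectrum and scales to unit *sample* (n − 1)
  standard deviation; chemometrics codes disagree on the denominator, so
  ours is stated and tested. A zero-variance row is an error naming the row.
* **Gap-segment first derivative** subtracts the mean of a trailing
  `segment`-point window from the mean of a leading one, with `gap` bands
  skipped between windows, and divides by the center-to-center separation
  (`segment + gap`, index units) so a unit-slope line yields exactly 1 —
  many implementations skip the division; ours is stated and tested.
  Edges shrink (output length n − 2·segment − gap + 1); every output value
  is a pure function of observed data, and the wavelength axis shrinks to
  the window midpoints. Defaults: gap = 1, segment = 2.
* The **default recipe** is crop(932.1, 2,217.8) → SNV → derivative. The
  order of SNV and derivative is genuinely open (sources describing this
  kind of calibration do not fix it); SNV first removes multiplicative
  scatter before differencing, which is the common chemometrics ordering.
  The order is fully configurable and the recipe is serialized inside the
  fitted model, so a model can never be applied with the wrong
  pretreatment.

## PLS calibration

`NIPALSPLS` implements classical NIPALS for a univariate response: X and y
are mean-centered (not variance-scaled — standard for spectral data where
band variances are informative), factors are extracted by iterated
weight/score/loading updates (convergence: relative score change < 1e−10,
cap 500 iterations; for a univariate response the loop converges on the
second pass) with deflation of X and y. Scores are mutually orthogonal to
< 1e−8 relative; with n_factors equal to the rank of centered X the model
reproduces least squares to < 1e−6 relative (both tested against
independent oracles, including sklearn's PLS as a cross-check). The
algorithm is deterministic and seed-free; the iteration starts from the
response vector, falling back to the maximal-variance X column if the
response is fully deflated. A constant response yields a zero-factor model
that predicts the mean.

Prediction uses the rotation **R** = **W**(**P**ᵀ**W**)⁻¹ (the triangular
structure of **P**ᵀ**W** is enforced); because NIPALS factors are greedy,
the K-factor model contains every smaller model as a prefix, and
`predict_per_factor` reads out predictions at all factor counts from one
fit.

**LOOCV** exploits that: one fit per held-out sample at `max_factors`
(default 20), predictions at every factor count by truncation — verified
exact (1e−9) against a brute-force loop that refits per factor count. The
chosen factor count is the smallest one attaining the minimum RMSECV. r² is
the squared Pearson correlation between reference values and held-out
predictions; 1 − SSE/SST is reported alongside (`r2_sse_by_factor`) because
usage of "determination coefficient" is ambiguous in this literature.

## Mapping

Every in-mask pixel spectrum passes through the model's stored recipe and
is predicted; out-of-mask pixels are NaN. Predictions are clipped by
default to [0, 1.5 × calibration max] with the clipped count recorded:
veins and petioles exceed a blade-only calibration range, PLS extrapolates
linearly there, and an explicit, logged clipping policy is preferable to
silent extremes. Pixels stream through in blocks of 32 image rows so
arbitrarily large cubes fit in memory; results are block-size independent
(tested to 1e−12 — the only difference across blockings is BLAS summation
order). Rendering writes a false-color PNG plus a lossless CSV matrix.

## Physiology

NC_s = NC_l · V_l / W_s with NC_l in mg/L, V_l in mL, W_s in g; the
mg/L · mL / g product resolves to mg/kg exactly (the two SI prefixes
cancel), which is fixed and tested because the formula as usually printed
is unit-ambiguous. RWC = (FW − DW)/(PW − DW) and RNC = NC/PNC are
deliberately not clamped to [0, 1]: noise can push a measurement past its
baseline and clamping would hide it. Storage summaries report mean ± se
(sample sd / √n) per temperature and day, requiring ≥ 2 replicates per
cell; post-hoc multiple-comparison lettering is out of scope.

## Synthetic data

The generator exists so that each pipeline stage faces the artifact it is
designed to remove, with ground truth retained.

Forward model: absorbance A(λ) = baseline + (c / 5,000 mg/kg) · 0.10 ·
analyte(λ) + w · 0.55 · interferent(λ), reflectance
R = m · 10^(−A) + o + ε. The analyte signature is two Gaussian peaks (1,500
and 2,050 nm, widths 60/45 nm) — a modelling stand-in, since the true NIR
signature of nitrate in a leaf matrix is not established band-by-band; the
interferent mimics leaf water (1,450/1,940 nm). The log-like nonlinearity,
the multiplicative scatter m ∈ [0.85, 1.15], the additive offset
o ~ N(0, 0.01) and the smooth baseline each exercise one pretreatment (SNV
kills m and o; the derivative kills the baseline). Per-band noise sd
defaults to 0.002 (~0.5–1% of typical reflectance), a moderate level at
which LOOCV recovery is strong (r² ≈ 0.99); real biological and instrument
noise is substantially harsher — published calibrations of this kind on
real leaves reach r² around 0.74 — so synthetic recovery quantifies
pipeline correctness, not field performance.

Calibration sets draw concentrations uniformly from 2,178–8,767 mg/kg (the
blade-tissue reference design range); the tabulated reference value equals
the truth, emulating an accurate wet-chemistry reference. The leaf phantom
is fully procedural (superellipse blade, tapered petiole, midrib and
oblique side veins): blade 3,000 mg/kg with a ±12.5% center-to-edge
gradient (leaf centers are nitrate-richer than edges), veins 12,000,
petiole 14,000 mg/kg. Stripes enter as a sinusoidal column gain (amplitude
10%, period 4 px) applied to the sample counts but not the references —
exactly the reference-drift mechanism that causes real push-broom stripes.
Raw counts are dark 120 + signal 3,000 · R · gain, clipped at zero.

Storage series follow RNC(t) = exp(−k(T)·t) with k = 0.026, 0.056, 0.23,
0.26 /day at 10/20/30/40 °C — chosen to match the reported declines of
roughly 10% by day 4, 20% by day 4, 50% by day 3 and 40% by day 2
respectively — and a temperature-independent RWC rate of 0.026/day, with 2%
multiplicative observation noise, 8 replicates, days 0–4.

What the phantoms do **not** model: radiative-transfer leaf optics,
instrument point-spread, wavelength-dependent illumination shape,
non-sinusoidal or drifting stripe patterns, specular highlights, and any
real nitrate band assignment. Passing tests therefore demonstrate that the
algorithms recover what their own forward model hides — necessary, not
sufficient, for field validity.

## Problem sizes and numerical choices

Default test and reproduction sizes: 210-sample calibrations (the reference
experiment's design size) with 15 LOOCV factors; 128 × 160 phantoms
(~8,400 leaf pixels × 256 bands); 100-problem oracle sweeps at 20 × 10.
These sizes make the whole suite and the reproduction script run in well
under a minute each on a single CPU while keeping every statistic stable
across seeds. Ties in factor selection break toward fewer factors;
derivative and crop reject configurations that do not fit rather than pad;
all random draws flow through `numpy.random.default_rng` seeds, and
identical seeds reproduce bit-identical synthetic data.

## Known limitations

* Vein/petiole concentrations lie outside the calibration range; linear PLS
  extrapolation underestimates them (clipping bounds the damage but cannot
  fix it). Region *ordering* is reliable; absolute vein/petiole values are
  not.
* The segmentation threshold is scene-dependent; heavily dehydrated leaves
  reduce the 1,450 nm contrast it relies on.
* The destriper assumes stripes aligned with an image axis and constant
  along it; slowly varying gains leak energy off the stripe line and are
  only partially removed. Scene structure lying exactly along the stripe
  direction narrower than the DC guard's passband is slightly attenuated.
* LOOCV cost grows as n² fits; for much larger calibrations a k-fold
  scheme would be preferable, but is out of scope here.
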