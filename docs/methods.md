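# Methods

This note documents the models, conventions, numerical choices and known
limits of phasorlab, in the spirit of a methods section: everything here
is either a definition or a property the test suite actually computes.

## The discrete phasor transform

Each pixel's histogram `I(k)`, `k = 0..B-1` (time bins of width `T/B`
under excitation period `T = 1/f`, or wavelength bins across a band
`[λ0, λ1]`), maps to per-harmonic coordinates

    G_n = Σ_k I(k) cos(2πnk/B) / Σ_k I(k)
    S_n = Σ_k I(k) sin(2πnk/B) / Σ_k I(k)

**Angle convention.** Bin *left edges* (`k`, not `k+½`) are used, which
makes a delta at bin 0 map exactly to (1, 0). The half-bin rotation this
induces relative to bin-center physics — like any instrument phase delay
— is absorbed by calibration, which real measurements need anyway.

**Zero-intensity pixels** are flagged invalid and excluded from every
downstream statistic; no sentinel value propagates. The same formula
serves spectral stacks (`k` starting at the λ0 bin); spectral fields
carry no repetition frequency and are used uncalibrated.

**Aliasing.** Harmonics `n ≥ B` are rejected. For valid pixels
`G² + S² ≤ 1` holds for any non-negative histogram (it is a normalized
average of unit vectors); this and the linearity of the transform in
photon counts are asserted as property tests.

## Calibration

A reference measurement of a fluorophore with known single-exponential
lifetime τ_ref pins, per harmonic, a correction phase shift
`Δφ(n) = φ_theory − φ_measured` and modulation factor
`k(n) = M_theory/M_measured`, where the theoretical point is the closed
form at `ω = 2πfn`. The reference phasor is the intensity-weighted mean
of the valid pixels' complex phasors (not a mean of phases). Applying a
correction multiplies each pixel's `G + iS` by `k(n)·e^{iΔφ(n)}`; it is
exactly invertible by `(−Δφ, 1/k)` (restoration to 1e-12 is asserted).
Manual corrections accept user-entered `(Δφ, k)` pairs, wrapped into
(−π, π].

**Discretization limit.** For a periodic exponential sampled in B bins,
the discrete phasor is `(1−r)/(1−r·z)` with `r = exp(−T/(Bτ))`,
`z = exp(2πin/B)` — it differs from the continuous `1/(1−iωτ)` by a
*τ-dependent* factor (harmonic aliasing). A rotate+scale calibration
therefore cancels discretization exactly only at τ_ref; residuals for
other lifetimes scale as `1/B²`. Measured after calibration at
τ_ref = 4 ns over τ = 0.5–8 ns and harmonics 1–2: max coordinate error
≈ 2.8e-4 at B = 256, ≈ 1e-6 at B = 4096, ≈ 4e-9 at B = 65536. Projected
lifetimes are less sensitive: all three estimators stay within 0.1 % of
the true lifetime already at B = 256. Tests that require near-exact
closed-form agreement use B = 16384.

## Lifetime projections

With `φ = atan2(S, G)` (full quadrant) and `M = √(G²+S²)`:

* **tau-phase** `τφ = S/(ωG)`; invalid where `G ≤ 0` or the result is
  negative.
* **tau-modulation** `τM = √(1/M² − 1)/ω`; invalid where `M = 0` or
  `M > 1`.
* **tau-normalized** projects radially from the circle center (½, 0):
  `θ = atan2(S, G−½)` restricted to [0, π] (pixels with `S < 0` are
  invalid), `G_N = ½(1+cos θ)`, `τN = √((1−G_N)/G_N)/ω`.

The algebraic forms are fixed by requiring that a point *on* the
universal circle return the generating exponential's true τ; the suite
asserts the three estimators agree to 1e-9 (relative) on the circle, and
that `τφ ≤ τM` for two-component mixtures (points inside the circle).

**Custom projections** intersect the ray from an arbitrary origin through
the pixel with the universal circle. Radial mode keeps the nearer
non-negative intersection, angular the farther (they coincide for origins
strictly inside the circle; tangent rays count as hits, misses flag the
pixel invalid). Origin (0,0)/angular is definitionally tau-phase and is
computed through the tau-phase formula so the two paths agree
bit-for-bit; origin (½,0)/radial reproduces tau-normalized to 1e-12.

## Phasor-space operations

* **Filtering**: a uniform (box) kernel of odd size ≥ 3 is convolved over
  each harmonic's G and S maps, `repeats` times, all harmonics together.
  Invalid pixels are excluded and neighborhoods renormalized by the valid
  count (which also handles edges). A mean — not median — filter is used:
  convolution is the operation the workflow names, and it preserves the
  linear-mixture semantics of phasor coordinates. Neighborhoods are not
  intensity-weighted. Intensity and validity pass through unchanged.
* **Intensity masking**: `valid ← valid ∧ (tmin ≤ I ≤ tmax) ∧ external`,
  bounds inclusive; external masks must match the image shape.
* **Histograms**: R×R grid (default 256, extent [−1,1]²), rows binning S
  and columns G, numpy half-open bins with the last closed. Stored counts
  are always raw; log scaling (log1p) affects display values only. Total
  counts equal the number of in-extent valid pixels.
* **Cursors**: circles in phasor space, boundary-inclusive, labelled
  1..K in draw order with the later-drawn cursor winning overlaps
  (deterministic painter's rule); label 0 means unassigned or invalid.
  The reciprocal operation marks exactly the histogram bins occupied by
  ≥ 1 valid pixel of an image-space region; it distributes over unions.

## Gaussian-mixture clustering

Features are the (G, S) coordinates of valid pixels — 2 dimensions per
selected harmonic (default: harmonic 1; harmonics may be concatenated).
A full-covariance mixture is fitted by EM written out in-package so that
the per-iteration log-likelihood trace is recorded (its monotonicity is
asserted on every fitted model in the tests) and user initial means are
honored exactly; `sklearn.mixture.GaussianMixture` serves as an
independent cross-check in the suite, never as the implementation.

Settings: relative log-likelihood tolerance 1e-7, max 500 iterations,
1e-8 added to covariance diagonals each M-step. Initialization uses
user means (with isotropic data-variance covariances) or k-means++ under
an explicit seed recorded on the model; identical data and seed give
bit-identical models. Models persist as JSON (weights, means,
covariances, colors, seed) and can be applied to other fields: posteriors
sum to 1 at valid pixels, hard labels are the posterior argmax (ties to
the lowest index), invalid pixels get label −1.

**Confidence ellipses.** For a 2-D component, the Mahalanobis radius
containing a fraction ℓ of the mass is `r = √(−2 ln(1−ℓ))` (the χ²₂
quantile); semi-axes are `r·√eigenvalues` with orientation from the
leading eigenvector. The default display level is 0.88; Monte-Carlo
coverage at that level is verified to within 3 standard errors on 1e5
draws (this is also what `scripts/acceptance.py` reports).

## Multi-harmonic unmixing

Component matrix: column `i` stacks `[G_1, S_1, …, G_N, S_N, 1]` for
component `i`, from the closed form (lifetime-defined) or stored
empirical coordinates; duplicate components (stacked distance ≤ 1e-9)
raise a conditioning error naming the pair. Per valid pixel the system
`A f = m` is solved exactly when `C = 2N+1`, by least squares when
`C < 2N+1`. The sum-to-one row is part of the system (weight 1) rather
than eliminated, keeping both branches uniform. Under `nonneg=True` the
solver switches to NNLS with the sum row weighted 1e3, holding Σf = 1 to
~1e-6; the default solver deliberately reports negative fractions — they
diagnose badly chosen components. All harmonics enter with equal weight
(no SNR weighting). Fractions are photon fractions; molar conversion is
out of scope.

**Noise amplification.** The 5-component, 2-harmonic system at
τ = {0.5, 1, 2, 4, 8} ns and f = 80 MHz has condition number ≈ 235:
per-pixel fraction noise is ~50× the phasor coordinate noise, giving a
per-pixel fraction RMSE of ≈ 0.05 at 1e5 photons/pixel. Noiseless
mixtures are recovered to 1e-9; quantitative per-pixel fractions at
capacity require either far larger photon budgets or spatial pooling
(the pooled estimate over a uniform 32×32 region reaches a few 1e-3,
asserted in the suite). Practical workflows should use fewer, better
separated components or aggregate over regions.

## Synthetic data generator

The generator emulates what the analysis sees from an instrument at desk
scale and carries exact ground truth:

* **Decays**: the steady-state periodic exponential, point-sampled at bin
  centers `(k+½)T/B` and normalized per species to unit area, so mixture
  weights are exactly photon fractions; expected counts are scaled to
  `photons_per_pixel` and Poisson-sampled under a fixed seed (or returned
  as expected values with `noise="none"`). The bin-center convention is
  independent of the transform's left-edge convention — calibration
  reconciles the two, mirroring real instruments.
* **Spectra**: Gaussian emission bands discretized over the detection
  band (σ = 0 collapses to the nearest bin); mass falling outside the
  band triggers a truncation warning and is recorded in the ground truth.
* **Calibration fixtures**: a known `(Δφ, k)` distortion is realized by a
  circular time shift of the continuous decay (phase scales with harmonic
  number, like a real delay) plus uniform-background mixing (modulus
  scaled equally at all harmonics; only `0 < k ≤ 1` has a count-based
  realization). The shifted profile is bin-integrated via 64×
  oversampling: point-sampling it would alias the moving wrap
  discontinuity into an O(1/B) phase bias, while integration — what a
  detector does — suppresses it to O(1/B²). Recovery tests compare
  distorted against undistorted references differentially, since the
  absolute correction also contains the fixed half-bin convention offset
  that calibration absorbs by design.

What the generator does **not** model: instrument response functions
(deconvolution is out of scope; phase/modulation distortions stand in for
the IRF), optical PSFs, detector afterpulsing, and background
autofluorescence. Passing tests therefore demonstrate correctness of the
transform algebra, calibration, clustering and unmixing under Poisson
statistics — not robustness to IRF mis-modelling or structured
background in real tissue.

## I/O conventions

Stacks are multi-page grayscale TIFFs (bin, row, col; uint16/uint32, or
float32 for expected-value data) with a JSON sidecar carrying frequency
or band; integer stacks round-trip bit-exactly. Decay traces are
two-column `bin,count` text files with sniffed delimiter and optional
header. Phasor fields persist in a documented **ref dialect**
(`phasorlab-ref-1`): little-endian float32 planes ordered intensity,
φ₁ (degrees), M₁, φ₂, M₂, … for contiguous harmonics 1..N, with a JSON
sidecar; invalid pixels store (0, 0) — a valid pixel lying exactly at the
origin in all harmonics is indistinguishable from the sentinel, a
documented edge case. Byte-level compatibility with legacy ref files is
not guaranteed (their layout is unpublished); the dialect tag makes this
explicit. Round-trip error is bounded by float32 quantization (≤ 1e-6 in
G and S). Fraction tables are RFC-4180 CSV (CRLF), one row per valid
pixel. Colored exports render hard (solid color per label), soft
(intensity-weighted, linear or log1p scaling, normalized to the image
max) or component mode (linear addition of component colors weighted by
fractions); 8-bit values round half away from zero, so a 50:50 blend of
255 and 0 renders 128.

## Determinism

Every stochastic element (scene sampling, GMM seeding) flows from
explicit seeds; the pipeline runner writes a manifest of SHA-256 hashes
and identical configs with identical seeds produce byte-identical
artifacts (asserted in the suite).

## Problem sizes used in the tests

The suite runs on desk-scale data chosen to make the statistics sharp:
64×64 scenes for unmixing, 5000–15000 points for clustering, 1e5 draws
for ellipse coverage, B = 256 bins as the standard histogram depth
(B = 2048–16384 where discretization itself is under test), photon
budgets of 1e4–1e6 per pixel. The full suite completes in a few seconds.
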