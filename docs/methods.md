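# Methods

This note documents the models, estimators and design choices behind
each analysis stage, what the synthetic generators do and do not
emulate, and the package's known limitations.

## Signal model of beating cilia and CBF estimation

A pixel over a beating ciliary tuft is modelled as

    I(y, x, t) = B + A·[1 + sin(2π f t / fps + φ + g·(y, x))]/2 + ε,

with background B, modulation amplitude A, cell-wise beat frequency f,
a linear phase gradient g (radians/pixel) standing in for the
metachronal wave, and additive Gaussian noise ε. A sinusoid is the
minimal periodic model carrying the spectral peak the analysis needs;
real waveforms have a distinguishable power and recovery stroke whose
harmonics this model omits — the estimator only uses the fundamental,
so passing tests show frequency recovery, not waveform fidelity.

The estimator is a single-taper periodogram per pixel: detrend
(`linear` by default, `mean` available), Hann taper, re-centre, real
FFT. The normalization makes the one-sided spectrum sum exactly to the
variance of the tapered trace (Parseval), so the DC bin is zero by
construction and excluded from peak search. Welch averaging is not
used because recordings are short (a few hundred frames); frequency
resolution is fps/T (0.5 Hz at 100 fps × 200 frames).

Defaults, with rationale:

* **band 0.5–30 Hz** — the physiological range of airway CBF.
* **activity**: a pixel is active when its in-band peak holds ≥ 0.2 of
  the total in-band power *and* rises ≥ 5× above the median in-band
  bin. White noise concentrates no power, so static pixels fail the
  ratio test; both constants are configurable because "static" is not
  defined at pixel level by any convention. A numerical floor at
  10⁻²⁰ × the pixel's mean square excludes machine-precision residue
  on exactly constant traces. The ratio statistic assumes enough
  in-band bins (T ≳ 100 frames) for the noise maximum to stay well
  below the threshold; very short recordings weaken it.
* **per-cell CBF** = interpolated median of dominant frequencies over
  active pixels (robust to boundary pixels); ties in the per-pixel
  argmax resolve to the lowest frequency bin.
* **beat modes**: static if active fraction < 0.05; restricted if the
  cell's mean peak power < 0.25 × the field-median active peak power
  (a relative criterion, since absolute intensities are
  instrument-dependent); otherwise beating. The visually defined
  rigid/rotational waveform classes are out of scope and never
  returned.

## Rotational polarity

Basal-foot orientation per cell is treated as a circular sample.
Angles use the mathematical convention (counterclockwise from +x) on
y-down images, i.e. θ = atan2(−Δy, Δx); all downstream statistics are
convention-free.

* **Detection**: scale-normalized Laplacian-of-Gaussian response,
  local maxima above a relative threshold with a minimum separation,
  sub-pixel refinement by response-weighted centroid. Deterministic;
  a blank image yields an empty set, not an error.
* **Pairing**: mutual nearest neighbour with a hard cap (default
  500 nm; the basal foot sits a few hundred nm from the body). Exact
  distance ties pair nothing; each spot is used at most once. Mutual
  NN avoids the chaining errors of greedy matching.
* **Statistics**: circular mean, R, circular SD √(−2 ln R) (undefined
  at R = 0, e.g. antipodal pairs), and the Rayleigh test with the
  standard O(1/n²) series correction, clipped into (0, 1]. Cells with
  fewer than 4 pairs are flagged unscored (Rayleigh validity).
* R was chosen as the per-cell polarity statistic because it is
  bounded, dispersion-free and matches rose-plot intuition; a
  threshold of 0.5 cleanly separates concentrated (κ = 8, theoretical
  R = I₁(8)/I₀(8) ≈ 0.94) from uniform populations at n = 50.

The generator draws angles from von Mises(μ, κ) — the canonical
circular family, enabling parameter-recovery tests; κ = 0 recovers the
uniform circle. Only the 2D basal plane is modelled: z is
max-projected before detection, matching how such stacks are scored.
Per-cell sample means at κ = 8, n = 50 scatter around μ with SD ≈ 3°,
so recovery is checked per cell against that cell's true angle sample
and against μ for the cohort-pooled mean.

## Ciliation and length morphometry

* **Basal bodies**: anisotropic Gaussian smoothing matched to the blob
  size (a matched filter), then local maxima above 0.35 × the smoothed
  maximum with ≥ 1 µm separation.
* **Cilia**: threshold (Otsu by default) → 26-connected components →
  3D thinning (skeletonization) → longest geodesic path per component
  by double Dijkstra over the voxel graph, with edges weighted by
  physical (anisotropic) distance. Thinning erodes filament tips and
  can fragment thin anisotropic chains, so the path search runs over
  all component voxels with a 5 % weight penalty off the skeleton:
  the route follows the centreline wherever one exists yet still
  reaches the true tips. The double sweep is exact for trees and is
  the standard diameter heuristic otherwise.
* **Length**: the voxel path is converted to physical coordinates and
  smoothed twice with an endpoint-preserving moving average
  (window ± 3 points) before segment summation; this collapses the
  quantization zigzag that otherwise inflates straight-segment lengths
  by several per cent. Straight 6 µm test filaments at (0.3, 0.1, 0.1)
  µm voxels are recovered within half a voxel diagonal at arbitrary
  orientation; the remaining error is endpoint rounding. Heavy
  smoothing slightly shortens strongly curved filaments — a known
  bias.
* **Counting**: cilia are counted as skeleton components, not assigned
  to individual basal bodies; tufts that merge under the threshold are
  undercounted (threshold is configurable). Components whose longest
  path is below `min_length_um` (default 1 µm) are discarded as
  puncta. Raising that floor can only reduce the count.
* **Ciliation level** = n_cilia / n_basal bodies; undefined (NaN, with
  a warning) when no basal bodies are found. 2D inputs are accepted
  throughout, which covers measuring on maximum-intensity projections;
  the default is genuine 3D path length.

Generator filaments are straight with a random tilt from +z (polar
angle uniform in [0, jitter], azimuth uniform) and roots snapped to
voxel centres on a jittered lateral grid that guarantees the minimum
separation for every seed (rejection sampling can stall near the
packing limit). Real cilia curve and cross; merged tufts are the main
unmodelled failure mode.

## Bead clearance

Beads are detected per frame with the same LoG detector and linked
frame-to-frame by mutual nearest neighbour under a maximum step; no
gap closing or merge/split handling (short, clean videos do not need
it — a documented limitation). Per track: speed = path length × fps /
(n − 1), straightness = net displacement / path length. Directional
coherence is the resultant length of the per-track net-direction unit
vectors — bounded, speed-free, and the same circular machinery as the
polarity stage. Clearance is called present iff coherence ≥ 0.6 and
mean speed ≥ 0.5 µm/s; both thresholds are conventions exposed in
configuration, chosen so that pure drift (coherence 1) and pure
diffusion (coherence ≈ n_tracks^(−1/2)) sit far on either side. The
generator's displacement model is drift·Δt + √(2DΔt)·N(0, I) per axis,
with beads truncated and flagged when they leave the field.

## Cohort statistics

* **t-test**: Welch (unequal variances) by default — per-cell imaging
  measures rarely have equal spread across groups; Student's variant
  is available. Zero variance in both groups is flagged degenerate
  (t = 0, p = 1 for equal means; p → 0 otherwise). At very small n the
  parametric p can fall below the resolution floor (1 / #relabellings)
  of an exhaustive permutation reference; the tests treat the
  parametric value as a refinement below that floor rather than
  expecting numerical agreement.
* **Fisher's exact test**: two-sided p as the sum of probabilities of
  all margin-consistent tables no more probable than the observed one
  (the common convention); a doubled-one-tail variant is offered.
  2×K tables are enumerated exactly for K ≤ 4 and totals ≤ 40; larger
  tables go through a seeded multivariate-hypergeometric Monte Carlo.
* **Percentages** round half-up in exact integer arithmetic
  (18.75 % → 19 %), matching how cohort fractions are conventionally
  printed.
* No multiple-testing correction is applied by default. Whether
  per-cell values should be nested within patients before testing is
  an open design question in this kind of data; the package tests
  whatever table it is given, so both per-cell and per-patient-mean
  comparisons can be run and labelled by the caller.

## Pipeline, determinism and problem sizes

Every stage consumes a `RunConfig` (YAML, flags override file values)
and emits CSV/TIFF/JSON plus a manifest with the config hash and
package version. All randomness flows through `numpy.random.Generator`
seeded from the config; identical config + seed reproduces
byte-identical CSVs (fixed column order, row order sorted by label,
`%.9g` floats, `\n` line endings).

The built-in benchmarks use 200-frame videos at 100 fps with 32–40 px
cells, 20-cell spot fields with 50 pairs per cell, 48×256×256 stacks
at (0.3, 0.1, 0.1) µm voxels with 12 basal bodies, and 10–100-bead
videos of 20–100 frames — sizes chosen to estimate every statistic
stably on a single CPU. The demo cohort (`demo_synthetic_cohort`)
contrasts a healthy arm (beating cells, κ = 8 polarity, 75 % ciliation,
drifting beads) with a loss-of-function arm (static cells, κ = 0.3,
25 % ciliation, diffusing beads).

## What passing tests do and do not show

The generators reproduce the statistical structure each stage assumes
— periodicity, circular concentration, filament geometry, drift vs
diffusion — with additive Gaussian noise rather than Poisson shot
noise, isotropic Gaussian PSFs rather than optical models, and no
photobleaching, drift, or debris. Recovery on these inputs validates
the estimators' correctness and calibration; performance on real
imagery additionally depends on segmentation quality (cell masks are
required inputs, not computed), labelling density and optical
artefacts not modelled here.
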