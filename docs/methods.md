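# Methods

## Spectral estimation

Replicate spectra are estimated on the Fourier grid ω_m = m/T,
m = 1..⌊T/2⌋−1 (the zero and Nyquist frequencies are excluded, and all band
operations live on this grid). The estimator averages R direct estimates
|Σ_t h_rt x_t e^{−2πiω_m t}|² under the orthonormal sine tapers
h_rt = √(2/(T+1)) sin(πrt/(T+1)). With unit-norm tapers no further
normalization is applied: unit-variance white noise then has estimated
spectrum ≈ 1 at every frequency, matching the convention
g(ω) = σ²/|φ(e^{−2πiω})|² used by the AR(2) simulators, and the raw
periodogram satisfies (2/T)·Σ_m Y(ω_m) ≈ sample variance. The default
R = ⌊√T⌋ balances variance reduction against resolution (the estimator is
consistent when R → ∞ with R/T → 0); users analyzing spectra with very
sharp peaks should lower R. Optional preprocessing (`standardize=True`)
performs an OLS linear detrend followed by division by the sample standard
deviation (ddof = 1), the usual treatment of interval-valved biomedical
series; constant series are rejected at a relative tolerance of 1e−10.

## Bands, clusterings, and the loss

Bands are half-open, left-closed runs of consecutive Fourier indices,
stored as integer cut offsets; frequencies in cycles/sample (and Hz, when a
sampling rate is supplied) are derived views, never stored. Every band must
contain at least `w_min` frequencies (default 5): band means and the
band-similarity ratio are degenerate on near-empty bands, and this floor is
the only constraint added beyond contiguity. All subpopulations share the
same number of bands L; this keeps collapsed measures comparable across
groups and is the assumption under which the selection criteria are defined
(unequal L is a known extension, see Limitations).

The loss is the 1/T-scaled sum of squared deviations of each replicate
spectrum from its group's mean collapsed (step-function) spectrum. Because
band means minimize within-band sums of squares, the minimized loss is
non-increasing under band refinement and under splitting any subpopulation
— properties the test suite asserts directly. Internally the loss is
evaluated in O(K·L) per candidate via per-replicate prefix sums
(T·loss = Σg² − Σ_jl S_jl²/n_jl with S_jl the in-group in-band sum), which
is what makes population-scale genetic search cheap; the readable
implementation in `fbam.bands.fbam_loss` is the reference the engine is
tested against (1e−10 agreement with a triple-loop oracle).

## Selection criteria

The band criterion R1 for adjacent bands l, l+1 of one group is the sum of
the two within-band root-sums-of-squares around each band's mean level
divided by the root-sum-of-squares around the width-weighted pooled mean.
S1 averages R1 over the J·(L−1) adjacent pairs. A printed variant that
divides by J·L instead is available (`S1(..., normalizer="JL")`); it
discounts larger L by (L−1)/L and in our experiments prefers two bands even
on noiseless three-plateau spectra whose band structure is unambiguous, so
the plain average is the default. Useful intuition for R1: splitting a flat
region gives R1 ≥ 1 (≈√2 in pure noise), splitting a linear spectral slope
gives R1 ≈ 1/√2 regardless of steepness, and splitting at a genuine level
change gives R1 near 0. S1 therefore discriminates sharply between banded
(piecewise-flat) spectra and over-split models, but is nearly flat in L for
smoothly sloping spectra.

The subpopulation criterion R2 is the sum of the two per-capita
within-group root-sums-of-squares around each group's mean collapsed
spectrum, divided by the Euclidean distance between the two step functions
on the full grid; its printed estimator has an index typo (the second
numerator sums over group i's bands) which we resolve to each group's own
bands, consistent with the population-level definition. S2 averages each
group's worst-case (largest) R2. Joint selection divides S1 and S2 by their
maxima over the fitted grid — equalizing their scales, so the maxima of the
scaled columns are exactly 1 — and minimizes the sum; degenerate ratios
(zero denominators) become +∞ so such cells are never selected; exact ties
break toward smaller J, then smaller L. Grids that contain only J = 1 (or
only L = 1) cells automatically fall back to single-axis selection, since
S2 (S1) is undefined there.

## Genetic search

A chromosome is the integer label vector (length K) plus one sorted
interior-cut vector (length L−1) per group. Mutation resamples each label
uniformly with probability p_m and jitters each cut with probability p_m by
a uniform integer offset in ±⌈0.05·M⌉; repairs are deterministic (empty
groups steal a random member of the largest group; cuts are sorted and
clamped into their feasible ranges with a forward minimum-width pass, which
always yields a feasible partition). Survivor selection is (μ+λ)
truncation — parents compete with offspring_per_parent = 2 offspring —
with duplicate chromosomes removed so that exact copies, common at low
mutation rates, do not crowd out distinct candidates; an elitist step
re-inserts the previous best if a generation ever loses it. Islands
(default 6 of 50 chromosomes) evolve independently and every 50 generations
exchange 5 random chromosomes around a ring (island 1 receives replacements
from the last island in the slots it sent onward).

Mutation-only search moves cuts slowly (a cut travels at most ⌈0.05·M⌉ per
accepted step), so at each migration epoch and at termination the island
elites undergo a deterministic memetic polish: coordinate descent that
alternates exact 1-D relocation of each cut (scanning all feasible
positions via prefix sums) with reassignment of every replicate to its
nearest group step function, until the loss stops improving. The polish
never degrades the elite and is what lets short runs (2 islands, 200
generations) reach the same optima as long ones; it can be disabled
(`GAConfig(polish=False)`) to study the plain GA. Stopping: at
max_generations (default 500) or when the global elite has not improved by
relative 1e−10 for stall_generations (default 100). All randomness derives
from SeedSequence streams keyed by (seed, J, L, island), so serial and
parallel grid fits are bitwise identical and every run is reproducible from
its seed. p_m (default 0.05), the offspring count, and the stopping rule
are exposed in `GAConfig`.

## Synthetic data

Three generator families mirror the simulation study and are first-class,
tested code:

* **Model 1** (piecewise-smooth spectra): three groups with boundaries
  (0.1, 0.25), (0.2, 0.3), (0.25, 0.4) cycles/sample and plateau levels
  (15, 7.5, 2), (25, 12.5, 4), (35, 17.5, 6); per-replicate levels are
  jittered U[±2]; plateaus are joined by cubic Hermite (smoothstep)
  transitions of half-width 0.025 with zero end slopes, so the value at a
  boundary is the mean of the adjacent levels. Series are drawn by Gaussian
  spectral synthesis, X_t = Σ_m √(2g(ω_m)/T)(A_m cos 2πω_m t +
  B_m sin 2πω_m t) with A, B i.i.d. standard normal, whose expected
  periodogram equals the target spectrum (verified by Monte-Carlo
  band-average recovery of the plateau levels to within 10%).
* **Model 2 a/b/c** (AR(2) peaks): group peak locations (0.23, 0.25, 0.27)
  / (0.21, 0.25, 0.29) / (0.19, 0.25, 0.31), per-replicate peaks
  U[ψ_j ± 0.02], bandwidth U[±0.005] around 0.15 (0.155, 0.165 for the
  outer groups of b, c), innovation sd 2.25, via
  φ1 = 2cos(2πψ)e^{−ℓ}, φ2 = −e^{−2ℓ}; recursion with a 500-sample burn-in
  (|φ2| ≤ e^{−0.1} in every configuration, so transients are far below
  numerical noise by then).
* **Model 3** (two-component mixtures): an AR(2) with ψ = 0, bandwidth
  U[0.48, 0.52], sd 2.5 (a broad low-frequency peak common to all groups)
  plus an AR(2) with group peaks U[0.2/0.26/0.32 ± 0.015], bandwidths
  0.05/0.065/0.095, sd 2; true spectra are the sums of the component
  closed forms.

What the generators do not emulate: real biomedical series are nonstationary
over long records, need artifact handling and resampling before analysis,
and have spectra that are neither piecewise-flat nor low-order AR. Passing
tests on these generators show the estimator/optimizer/selection machinery
recovers planted structure of these three kinds; they do not certify
performance on any particular clinical signal.

## Problem sizes and numerical choices

The replication suites and the acceptance script run 10 replications per
condition over {2,3,4}-based (J, L) grids with 2 islands and at most 200
generations — sizes chosen so a full pass stays within a few minutes on a
single core while leaving the generator parameters (the study conditions)
untouched. Spectra enter the pipeline raw (unstandardized) by default, as
the generators produce mean-zero series and the similarity ratios are
scale-invariant. Losses and criteria are double precision throughout;
oracle comparisons assert 1e−10 agreement; the stall rule uses relative
1e−10; duplicate detection hashes exact byte patterns.

## Known limitations

* On Model-3-type data (groups differing only in a narrow band of the
  spectrum, with replicate-level peak-location jitter), minimizing the loss
  on raw spectra can genuinely prefer clusterings that track overall
  spectral amplitude rather than the planted groups, and the joint
  criterion then tends to one more band than the planted four (splitting
  the steep low-frequency slope, where R1 ≈ 1/√2 provides no parsimony
  pressure). Variance-standardizing the series recovers the planted groups
  in this regime but degrades separation for amplitude-separated groups
  (Model-1-type data). The corresponding replication test is left failing
  rather than loosened; `standardize=True` is the recommended setting when
  groups are expected to differ in shape rather than scale.
* Equal L across subpopulations is assumed; unequal L would need a
  variable-length chromosome.
* Bands are contiguous; spectra whose group differences are spread over
  disconnected regions are summarized only up to contiguous approximations.
* The GA is stochastic; all reported runs are seeded, and the tiny-instance
  suite checks agreement with exhaustive enumeration, but global optimality
  on large instances is not guaranteed.
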