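# Methods

This note documents the models, parameter choices and numerical decisions
behind `connentropy`, and what the synthetic-data tests do and do not
demonstrate about real EEG.

## 1. Signal chain

### Preprocessing

Broadband conditioning uses linear-phase FIR filters designed with
`scipy.signal.firwin` and a Hamming window: a 1–70 Hz band-pass and a
49–51 Hz band-stop for power-line interference.  The filter order follows
the Hamming design rule (normalized transition width ≈ 3.3 / taps) with a
default transition width of 1 Hz, giving 661 taps at 200 Hz.  Filters are
applied zero-phase (forward–backward); because that is equivalent to a
single convolution with the taps' autocorrelation, it is implemented as one
FFT-based convolution after odd-reflection padding, which is numerically
equivalent to `filtfilt` but O(T log T) for long kernels.  Zero-phase
application squares the magnitude response, so stop-band attenuation is at
least twice the single-pass design value (measured: > 100 dB at 50 Hz and
at 0.2 Hz) and pass-band ripple stays below 1%.

One filter group delay ((taps − 1)/2 samples ≈ 1.65 s) is trimmed from each
end before segmentation so edge transients never contaminate the first or
last trial.  Recordings are then cut into consecutive non-overlapping 5-s
trials and the first twenty are kept; fewer than twenty is an error because
the protocol fixes the per-subject trial count.  Artifact rejection is out
of scope — synthetic data are artifact-free by construction — but a
user-supplied boolean trial mask is honored for real recordings.

Band decomposition into δ(1–4), θ(4–8), α(8–13), β₁(13–19), β₂(19–30) and
γ(30–70 Hz) reuses the same FIR machinery on the continuous (pre-trimming)
recording.  The 1 Hz transitions mean adjacent bands overlap slightly at
their edges; consequently a coupling structure injected into one band bleeds
weakly into its neighbors (visible as small SE effects in adjacent bands in
cohort simulations).  This is a property of any realizable filter bank, not
a defect.

### Orthogonalized AEC

For each ordered pair (seed i, test j) within a band-limited trial, the
test signal is regressed on the seed at zero lag (demeaned, no intercept)
and replaced by its residual, removing instantaneous linear cross-talk.
Amplitude envelopes are the modulus of the analytic signal; because the
Hilbert transform is linear, residual envelopes are formed directly from
the per-ROI analytic signals (|aⱼ − βᵢⱼ aᵢ|), which makes the full 68-node
computation one vectorized pass per seed.  The first and last 0.25 s of
each envelope are excluded from the Pearson correlation (Hilbert edge
artifacts).  The (i→j) and (j→i) correlations are averaged — orthogonalized
AEC is directionally asymmetric and averaging is the standard symmetric
reduction — and mapped to [0, 1].

Two mappings are provided: `abs` (default) keeps the magnitude of
anticorrelated envelopes, `clip` floors negatives at zero.  The signed
direction-averaged correlations themselves are exposed as
`aec_correlations`, and all independence/leakage diagnostics are defined on
them: for truly uncoupled signals the signed values scatter symmetrically
around zero, whereas any fixed-sign mapping has a positive noise floor
(≈ 0.8 × the per-trial estimation SD, i.e. ~0.1–0.15 here) that no
generator or correction can remove.

Degenerate cases: a zero-variance ROI gets zero weights with a warning; a
collinear pair (residual carrying < 10⁻¹² of the test signal's power) is
pure leakage and gets weight 0 rather than the correlation of numerical
roundoff.

### Histogram and entropy

Network weights are the strict upper triangle of each matrix
(n(n−1)/2 = 2278 values at 68 nodes).  The relative-probability histogram
is always on [0, 1] with N equal bins, left-closed/right-open except the
final bin (right-closed so a weight of exactly 1 is countable), normalized
to total mass 1.  The normalized Shannon entropy
SE = −(1/log₂N) Σ (q/Q) log₂(q/Q) uses the 0·log 0 := 0 convention and is
clamped to [0, 1] against floating-point underflow.  SE = 1 holds only for
an exactly uniform binned distribution; 2278 weights drawn uniformly give
SE ≈ 0.99 (tested as > 0.98).

The default N = 40 (bin width 0.025) is the outcome of the bin-selection
protocol at the study's dimensions and is used unless the protocol is
re-run (`run_bin_selection`).  The protocol computes, per trial, the counts
proposed by five rules; takes the median over all trials and subjects per
band and rule (half-integer medians round up); and keeps the maximum.  Rule
formulas: Square Root ⌈√n⌉; Sturges ⌈log₂n⌉ + 1; Scott width
3.49·s·n^(−1/3) and Freedman–Diaconis width 2·IQR·n^(−1/3), both converted
to counts via ⌈range/width⌉ with the range fixed at 1 — the common [0, 1]
histogram support — so counts are comparable across subjects
(`hist_range="sample"` is available).  The "Integers" rule (unit-width
integer-centered bins) is degenerate on [0, 1] and returns 2; it is kept
for protocol fidelity.

Per-subject summaries are unweighted arithmetic means of the per-trial SE
values and of the per-trial normalized histograms (renormalized against
floating-point drift).

### Statistics

The hierarchy is: Lilliefors normality per group and Brown–Forsythe Levene
(median-centered; configurable to mean-centered) as assumption checks;
global Kruskal–Wallis on SE per band; pairwise Mann–Whitney U
(asymptotic, tie-corrected, two-sided) only in bands whose global test
survives FDR; and per-bin Kruskal–Wallis across groups of the
subject-averaged histograms, again only in globally significant bands.
Benjamini–Hochberg correction is applied within narrow families — the 6
bands for the global tests, the 3 comparisons × analyzed bands for the
pairwise tests, the N bins within one band for the bin-by-bin analysis, and
the tested covariate set for Spearman confound checks.  These are the
narrowest defensible groupings; both thresholds 0.05 and 0.01 are flagged
in every report.  Degenerate inputs (all values identical) return H = 0,
p = 1 rather than an error.

The Lilliefors null distribution (KS statistic with estimated mean and SD)
is simulated: 10,000 seeded standard-normal samples per sample size, cached;
p = (1 + #{null ≥ observed}) / (10,001).  This avoids interpolation in
printed tables; the statistic agrees with `statsmodels` to machine
precision and the p-values to ±0.03 inside the tables' range.  Note the
test's power against a uniform alternative is ≈ 0.6 at n = 100 and > 0.9
only from n ≈ 200 (verified against a statsmodels Monte-Carlo oracle).

Groups with fewer than four observations skip the normality check with a
warning (nonparametric tests are used regardless).

## 2. Synthetic cohort generator

### Signal model

Per band b, node i:  xᵢᵇ(t) = eᵢᵇ(t) · cᵢᵇ(t), where

* cᵢᵇ is Gaussian noise with a flat spectrum confined to the band
  (spectral synthesis; independent across nodes), and
* eᵢᵇ = exp(σₘ zᵢᵇ) is a lognormal amplitude modulator driven by a slow
  Gaussian field z with pass band 0.3 Hz to min(0.45 × carrier bandwidth,
  4 Hz).  σₘ = 1 by default (envelope coefficient of variation ≈ 1.3,
  strong but physiological modulation).

The broadband recording is Σ_b √(pᵇ) xᵢᵇ with a 1/f-flavoured band-power
profile p (δ 1.0, θ 0.7, α 1.0, β₁ 0.5, β₂ 0.35, γ 0.25), plus optional
leakage: multiplication by the symmetric mixing matrix I + λG (G symmetric,
zero-diagonal, N(0, 1/n) entries, drawn once per cohort like a head model);
λ = `leakage_mix` defaults to 0.2.

The modulator bandwidth choice matters: the per-trial AEC estimation SD is
set by the number of effective envelope samples per 5-s trial.  Envelopes
confined below 1 Hz give ~6 effective samples and per-trial SDs near 0.2,
smearing any coupling structure beyond recognition; letting the envelope
fluctuate up to a few Hz (still far below each carrier band) is both closer
to the empirical envelope spectra of band-limited cortical oscillations and
necessary for coupling structure to be recoverable at the protocol's trial
length.

### Exact, calibrated coupling

Coupling targets are *measured-AEC* values.  The chain from a target t to
the Gaussian field correlation ρ inverts three attenuations in closed form:

1. lognormal transform: corr(e₁, e₂) = f(ρ) = (exp(ρσₘ²)−1)/(exp(σₘ²)−1);
2. Rayleigh dilution: the measured envelope is e·R with R the carrier's own
   (Rayleigh) envelope, independent across nodes, so the product
   correlation is divided by A = 1 + ((4−π)/π)(1 + μₑ²/σₑ²)  (A ≈ 1.43 at
   σₘ = 1);
3. band retention κᵇ: within-trial demeaning of the slow field and clipping
   of modulation sidebands by the band filters lose a band-dependent
   fraction of ρ.  κ is measured once through the *full* analysis chain by
   `calibrate_band_retention` and shipped as constants
   (δ 0.82, θ 0.85, α 0.88, β₁ 0.92, β₂ 0.94, γ 0.96).

So ρ = f⁻¹(t·A)/κᵇ, capped at 0.999.  Each band therefore has a measurable
ceiling f(κᵇ)/A (δ ≈ 0.52 … γ ≈ 0.65); targets above it saturate, and the
realized (post-calibration, post-saturation) values are stored per subject
as ground truth.  The slow fields are *whitened* before mixing — their
sample covariance is forced to the identity and then multiplied by the
Cholesky factor of the target correlation — so the realized modulator
correlation equals the calibrated value exactly instead of up to O(1/√T)
sampling jitter.  Validation: targets {0, 0.2, 0.4, 0.6} are recovered by
trial-averaged orthogonalized AEC monotonically and within ±0.1 (γ band;
narrow bands saturate slightly below 0.6 as per their ceilings).

Setting `sigma_m = 0` produces unmodulated stationary carriers (only valid
with all-zero coupling targets); this is the reference condition for
leakage diagnostics.

### Group structure

An explicit target matrix (`PairTargets`) is honored exactly up to a
nearest-PSD eigenvalue clip.  The default `StrataCoupling` builds a modular
network instead — within-module pairs share a target drawn from a high
stratum, cross-module targets are geometric means of per-node strengths
drawn from a low stratum — because a dense matrix of independently drawn
strong correlations is not positive semi-definite, while the modular
construction is PSD by design and neurophysiologically natural.

The default group difference (an assumption, since no generative model of
the clinical contrast exists): identical stratum ranges (low [0.01, 0.09],
high [0.36, 0.50]) in all groups, with the high-stratum mixture weight
p_high = 0.25 / 0.165 / 0.08 for control / MCI / dementia.  Groups thus
differ only in the dispersion of the coupling-strength distribution, and
only within the two strata; the dementia group's scarcity of high-coupling
pairs encodes the disconnection pattern and yields the lowest SE in
coupled bands.

### Leakage correction: what it can and cannot remove

For *stationary Gaussian* uncoupled signals, pairwise orthogonalization
removes instantaneous mixing essentially exactly: with x′ = x + λy at
λ = 0.5, the mean signed AEC stays within ±0.03 of the unmixed value
(slightly negative overall in narrow bands — the regression overfits short
trials, an effect of order 1/√(effective samples), largest in δ).

For strongly amplitude-modulated signals, however, mixing creates a
*quadratic* envelope dependence that a linear zero-lag regression cannot
remove: the residual retains a scaled copy of the seed's sources, and its
envelope co-fluctuates with the seed's envelope through the shared
modulator.  At λ = 0.5 this residual bias reaches ~0.2; at the default
cohort leakage (effective per-pair mixing ~λ/√n with λ = 0.2) it is below
0.02.  Dense mixing additionally creates third-party ("ghost") envelope
correlations that no pairwise correction addresses.  Both effects are
real properties of the method, documented rather than hidden: leakage
diagnostics in the tests use the stationary reference condition, and the
cohort default keeps modulated-leakage bias negligible.

### What the generator does not emulate

No forward modeling or scalp projection (the pipeline starts at ROI
series); no artifacts (ocular, muscular) and hence no artifact selection;
no cross-frequency or phase coupling (AEC-style amplitude coupling only);
no spatial autocorrelation beyond the module structure; no per-subject
covariates beyond optional random ones for confound tests.  Passing the
cohort-level tests therefore shows that the *pipeline* recovers known
amplitude-coupling structure through realistic estimation noise — not that
real dementia EEG behaves like the generator.

### Estimation noise and the limits of bin-level localization

A 5-s trial of a band with bandwidth B carries at most ~B·T independent
envelope samples, so per-trial AEC estimates have an SD ≥ ~0.13 (γ) to
~0.18 (δ) whatever the generator does.  Measured response kernels
K(observed bin | target) show that any coupling target in [0, 0.1] spreads
35–43% of its observed per-trial mass into [0.1, 0.25], and targets near
0.4 spread ~15–22% there.  Consequently, group differences confined to the
[0, 0.1] and [0.3, 0.6] *target* strata necessarily also shift observed
mass in the mid range: a linear-programming search over all stratum-
supported group contrasts, using the measured kernels and subject-level
variances, bounds the achievable strata-to-mid standardized-effect ratio at
≈ 2, while keeping 18 mid-range bin tests quiet under BH at n = 60 subjects
would require ≈ 6.  The cohort-level simulations therefore reproduce the
qualitative dichotomy — strong, FDR-significant bins in both strata with
SE separating the groups in exactly the affected bands — but also flag
mid-range bins, unlike the clinical observation the design emulates (where
between-subject heterogeneity and possibly cancelling effects kept the
mid range quiet).  This limitation is asserted honestly in the acceptance
suite rather than tuned away.

## 3. Problem sizes used in tests

Unit tests run on 2–6-node networks and single recordings.  The
cohort-level recovery test uses 15/20/25 subjects, 32 ROIs, 115-s
recordings (twenty 5-s trials after edge trimming) with coupling injected
in δ, α and β₁ — chosen as a faithful scaled-down replica of the full
45/69/81 × 68-ROI design.  The type-I-error test runs 500 null cohorts of
direct weight-matrix draws (3 × 8 subjects, 16 nodes, 3 trials), isolating
the KW + BH bin-by-bin family from signal-level cost.  The acceptance
script verifies the full 68-ROI, 6 × 68 × 68 × 20 per-subject
dimensionality on one subject.

## 4. Reproducibility

Every stochastic component runs off `numpy` `SeedSequence` substreams
spawned from a single cohort seed, one per subject, so generation is
bit-identical for a fixed configuration and independent of consumption
order.  Pipeline runs record a config hash, seed and package versions in
the manifest; `replay_from_manifest` re-executes a synthetic run and
reproduces the tables exactly.
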