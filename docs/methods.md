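# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the known limitations of the package. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Signal model and estimators

### Time-varying MVAR and the dual Kalman filter

Source signals are modeled as x(t) = Σ_r A_r(t) x(t−r) + ε(t),
ε ~ N(0, W). The DEKF couples two filters per sample: a state filter
over the stacked lag vector [x(t−1); …; x(t−p)] with the companion
transition built from the current parameter estimate, and a parameter
filter over θ = vec(A₁…A_p) under a random-walk prior θ(t) = θ(t−1) + η,
η ~ N(0, q·I). The parameter filter's innovation is the one-step
prediction error; its observation covariance is W (estimated by least
squares on the initialization window) plus the observation-noise floor.

Defaults and why:

* **order p = 5** at 500 Hz (covers a 10 ms interaction delay); the
  pipeline typically estimates at 125 Hz after decimation with p = 3.
* **q = 1e-5** per parameter per step. Larger q tracks faster changes —
  a step change of 0.5 in a cross-coefficient is crossed at half-height
  within ~230 samples — but on near-unit-root oscillators the
  forgetting dynamics of random-walk tracking produce a shrinkage bias
  on the collinear autoregressive terms that grows with q (at q = 1e-4
  the time-averaged error on a pole-radius-0.95 network is ~0.28; the
  effect reproduces in an independent per-row Kalman reference, so it
  is a property of the tracker, not of this implementation). For
  stationary analysis blocks the pipeline uses q = 1e-6.
* **Initialization**: least-squares MVAR on the first 2 s (truncated-SVD
  solve, so near-collinear narrowband windows cannot produce unbounded
  starts); parameter/state covariances 0.1·I; observation noise
  1e-3 × mean innovation variance. The first max(10·p, 100) samples of
  the trajectory are discarded as warm-up.
* **Divergence guard**: the fit aborts with a diagnostic if the
  parameter norm exceeds a configurable bound (default 1e3).

### tPDC and edge summarization

PDC is computed from the coefficient trajectory at a configurable time
stride (default 10) over 9 frequencies spanning the band. Column
normalization Σ_i π_ij² = 1 holds to 1e-6 everywhere (tested to 1e-12).
An edge's scalar strength is the band-and-time mean of π. Channels are
standardized to unit variance before estimation: plain (non-generalized)
PDC is scale-variant, and heterogeneous source amplitudes would
otherwise distort the column normalization.

**Decimation.** Mu/beta dynamics sampled at 500 Hz make the MVAR
regression nearly collinear (adjacent lags are almost identical), which
destroys edge contrast for both least-squares and DEKF estimators.
`recover_network(..., decimate=4)` applies zero-phase FIR decimation to
125 Hz before estimation; the band of interest (8–20 Hz) is untouched.

### Surrogate thresholding

Non-overlapping 1 s windows are shuffled **independently per channel**
(100 surrogates), the model is refitted, and each edge is thresholded at
the 95th percentile of its surrogate strengths, using the conservative
"higher" order statistic so the null exceedance stays at or below the
nominal level. Joint (same-order-across-channels) shuffling is available
but documented as vacuous: it preserves within-window lagged coupling,
so surrogate strengths coincide with the observed ones. A "mean"
threshold mode (the literal averaged-surrogate rule) is retained with a
prominent warning, since a mean threshold flags roughly half of all
null edges. Thresholds can be per-edge (default) or one pooled global
value.

### Time-reversal validation

For a candidate edge, Δ = strength(src→dst) − strength(dst→src) is
computed on the original and time-reversed series. Default rule
("reduction"): the candidate's direction must dominate (Δ > 0) and
reversal must remove at least γ = 0.5 of the asymmetry
(Δ_rev ≤ (1−γ)·Δ); a sign flip always passes. A "strict" mode demanding
a sign flip with |Δ_rev| ≥ γ|Δ| exists for comparison, but in
multichannel narrowband systems the reversed asymmetry collapses toward
zero rather than mirroring, so the strict rule rejects most genuine
interactions. Zero-lag mixing (the volume-conduction analogue) leaves
its weak asymmetry unchanged under reversal and fails the reduction
rule; the constructed suites measure ≥ 90% pass on lagged-causal pairs
and ≥ 90% rejection on instantaneous-mixing pairs.

### DICS beamformer

Cross-spectra are Welch-averaged (Hann, 1 s segments, 50% overlap) over
band bins. Filters use the real part of the band-mean CSD with Tikhonov
loading λ = 5% of the mean sensor power (mean diagonal = mean
eigenvalue); unit gain w_s·L_s = 1 holds to machine precision. Lead
fields are fixed-orientation scalar gains; the built-in toy forward
model places sensors on a Fibonacci hemisphere and decays gain with
squared distance — a geometric stand-in adequate for exercising the
beamformer algebra, not a physical volume-conductor solution. Pooled
source signals weight voxels by band power (weights sum to 1). Source
significance uses 100 permutations of 1 s segments with the add-one
p-value (1 + #{perm ≥ obs})/(1 + n_perm) and a 99th-percentile
significance criterion.

## 2. Synthetic study conditions

The generator emulates the recording conditions the pipeline targets:
500 Hz sampling, band-limited sources in mu (8–12 Hz) and low beta
(13–20 Hz), 40–80 s condition blocks, two-group cohorts.

* **Node dynamics**: damped AR(2) oscillators, pole radius 0.95, node
  frequencies spread evenly across the band, innovation variance set so
  each isolated oscillator has unit variance.
* **Directed edges**: cross-coefficients at lag 5 (10 ms at 500 Hz, a
  physiological cortico-cortical delay; at a 2 ms lag the direction of
  narrowband coupling is nearly invisible to time reversal). Edge
  magnitude is the requested relative strength times the target
  oscillator's gain at the source frequency, so an edge of strength r
  contributes roughly a fraction r of the target's amplitude —
  without this compensation resonant amplification stacks ~6× per
  directed hop and variance explodes along paths.
* **Graph structure**: while the edge count permits one direction per
  unordered pair, edges are oriented along a random topological order;
  the coupling is then acyclic, the companion matrix block-triangular,
  and stability is inherited from the uncoupled oscillators at any
  coupling strength. Reciprocal requests introduce feedback and are
  shrunk to spectral radius < 0.98.
* **Group profiles**: `dense_longrange` (control-like): 5 nodes, 10
  edges, strengths 0.30–0.45, at least one edge ≥ 80 mm on the fixed
  occipito-frontal coordinate template; `sparse_local`: 5 nodes, 4
  edges, strengths 0.18–0.30, all edges ≤ 85 mm (the template's
  shortest pairs; long anterior–posterior pairs start at 98 mm). The
  strength difference encodes that the emulated group difference is in
  interaction strength as well as edge count.
* **Behavior**: equal-variance Gaussian signal detection,
  P(hit) = Φ(d′/2 − c), P(FA) = Φ(−d′/2 − c); cohort defaults d′ = 2.5
  (control-like) vs 1.2.
* **Walker stimuli**: a parametric sinusoidal-limb gait model (15 dots,
  1 Hz gait cycle = two steps per second); the scramble control permutes
  dot positions and re-times each path to constant speed by arc-length
  resampling, preserving path shapes and per-dot cycle frequency. This
  is a stand-in for motion-capture data, not a reconstruction.

**What passing tests do and do not show.** The synthetic cohorts have
stationary, Gaussian, exactly-MVAR sources, a known lead field, and no
artifacts, non-stationarities, or inter-subject variability in source
geometry. Passing recovery and calibration tests therefore validates
the *machinery* (estimators unbiased where claimed, nulls calibrated,
direction tests discriminating) — not that real-cohort effect sizes or
classification accuracies would be reproduced.

## 3. Problem sizes used in tests and the acceptance script

Per-subject recordings of 40 s (20,000 samples at 500 Hz, decimated to
125 Hz for estimation), 20 subjects per group, 100 surrogates per
subject, 100 localization runs, 2000 null replicates for the rank-test
calibration, 20 seeded runs per time-reversal construction. Edge
recovery in the cohort experiments uses the static least-squares tPDC
route, which on these stationary blocks agrees with the dual-Kalman
route (band-mean strengths correlate > 0.9; verified in the suite, and
a dedicated test recovers the dense network through the DEKF route);
the DEKF's own recovery quality is measured separately on a 3-node
MVAR(2) (coefficient RMSE ≤ 0.05 against truth and the least-squares
oracle).

## 4. Statistics and classification choices

* d′ uses the 1/(2N) correction for extreme rates; negative values are
  legitimate.
* The 1.5-SD outlier rule is single-pass (mean/SD from the full group,
  not re-estimated) and applied per condition.
* Mann-Whitney uses the exact null for n ≤ 12 per group without ties,
  otherwise the tie-corrected normal approximation; Kruskal-Wallis uses
  the chi-square approximation with tie correction. All tests two-sided
  at α = 0.05, no multiple-testing correction (mirroring the emulated
  analysis; a documented limitation).
* Age enters optionally as rank-based residualization before group
  tests (`rank_residualize`), since no standard way exists to put a
  covariate inside a rank test.
* SVM: K(x,y) = (0.25·xᵀy + 1)³, class-balanced soft margin, C ∈
  {1…10} selected by nested 3-fold search inside each training portion,
  features standardized on the training portion only. The outer scheme
  is 10 stratified Monte-Carlo splits at 75/25 (reconciling a 10-fold
  count with 75/25 fractions); classic stratified k-fold is available.

## 5. Known limitations

* The forward model is geometric, not biophysical; no BEM/FEM, no
  realistic conductivities, no free source orientations.
* Plain PDC (not generalized/renormalized) is used, with channel
  standardization as the scale fix; information-flow variants (DTF,
  spectral Granger) are out of scope.
* The DEKF noise covariances are package defaults, documented above —
  not inferred values of any reference implementation.
* Artifact rejection is a transparent amplitude/z-score rule standing
  in for proprietary template matching; no ocular regression or ICA.
* Beamformer leakage between extracted sources attenuates the
  per-edge strength contrast in the fully end-to-end sensor-space demo
  (`run_all`); edge counts still separate the groups there, and the
  source-space experiments quantify recovery without leakage.
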