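# Methods

## Model and quantification chain

A qPCR amplification curve — fluorescence read once per thermal cycle —
has four phases: baseline, exponential, transitional, plateau.  cqman
models the whole trace with the modified Gompertz sigmoid

    y(x) = y0 + (ymax − y0) · exp(−exp(−(x − x0)/b)),   b > 0,

and fits it to the raw fluorescence of each well by Levenberg–Marquardt
least squares.  The Gompertz family is asymmetric (fast exit from baseline,
slow approach to plateau), which matches real amplification data better
than symmetric logistic fits and is comparatively insensitive to how many
plateau cycles a run happens to record.

All quantities downstream of the fit are closed-form, which makes the
pipeline deterministic and cheaply verifiable against numeric oracles:

* **Second-derivative maximum.**  Writing u = exp(−(x − x0)/b), the second
  derivative (ymax − y0)/b² · u(u − 1)e^(−u) is maximized on the
  accelerating branch at the root u\* = (3 + √5)/2 of u² − 3u + 1 = 0, so
  x_SDM = x0 − b·ln u\* and F_SDM sits at the universal amplitude fraction
  exp(−u\*) ≈ 0.072946.  The SDM marks the end of the exponential phase.
* **Threshold and quantification cycle.**  Fq = (y0 + F_SDM)/2; inverting
  the model gives Cq = x0 − b·ln(−ln((Fq − y0)/(ymax − y0))), i.e. exactly
  b·ln(1 + ln 2/u\*) ≈ 0.23488·b cycles before the SDM.  The construction
  needs no baseline-phase estimation, the classic failure mode of
  subtraction-based methods.
* **Efficiency.**  F_n = offset + α·E^n fitted over the exponential-phase
  window (below); per-gene efficiencies are averaged arithmetically over
  all usable reactions of the gene (all dilution levels and replicates).
* **Initial target quantity.**  F0 = E_mean^(−Cq).  F0 is on an arbitrary
  fluorescence-derived scale; every evaluation step that follows first
  normalizes it, so only ratios matter.

Savitzky–Golay smoothing is exposed (`smooth_for_display`) for plotting
only.  Smoothing before fitting biases quantification, so no analysis
routine accepts smoothed input; a pipeline test asserts that results are
bit-identical whether or not smoothing was ever invoked.

## Fitting details

* Initialization is deterministic and derivative-free: y0 from the mean of
  the three lowest observations, ymax from the maximum, x0 from the
  half-amplitude crossing, b from half the 25 %→75 % crossing span
  (floored at 0.5 cycles).
* b is optimized on the log scale so it stays positive along the LM path;
  analytic Jacobians are supplied.  Convergence: relative tolerances 1e−10,
  at most 200 iterations' worth of function evaluations.
* **No-amplification rule.**  A well is flagged (never an exception that
  aborts the plate) when the optimizer fails, when the fitted amplitude is
  below 5× the residual standard deviation of the first five cycles, or
  when the fitted rise lies outside the observed cycle range
  (x_SDM < 1 or x0 > n_cycles) — the signature of a noise-chasing fit on a
  flat well.  The last clause is what makes no-template controls robustly
  rejected: a sigmoid "fitted" to pure noise can fake arbitrary amplitude
  by parking its rise before cycle 1, where no data constrain it.

## Efficiency window

The raw Cq→x_SDM span is only ≈ 0.235·b cycles — fewer than two integer
cycles for realistic b — so the window of integer cycles
[⌈Cq⌉, ⌊x_SDM⌋] is extended backwards (never past cycle 1, never past
x_SDM) until it holds at least `min_points` cycles.

`min_points` defaults to **6**.  With the free offset the exponential
model has three parameters; four-point windows leave one residual degree
of freedom and the estimator is ill-conditioned at realistic noise: in
simulation (window SNR profile of the pipeline itself) 4-point fits show
estimator SD ≈ 0.6 with ~20 % of fits running away to the efficiency
bound, while 6-point windows anchor the offset with two baseline-side
cycles and roughly halve both figures.  On noiseless data the extra
cycles are harmless (they are still exponential-phase samples).  The
window size remains configurable.

Efficiency estimates at (or numerically against) the bounds — default
(1.0, 3.0] — are treated as failures and excluded from the gene mean
rather than clipped, so runaway fits cannot bias it.  A gene with no
usable efficiency yields no F0 for any of its wells.

## Evaluation indicators

Inputs are normalized per gene: concentrations divided by the top
concentration (NC, top = 1) and F0 divided by the mean F0 of the gene's
top-concentration replicate group (top-group mean = 1 exactly).  This
removes the arbitrary per-gene fluorescence scale; a test asserts all
indicators are invariant to rescaling any gene's F0.

1. **Bias (ratio form):** |mean-F0 ratio between the extreme levels −
   expected ratio| (10 000 for a 5-point 10-fold series high/low; 0.001
   low/high), averaged over genes.
2. **Bias (slope form):** |OLS slope of log10 F0 on log10 NC − 1|,
   averaged over genes.
3. **Relative error:** mean |(F0 − NC)/NC| over wells.  The signed RE is
   aggregated by absolute value so over- and under-estimates cannot
   cancel.
4. **Coefficient of variation:** sample SD/mean × 100 % per replicate
   group, averaged over levels then genes.
5. **Precision:** within-group sample variance, averaged likewise.
   (Sample, n−1, statistics throughout: groups are size 3 or 11.)
6. **Resolution:** per gene, OLS of log10 NC on log10 F0; the half-width
   h of the two-sided 95 % *prediction* interval at each level's mean
   log10 F0 is converted to a fold 10^h; folds are geometric-mean-averaged
   over levels, then averaged over genes.  Equals 1 in the zero-residual
   limit.  A prediction band (not a confidence-of-mean band) is used
   because resolution asks what fold-change in a *new* observation is
   distinguishable; the implementation is cross-checked against
   statsmodels' prediction intervals.

**Rank synthesis.**  A methods × indicators table (all lower-is-better,
or per-column directions) is ranked per indicator with average ranks for
ties.  The Friedman statistic uses the ties-robust form

    χ² = (k−1)·Σ_j (R_j − n(k+1)/2)² / (Σ_ij r_ij² − nk(k+1)²/4)

with indicators as blocks (n) and methods as treatments (k), defined as 0
for completely tied data; p-values come from the χ²_{k−1} approximation.
That approximation is a *tail* approximation: exact enumeration of the
within-block permutation null shows mid-range p-values run low at small
block counts, so tests assert agreement with the exact null only in the
rejection region, which is where the test is used.

## Simulator

Curves are generated mechanistically, not by sampling the Gompertz model —
fitting the generator's own model would be circular — via

    N_n = N_{n−1}·E_n,   E_n = 1 + (E − 1)·max(0, 1 − (N_{n−1}/K)^h),
    F_n = baseline + drift·n + scale·N_n + ε_n,  ε_n ~ N(0, noise_sd²).

The per-cycle gain is the full efficiency E while product is scarce and is
suppressed by the factor 1 − (N/K)^h as product approaches the carrying
capacity K, stalling exactly at N = K (flat plateau).  The default
exponent h = 2 encodes product–product reannealing, a bimolecular process
(rate ∝ N²) that is the classic driver of the qPCR plateau.  A saturation
law that never reaches E_n = 1 was tried and rejected: its perpetually
creeping plateau means different dilution levels observe different amounts
of "almost-plateau", which biases the fitted shape parameter per level and
stretches the recovered Cq spacing beyond log_E 10 — an artifact of the
generator, not of real reactions, whose plateaus genuinely flatten.

Defaults (the simulated study conditions):

| parameter | default | rationale |
| --- | --- | --- |
| efficiency E | 1.85 | middle of the commonly observed 1.65–1.9 range |
| carrying capacity K | 1e9 copies | plateau onset after ~18–30 cycles across the 15–150 000 copy range |
| hill h | 2 | bimolecular reannealing; smooth, realistic transition (fitted b ≈ 1–2 cycles) |
| fluorescence scale | 5e−10 /copy | plateau ≈ 0.5–1 a.u., baseline 0.05 — normalized-trace magnitudes |
| noise sd | 0.01 | ~1–2 % of plateau, additive Gaussian, seeded |
| n_cycles | 45 | long enough for a 15-copy input to reach plateau |

Dilution plates jitter per-gene efficiency (SD 0.02, clipped to (1.6, 2]),
baseline (SD 0.005) and scale (log-SD 0.05) deterministically from the
seed, emulating amplicon-to-amplicon variation; replicates differ only in
noise.  Ground truth (true E, true N0 per well) is returned alongside.
No-template controls are baseline + drift + noise.

What the simulator does **not** emulate: Poisson sampling of very low copy
inputs, proportional/heteroscedastic noise, inter-plate calibration
offsets, and kinetic outliers/inhibition (reactions whose efficiency
changes mid-run).  Passing tests therefore demonstrate correctness of the
algorithmic chain under realistic curve shapes and additive noise — not
robustness to inhibited reactions, which is a known weak point of
single-curve sigmoid methods generally.

## Numerical choices and degenerate inputs

* Analytic SDM and Cq formulas are guarded by brute-force oracles
  (grid maximization of a numeric second difference; bisection inversion)
  in the test suite and the acceptance script.
* Curve validation: cycles must be consecutive integers from 1 and at
  least 10 cycles long; fluorescence must be finite.  Wells without a
  known concentration simply drop out of indicator computations.
* Windows that cannot reach `min_points` cycles within [1, ⌊x_SDM⌋], and
  constant-fluorescence windows, give `efficiency_failed` for that curve.
* Results CSV: fixed column order, ≥ 9 significant digits, blank numeric
  fields for failed wells; long-dialect plate CSV round-trips floats
  exactly (shortest-repr write, round-trip parse).

## Problem sizes

The test suite and acceptance script run the full simulated designs:
300-curve (20 gene × 5 level × 3 replicate) plates noiseless and across
20 noisy seeds, the 44-curve (4 × 11) high-replication design, 1000-draw
closed-form oracle sweeps, and exhaustive Friedman permutation nulls at
k = 3, n = 4 — sizes chosen to exercise every code path at full design
scale while keeping a complete run in a few minutes on one CPU.
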