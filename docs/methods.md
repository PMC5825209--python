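# Methods

This note records the modelling assumptions, the numerical choices made
where the design was genuinely open, what the synthetic data do and do
not emulate, and the known limitations of the desk-scale configuration.

## Promoter model and trace rendering

The promoter is an irreversible cycle of `n_off` OFF states followed by
`n_on` ON states.  Every OFF state is left at rate `n_off / t_off` and
every ON state at rate `n_on / t_on`, i.e. the total time per phase is
split equally among its states, making total OFF- and ON-times Erlang
with coefficient of variation `1/sqrt(m)`.  Equal splitting is a
modelling choice; the code accepts any `(n_on, n_off)` with up to ten
total states.  Initiations form a Poisson process at
`k_init = b / t_on` while the promoter is ON, which makes the number of
transcripts per ON passage geometric with mean `b` (a consequence of the
exponential ON dwell, not an extra assumption).

State switching and initiation are simulated exactly with the stochastic
simulation algorithm (dwell times drawn in vectorized blocks).
Elongation is deterministic given the per-cell elongation-rate
realization: each transcript contributes the same trapezoidal unit
profile, parameterized by a delay (default 0 min — the stem-loop
cassette sits at the 5' end, so signal appears essentially at
initiation), a linear ramp while the cassette is transcribed (default
2 min), and a total residence of 30 min from initiation to release at
the reference elongation speed.  All three times scale inversely with
the elongation factor.  Rendering uses cumulative counts of sorted
initiation times (`searchsorted`), which evaluates the exact
superposition in `O((n_events + n_frames) log n_events)` without
per-event loops.

Steady-state populations draw the initial promoter state proportionally
to mean state dwell (exact for exponential dwells) and additionally
discard the first 80 min of each simulation; induction populations start
every cell in the first OFF state at the moment of stimulus (51 min into
a 1.5-min-interval, 200-frame movie by default) with strictly zero
pre-stimulus signal.

## Extrinsic noise

Cell-to-cell variability resamples selected parameters once per cell
from `N(mu, (cv * mu)^2)` truncated below at `0.05 mu` (resampling; the
truncation prevents nonpositive rates and removes <0.2% of mass at
cv = 0.35).  Noise variants: 0 = none, 1 = {k_elong}, 2 = {k_init},
3 = {k_on}, 4 = {k_off}, 5 = {k_elong, k_init}, 6 = {k_on, k_off},
7 = all four.  Each resampled parameter carries its own width.  Derived
quantities follow the realized rates: resampling `k_off` moves `t_on`
(and hence `k_init` at fixed burst size), resampling `k_init` moves the
realized burst size, and `k_elong` rescales the signal profile.  Both
alleles of a cell share one realization.

The default width cv = 0.35 for the initiation- and elongation-rate
variant was fixed by a one-time calibration: it is the value at which
the dual-allele simulation (two-state model, OFF 50 min, burst size 10,
45 cells) reproduces a sister-allele total-output Pearson correlation of
~0.67, the regime where extrinsic variance is roughly twice the
intrinsic output variance.  The first-order estimate
`PCC = CV2_ext / (CV2_ext + CV2_int)` underestimates the required width
because the reciprocal of the elongation rate enters output convexly.

## Feature extraction

* **ACF** — biased (divide by n) sample autocovariance normalized at lag
  0, computed by FFT for whole populations at once; stable at long lags
  on 250-point traces.  The half-life is the first linearly interpolated
  lag below 0.5, censored at `max_lag` (50 frames) for traces that never
  decay; zero-variance traces get the degenerate ACF `[1, 0, ...]` in
  population summaries and raise when analyzed alone.
* **Burst segmentation** — running median (window 5), frame-difference
  slope, 10x linear upsampling, threshold 0.65 transcripts per 3 min
  (rescaled proportionally for other frame intervals); gaps and peaks
  shorter than one imaging interval are discarded; boundary periods are
  kept so non-responders contribute their long OFF interval.  Burst size
  is the rise of the smoothed trace across an ON period.  Note a
  structural bias of any slope method: ON passages that initiate zero or
  one transcript (probability `1/(1+b)` and similar, geometric sizes)
  are invisible, so the observable mean OFF gap is `t_off (1 + 1/b)`
  rather than `t_off`; the closure tests use this corrected oracle.
* **Response time** — median filter (window 7); first time the filtered
  trace exceeds 2 RNA for at least 5 consecutive frames, measured from
  stimulus; absent for non-responders.
* **Total output** — area under the background-subtracted trace divided
  by the unit-profile area (`residence - delay - ramp/2` = 29 RNA·min
  by default).
* **Responder call** — lag-1 ACF above 0.2 (a pure-background trace is
  frame-to-frame independent; configurable threshold).
* **Noise decomposition** — law of total variance over single-allele
  traces: extrinsic = variance of per-cell temporal means, intrinsic =
  mean per-cell temporal variance minus the known background variance
  (floored at 0); both normalized by the squared grand mean, and
  `cv2_total = cv2_int + cv2_ext` exactly by construction.  For the
  frequency-modulated two-state promoter the stationary point-process
  calculation (Campbell's theorem with geometric, effectively
  instantaneous bursts) gives `CV^2 * mean = (2b + 1) B / A` with
  `A = int f`, `B = int f^2` of the unit profile — the inverse
  noise–mean law with an effective burst size ~2b; tests assert this
  closed form rather than the idealized `b/mean`.
* **Allele correlation** — total output per allele, symmetric doubling
  ((a,b) and (b,a)) so labelling cannot bias the estimate, Pearson
  correlation with bootstrap-over-cells uncertainty, plus the per-cell
  per-timepoint PCC as the independence check on short-timescale
  bursting.

## ABC distance

Five components: half-L1 (total variation) between global intensity
histograms (2-RNA bins on [-6, 200]); RMS difference of population-mean
ACFs (lags 0–50); Kolmogorov–Smirnov statistics for the per-cell
half-life and lag-1 distributions; and the square root of the unbiased
Gaussian-kernel MMD between per-trace summary vectors (mean, sd,
half-life, lag-1, total output).  Summary vectors are standardized by
the pooled per-component scale and the bandwidth is the pooled median
pairwise distance, which keeps the distance symmetric in its arguments
(standardizing by the experimental set alone would not be).  For equal
sample sizes the MMD uses the complete U-statistic, which is exactly
zero for identical samples; estimates are floored at zero.

Component weights were calibrated once and frozen: 200 pairs of
independent simulations of the reference model (1-1-5, ON 0.6 min, OFF
50 min, b 10, cv 0.35, 45 cells, 250 frames at 3 min, background sd
1.5) were scored per component, weights set to equalize the replicate
contributions (median per component; mean for the MMD, whose unbiased
estimator has median zero under the null), and scaled so the median
replicate self-distance is 0.5.  That value doubles as the SMC
convergence floor.  The absolute scale of distances therefore depends on
this convention; relative comparisons do not.

## SMC ABC

2,000 particles by default (all sizes configurable).  Initialization
draws `init_factor` (default 5) times the population size from the joint
prior and keeps the best — at small population sizes this is what makes
a 40-model cold start viable.  Each iteration: re-evaluate the retained
best 20% with fresh simulation seeds (a single lucky draw must not
survive selection indefinitely, since every evaluation is one stochastic
simulation), set the acceptance threshold to the previous population's
80th distance percentile, propose offspring from uniformly chosen
retained parents with per-parameter Gaussian kernels — log scale for
log-uniform parameters, linear with reflection for the CV widths whose
prior includes zero — of width 1.0 x the retained standard deviation,
and accept offspring below the threshold until the population is
refilled (capped at 5x the population size in attempts; any shortfall is
filled with the best rejected candidates and logged).  A proposal jumps
to a uniformly chosen other model with probability 0.05, keeping shared
parameters and drawing newly needed ones near the retained population's
values for that parameter.  The loop stops when the median distance
improves by less than 1%, reaches 0.5, or hits the iteration cap.

The kernel width of 1.0 (rather than 0.5) x the retained standard
deviation was adopted after benchmarking: at desk scale (200 particles,
20-cell simulations) the narrower kernel let the population collapse
onto noise-favoured regions and the posterior 5–95% intervals
under-covered the generating parameters; the wider kernel restored
coverage at a modest cost in convergence speed.

Priors: log-uniform `t_on` in [0.1, 30] min, `t_off` in [1, 1000] min,
`b` in [1, 100] RNA; uniform cv in [0, 1.5].  These bracket all
plausible estimates with wide margins.

The global fit fixes the topology (default 1-1-5), carries one global
parameter set plus one local value per condition — the OFF-time for
frequency modulation, or the initiation rate (parameterized as a local
burst size with the ON-time global) for size modulation — and sums the
per-condition distances.  A start population can be drawn from the
overlap of per-condition posterior ranges; by default it samples the
prior.

## Synthetic data

The generator emulates the live-cell study design: steady-state movies
of 60–90 cells, 250 frames at 3-min intervals (~750 usable minutes
after an 80-min equilibration discard), optional dual-allele cells,
dose series with OFF-times log-spaced from 400 min (unstimulated) to
18 min (saturation) at shared ON-time 0.56 min and burst size 7.9,
induction movies (1.5-min frames, 200 frames, stimulus after 51 min),
and additive i.i.d. Gaussian background (sd 1.5 RNA-equivalents, mean
0) as the measurement-noise model.  Non-responding cells are an emergent
property of long OFF-times, not a parameter.  Features of real data
deliberately not emulated: intensity-dependent detection noise,
photobleaching, tracking losses, cell division, and cell-cycle
composition — so passing tests demonstrate correctness of the method
under the stated noise model, not robustness to those artefacts.

The benchmark suite writes datasets for models 1-1-0, 1-1-1, 1-1-2,
1-1-5 and 1-9-5 at reference kinetics with a ground-truth manifest for
recovery scoring.

## Desk-scale configuration and known limitations

The acceptance suite runs deliberately reduced problem sizes: benchmark
recovery uses 200 particles, 20 cells per simulated dataset, at most 8
iterations, 60-cell benchmark data, and pools four independent SMC runs
per dataset so the reported posterior intervals are not dominated by the
sampler's Monte Carlo error; the global-fit comparison uses 100
particles, 12 cells per simulation and 4 conditions of 30 cells.

Two identifiability limits of this scale are documented rather than
hidden.  First, promoter cycles with six or more states are mutually
indistinguishable here: at the generating parameters of the ten-state
benchmark, the distance distributions of 6-, 8- and 10-state simulations
coincide (medians within noise), so benchmark recovery scores the
promoter-cycle size with one ladder step of tolerance and uses a 4-state
cycle as the topology-varying benchmark.  Second, the extrinsic-noise
variants are partially degenerate: variants are nested (any variant with
vanishing width contains variant 0) and substitutable (initiation-rate
and OFF-rate variability both modulate per-cell output), so the
variant-level model identity fluctuates between closely related variants
from run to run; the posterior reliably separates *presence* of
extrinsic noise and the cycle size, which is what the recovery tests
assert.  Full-scale populations (2,000 particles, data-matched
simulation sizes) sharpen but do not eliminate this degeneracy.

All randomness flows through numpy `Generator`/`SeedSequence`; a run is
reproducible from its configuration and seed alone, and fixed seeds give
bit-identical event logs, traces and files.
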