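# Methods

## Model and derived quantities

Cumulative above-ground biomass (g/individual) and N and P uptake
(mg/individual) of a species in a given community context are modelled as
a three-parameter logistic in time,
`NU(t) = NU_max / (1 + exp(r (t_max − t)))`, with `t` in weeks after
seedling emergence. The instantaneous rate is its derivative
`r·NU·(1 − NU/NU_max)`, unimodal with maximum `I_max = r·NU_max/4` at
`t_max`. All three derived comparisons — cumulative maxima, peak rates and
peak timing — are closed-form functions of the fitted parameters; no
numeric differentiation or optimisation is involved at analysis time.
`r` is treated as per-week throughout (consistent with a weekly harvest
axis and the magnitude of the reference estimates); a 1/7 constant
(`PER_WEEK_TO_PER_DAY`) converts reported rates to daily units. The
logistic is evaluated through `scipy.special.expit`, which saturates
gracefully for arguments beyond ±700 instead of overflowing.

Only the 3-parameter logistic is offered. Asymmetric growth forms
(Gompertz, Richards) are out of scope by design.

## Estimation

Each (species, context, response, replicate) series is fitted by
unweighted nonlinear least squares in two stages: a damped trust-region
pass (`scipy.optimize.least_squares`, TRF) from heuristic starting values,
then a polishing pass restarted from the stage-1 optimum. Tolerances are
ftol = xtol = 1e−12, gtol = 1e−10, at most 1000 function evaluations per
stage; they are recorded in `fitting.FIT_TOLERANCES`. Bounds are
`NU_max > 0`, `0 < r ≤ 200/week`, `0 < t_max < 2 × last harvest week`.
On noiseless logistic input the fit recovers the generating parameters to
better than 1e−6 relative (exercised routinely in the tests).

Starting values: `NU_max⁰ = 1.05 × max(observed)`; `t_max⁰` the earliest
week reaching half the observed maximum; `r⁰` the slope of a straight line
through `logit(value/NU_max⁰)` over the interior points (5–95% of the
provisional asymptote), floored at 0.05/week. Constant or all-zero series
raise a non-identifiability error; fewer than 5 points (or fewer than 3
distinct weeks) an insufficient-data error.

Covariances come from the Gauss–Newton approximation
`σ̂² (JᵀJ)⁻¹` with `σ̂² = SSE/(n−3)`. A fit is reported `converged=False`
(never an exception) when the optimizer fails or the standard errors are
not finite; additional flags mark a `t_max` estimate at its bound and an
asymptote whose SE exceeds the estimate — both symptoms of series
truncated before the plateau, where a saturating curve is genuinely
non-identifiable.

Default aggregation fits each replicate block separately and reports
mean ± SE (sd/√n) over converged replicate estimates, matching how the
reference trial reports its parameter tables (n = 3); a pooled fit over
all blocks is available behind `per_replicate=False`. Groups with too few
points are skipped with a structured warning, not a crash.

### Calibration caveat

Wald intervals use the t(n−3) quantile. Their coverage is honest
(~92% empirical for nominal 95%) when the residual model matches the
estimator, i.e. under additive Gaussian noise. Under the generator's
default multiplicative log-normal noise the unweighted estimator is
deliberately misspecified (the estimator mirrors the plain least-squares
convention of field practice), and NU_max interval coverage degrades to
roughly 75–80% at CV 10%. Point estimates remain accurate (median NU_max
error ≈ 3% under study conditions); only the stated uncertainty is
optimistic. Users needing calibrated intervals under multiplicative noise
should bootstrap over replicates.

## Comparative statistics

- **Percent contrasts** are ratios of mean parameters,
  `round(100·(a/b − 1))`, half away from zero — the convention that
  reproduces the reference trial's printed "x% more" figures from its
  parameter means. The per-replicate-ratio alternative is deliberately not
  the default; a few of the trial's printed values appear to have used a
  different aggregation and do not reproduce from the table means under
  any single convention (they are documented exclusions in the tests).
- **Peak-rate contrasts** apply the same convention to
  `I = r̄ · N̄U_max / 4` computed from each summary's mean parameters.
- **LER** uses plot-level yields from the final two harvest weeks
  (configurable), pairs mixture and monoculture replicates by block order
  for SEs, and is scale-invariant by construction. Rounding: LER to two
  decimals, contrasts to whole percent.
- **Temporal shifts** are differences of mean `t_max` (first key minus
  second; negative = first peaks earlier), with SE `√(SE_A² + SE_B²)` and a
  two-sided t-test (df = n_A + n_B − 2) labelling the direction or `none`.
- **Letter displays**: one-way ANOVA across contexts gates Tukey HSD
  (`scipy.stats.tukey_hsd`); the compact letter display uses the standard
  insert-and-absorb algorithm with letters assigned by descending group
  mean, so output is deterministic and row-order invariant. Under a shared
  truth with 3 groups of 3 replicates this procedure leaves all groups on
  one letter in ≈95% of datasets at α = 0.05. Welch's ANOVA is available
  for heteroscedastic groups. The reference trial never names its test;
  ANOVA + Tukey at α = 0.05 is adopted as the conventional reading of its
  "post hoc test" language, and no analysis here depends on matching its
  letters exactly.
- **%Ndfa** is the isotope-dilution estimator above. Estimates outside
  [0, 100] are flagged, not clamped — clamping would hide calibration
  problems. Reference averaging takes the plot mean first (each record is
  already the pooled sample of a plot's three sampled individuals), then
  averages across replicate plots. The diversity-level test treats weekly
  means as replicate observations, justified by the absence of a week
  effect on fixation in the emulated trial.

## Synthetic data generator

The generator is first-class, tested code. Its defaults reproduce the
reference trial's design: species oat/lupin/camelina; contexts isolated
single, monoculture, and the oat–lupin and oat–camelina mixtures
(10 species × context trajectories); integer harvest weeks 1–18 after
emergence; 3 replicate plots per harvest (540 records); sowing densities
400/160/592 seeds m⁻² on 0.25 m² plots with a substitutive (half-density)
mixture design. Ground-truth logistic parameters default to the trial's
published estimates for all three responses; the one trajectory the trial
could not estimate (camelina-single N) is filled with a plausible
single-plant value (NU_max = 300 mg, r = 0.9/week, t_max = 16.61 weeks)
scaled from the other species' single/community ratios — it is a synthetic
stand-in, not a published estimate.

Replicate noise is multiplicative log-normal with CV 10% by default
(mean-one factors, so the expected value lies on the curve and values stay
positive); additive Gaussian truncated at zero is offered for sensitivity
checks. Replicates are independent draws around one shared truth — no
block random effect, since the emulated analysis models none. Isotope
values get additive noise of 0.3‰ SD, which propagates to weekly %Ndfa
SEs of ≈5 percentage points at n = 3, matching the magnitudes the trial
reports. Legume δ¹⁵N is synthesized by inverting the %Ndfa estimator at
the prescribed weekly truth (defaults: the trial's weekly Ndfa means per
diversity level, weeks 5–16, with β = −0.5‰ and reference δ¹⁵N = +3.0‰
constant across weeks), so the noiseless round trip is exact by
construction. Plot yields are derived from the biomass curve at the final
two weeks times plants per plot times a fixed harvest-index-like factor
of 0.4; organic-acid totals scale with root dry weight (root:shoot 0.25)
at species rates ordered camelina > oat > lupin. These auxiliary constants
are phenomenological conveniences so every pipeline stage has input, not
agronomic claims.

All randomness derives from one top-level seed via
`numpy.random.SeedSequence.spawn` with substreams assigned in sorted
(species, context) order, making outputs byte-stable and independent of
iteration order.

What the generator does **not** emulate: weather, soil-water and light
competition dynamics, block effects, within-plot spatial structure,
measurement rounding, or any mechanistic link between the three responses
(biomass, N, P are drawn independently around their own curves). Passing
recovery tests therefore demonstrate the estimators' correctness under
the stated noise model, not robustness to real-world violations of it.

## Problem sizes used in the verification suite

Stochastic checks run at desk scale, chosen to finish comfortably on one
CPU while leaving clear margins: parameter recovery uses 200 seeds × 3
replicates of the 18-week design; interval calibration 500 single-series
simulations; the type-I letter-display experiment 500 three-group
datasets; the permutation oracle 60 datasets × 4000 relabelings with
groups of 5 (tiny n = 3 groups make the discrete permutation distribution
disagree with the F test too often near the threshold to be a useful
oracle).

## Known limitations

- Wald interval miscalibration under multiplicative noise (above).
- Per-replicate SEs with n = 3 are themselves noisy; letter displays on
  such groups have limited power.
- The reference-plant rule assumes the oat–camelina oat is an unaffected
  ¹⁵N baseline for mixtures; if that species pair interacts through N, the
  %Ndfa level (not its contrasts) shifts.
- The LER block pairing (mixture block i with monoculture block i) is a
  convention; with fully randomized blocks the SE, not the mean, is
  affected.
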