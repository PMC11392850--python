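# Methods

## The propensity measure

Let |N| be the cumulative NREM sleep (seconds, wake excluded) since the end
of the last REM bout, and let F be the CDF of |N| over REM cycles. The REM
propensity at |N| = n is the conditional probability that the transition to
REM occurs before another Δ seconds of NREM accumulate:

    p_Δ(n) = [F(n + Δ) − F(n)] / [1 − F(n)],     Δ = 30 s by default.

This is a discrete-horizon hazard: unlike the raw CDF (which by construction
increases monotonically and therefore cannot test an hourglass hypothesis),
p_Δ may rise, peak, and fall. F is modelled per |REMpre| bin as a
two-component Gaussian mixture on log |N|,

    k_l·N(μ_l, σ_l) + (1 − k_l)·N(μ_s, σ_s),   μ_l > μ_s,

i.e. |N| is a two-component lognormal mixture. For any such mixture p_Δ has
at least one strict local maximum on a bounded grid and decays to zero as
n → ∞ (the lognormal hazard falls off like log(n/e^μ)/(σ² n)); the pipeline
asserts both properties on every fit rather than assuming them.

### Numerical evaluation

p_Δ for a fitted mixture is computed from survival functions,
p = 1 − S(n+Δ)/S(n) with S the mixture survival (scipy `norm.sf`), which is
exact deep into the upper tail where 1 − CDF loses all precision in double
arithmetic (1 − F underflows around F ≈ 1 − 1e−16, while S remains
representable down to ~1e−300). Only when S(n) underflows to exactly zero is
p defined as 1 (the transition is then numerically certain to have already
occurred) with a warning. The generic `propensity_at`, which accepts an
arbitrary CDF callable, instead treats CDF values within 1e−12 of 1 as 1 to
avoid 0/0.

The curve is evaluated at integer seconds 1…3000. The peak is the largest
|N| among strict local maxima; a plateau of exactly tied values counts once,
at its rightmost point, and grid endpoints are never eligible. Cycles are
grouped BEFORE the peak iff their realized |N| is strictly below the peak
(ties go AFTER).

## Cycle extraction

REM bouts are maximal runs of consecutive REM epochs. Each consecutive pair
of bouts defines a cycle; |N| sums only the NREM epochs strictly between
them, wake (including single-epoch microarousals) is tallied separately. A
cycle is discarded when a single continuous wake bout in its inter-REM
interval exceeds 300 s ("extended wake": the animal was not primarily
asleep); a cumulative-wake variant of the rule is available as a
sensitivity switch. A pair of REM bouts separated by wake alone (|N| = 0)
yields no cycle. A cycle's LIGHT/DARK phase is the phase of its REMpre
onset epoch (epoch midpoint against a half-open [lights-on, lights-off)
schedule), and light and dark cycles are analyzed fully separately.
|REMpre| bins are [0,30), [30,60), [60,90), [90,120), [120,150),
[150,180), and >180 s.

## Mixture fitting

EM on (k_l, μ_l, σ_l, μ_s, σ_s), stopping when the squared Euclidean
distance between successive parameter vectors drops below 1e−10 (cap
10,000 iterations, non-convergence flagged). Twenty random restarts: means
drawn uniformly between the sample's 10th and 90th percentiles, sds uniform
in [0.25·s, 1.5·s] with s the sample sd, k_l uniform in [0.1, 0.9] — scale
free and covering plausible optima. A component sd falling below 1e−3
log-seconds marks the restart as collapsed; it is discarded and redrawn (up
to 10× the requested count). Among converged restarts the fit with the
lowest Kolmogorov–Smirnov statistic against the sample ECDF is kept.
Components are relabelled after every fit so μ_l > μ_s. Natural logs
throughout (the base only rescales parameters).

Goodness of fit uses a Monte-Carlo corrected KS test (Lilliefors-like,
because the parameters were estimated from the same sample): draw replicate
samples of the same size from the fitted mixture, refit each with the same
protocol, and report the fraction of replicate KS statistics ≥ the observed
one. The default refits replicates with the full 20-restart protocol
(faithful but costly); a fast mode initializes the observed fit at a
supplied parameter vector and each replicate refit at the fitted truth — a
single EM start each — which keeps the bootstrap calibrated (rejection rate
at α = 0.05 measured in [0.02, 0.10] over 500 trials at n = 150 with 100
replicates) at ~1/20 the cost.

## Classification and chains

A cycle is sequential iff its |N| is strictly below its bin's cutoff, the
point where the weighted component densities k_l·N_l and (1−k_l)·N_s
intersect (the responsibility crossover). The intersection is the root of a
quadratic in log |N| (linear for equal sds) selected inside (μ_s, μ_l);
degenerate weights or no root between the means mean one class dominates
everywhere, and the bin is labelled all-single. Fixed special-case rules
mirror the degeneracies of the mouse data: the light >180 s bin is
all-single; the dark >180 s and [90,120) s bins borrow the cutoff of the
neighbouring ([150,180) and [120,150)) bin. When a borrow source is itself
degenerate — a real occurrence at dark-phase bin sizes of ~100–150 cycles,
where the lowest-KS EM solution can be two nearly concentric components
with no crossing — the nearby-bin approximation generalizes to the nearest
bin with a numeric cutoff; it is an error only if no bin has one.

Chains: for each single cycle with at least one following cycle in the same
recording, |S| counts the immediately following consecutive sequential
cycles (|S| = 0 when the next cycle is single). A terminal single — the
last cycle of a recording — has no observed successor and is censored
rather than assigned |S| = 0 (a flag includes them as 0 for sensitivity).

## Statistics

The propensity at REM onset is the curve value at the cycle's realized |N|
(nearest grid second; the direct formula beyond 3000 s). Pearson r with the
two-tailed t-test p (t = r·√((n−2)/(1−r²))) is used for: propensity vs
|REMpost|, per phase and before/after-peak group; propensity vs |S|;
propensity vs the 0/1 indicator of a following sequential cycle
(point-biserial by the plain Pearson formula); and propensity vs |S|
restricted to |S| ≥ 1. A maximum-likelihood logistic regression (Wald p) of
the indicator is reported as a companion; perfect separation is flagged,
not fatal. REM fractions are per-cycle rempre/(rempre + |N|) — wake is
excluded so the ratio is sleep composition — compared between single and
sequential cycles and between singles and chains by Welch's
unequal-variance two-tailed t-test; a chain's fraction pools its members'
epochs (Σ rempre / Σ (rempre + |N|)). α = 0.05 everywhere, no
multiple-testing correction.

## Validation procedures

Train/test: an 80/20 seeded uniform split at cycle level; mixtures fitted
on the training cycles, and on the test cycles an empirical propensity
computed at each second t as (# cycles with |N| ∈ [t, t+30)) / (# cycles
with |N| ≥ t), averaged over 30 s bins of t (bins start at t = 1 s;
seconds with an empty denominator are omitted, not imputed as zero).

Surrogate |N|: walk intervals [1, 31), [31, 61), …; at each interval start
compare p30 with a fresh uniform draw; the first interval whose propensity
exceeds the draw yields |N| uniform within it. A cap (default 1e6 s)
guards against non-terminating walks in the extreme tail; capped draws are
flagged, excluded and counted. By construction the probability of firing in
an interval, conditional on survival to it, is exactly p30 at its start, so
the empirical hazard of a large surrogate sample is the Monte-Carlo oracle
for the analytic curve (agreement within ±0.02 on every 30 s bin with ≥500
survivors at 1e5 draws).

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with all latent
truth recorded. Defaults are plausible-scale choices for scored mouse
sleep, not estimates from any recorded dataset:

- per-bin mixtures: μ_s = log 150 s (σ_s = 0.45), μ_l = log 800 s
  (σ_l = 0.5), k_l rising linearly 0.60 → 0.90 across |REMpre| bins
  (sequential cycles are rarer after long REM bouts); the resulting curves
  peak at ≈1350–1550 s with peak propensity ≈0.06–0.09;
- REM bouts: lognormal with median 90 s (σ_log = 0.55), chained — one
  cycle's REMpost duration is the next cycle's REMpre — so recordings are
  realized as alternating bout sequences; ~40 cycles per recording, capped
  at 11.5 h so a recording stays inside one phase;
- wake: Poisson(1.5) bouts per inter-REM interval, lognormal durations
  (median 20 s, σ_log = 0.75), and with probability 0.03 an extended bout
  of 300 s + Exp(120 s) that triggers the discard rule downstream;
- couplings (both zero by default): the propensity at REM onset shifts the
  next REM bout's log-duration by b_rempost·(p30 − 0.05) and the log-odds
  that the next cycle is sequential by b_seq·(p30 − 0.05). The documented
  effect sizes for coupled scenarios are b_rempost = 6 and b_seq = 30 —
  large coefficients only because the propensity's scale is small (sd of
  p30 at onset ≈ 0.015 among coupled cycles), yielding realistic observed
  correlations of r ≈ 0.1–0.15. Couplings act only for light-phase cycles
  with |N| below 80% of their bin's true peak: the margin keeps the
  generating coupling strictly inside the recovered before-peak group, since
  the fitted peak location carries ~±10% noise and a coupling extending
  exactly to the true peak would otherwise leak into the after-peak group
  in about half of all cohorts.

Durations are rounded half-up to whole 2.5 s epochs at rendering; records
carry both real-valued and rounded truths, and extraction recovers the
rounded values exactly. What the generator does **not** emulate: circadian
modulation beyond the binary phase gate, mouse-level heterogeneity,
autocorrelated wake structure, or scorer noise. Passing tests therefore
show the pipeline recovers the assumed statistical structure at realistic
sample sizes — not that real sleep obeys it.

## Problem sizes and reproducibility

End-to-end checks simulate cohorts of 4800 light and 950 dark cycles
(≈4650/920 after the wake filter), matching the scale of the mouse study
the analysis targets; per-bin fits then range from ~20 to ~1700 cycles.
Calibration of the corrected KS test uses 500 trials in fast mode (n = 150,
100 bootstrap replicates; p-value resolution 0.01 suffices for an α = 0.05
decision); type-I calibration of the correlation tests uses 1000
cycle-level replicates with true-parameter propensities, since the null
under test does not depend on the refit. All randomness flows from
numpy `SeedSequence` spawning (per-stage children of one master seed), so
every stage is independently reproducible and reruns are byte-identical.

## Known limitations

- The lowest-KS restart selection can, at small n, prefer a degenerate
  two-concentric-component solution over the separated one; downstream code
  treats such bins as all-single or borrows a neighbour's cutoff rather
  than failing.
- Peak location is a high-variance statistic (the curve is flat near its
  maximum), so before/after group membership is noisy near the peak.
- The per-bin cutoff is a hard threshold; soft responsibility-based
  labelling is out of scope.
- The empirical propensity is undefined at seconds with no surviving
  cycles; bin averages simply omit them, which can bias tail bins when
  survivors are very sparse.
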