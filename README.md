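# rempropensity

Predictive REM-sleep propensity analysis of fixed-epoch scored hypnograms.

During sleep, mammals alternate between REM and NREM sleep in irregular
ultradian cycles. A long-standing hypothesis holds that an "hourglass-like"
homeostatic pressure to enter REM sleep accumulates during NREM sleep and
discharges during REM. Testing it requires a *predictive* measure of REM
pressure. This package implements such a measure for scored rodent sleep
data: the probability of entering REM within the next Δ|N| seconds of
accumulated NREM sleep,

```
p_Δ|N|(|N|) = [F(|N| + Δ|N|) − F(|N|)] / [1 − F(|N|)]
```

a discrete-horizon hazard of the inter-REM interval's NREM duration |N|,
with Δ|N| = 30 s by default. The CDF `F` comes from a two-component
Gaussian mixture fitted to log |N| within bins of the preceding REM bout's
duration |REMpre|:

```
P_GMM(x) = k_l · N(x; μ_l, σ_l) + (1 − k_l) · N(x; μ_s, σ_s),   μ_l > μ_s
```

whose short component captures "sequential" REM cycles (rapid REM/NREM
alternations) and whose long component captures ordinary "single" cycles.

The package provides the full analysis chain for users working with scored
sleep data (and anyone studying duration distributions of alternating bout
processes):

- **hypnogram I/O** — TSV reading/writing, lumping of NREM sub-stages,
  LIGHT/DARK phase labels from the clock schedule (12:12, lights on 07:00);
- **cycle extraction** — REM bouts, |REMpre|, |N| (wake and microarousals
  excluded), |REMpost|, discarding cycles with a wake bout longer than
  5 min, |REMpre| binning ([0,30), [30,60), …, >180 s);
- **mixture fitting** — expectation-maximization with 20 random restarts
  (lowest Kolmogorov–Smirnov statistic wins) and a Monte-Carlo corrected
  (Lilliefors-like) KS goodness-of-fit test;
- **propensity curves** — p₃₀ on the 1…3000 s grid, peak location (largest
  strict local maximum), before/after-peak grouping of cycles;
- **classification** — sequential/single labels via the intersection of the
  weighted mixture components, special-case bin rules, chain counting;
- **statistics** — Pearson correlations (two-tailed t-test) between the
  propensity at REM onset and REM-bout features, a companion logistic
  regression, and Welch comparisons of REM sleep fractions;
- **validation** — train/test empirical propensity and surrogate |N|
  generation from the propensity itself;
- **synthetic data** — a hypnogram cohort generator with known ground truth
  (per-bin mixtures, wake interleaving, configurable couplings), so every
  stage is testable without recorded data.

## Worked example

Fit the mixture to (here, synthetic) log |N| data, evaluate the propensity
curve and the sequential/single cutoff:

```python
import numpy as np
from rempropensity import (GmmParams, fit_with_restarts, evaluate_curve,
                           compute_cutoff)
from rempropensity.gmm import sample_mixture

true = GmmParams(k_l=0.8, mu_l=np.log(800.0), sigma_l=0.5,
                 mu_s=np.log(150.0), sigma_s=0.45)
logn = sample_mixture(true, 1500, seed=0)    # stand-in for log(|N|) data

fit = fit_with_restarts(logn, n_restarts=20, seed=1)
p = fit.params
print(f"k_l={p.k_l:.3f}  mu_l={p.mu_l:.3f}  sigma_l={p.sigma_l:.3f}  "
      f"mu_s={p.mu_s:.3f}  sigma_s={p.sigma_s:.3f}  KS={fit.ks_stat:.4f}")

curve = evaluate_curve(p, delta_s=30.0)
print(f"peak propensity {curve.values.max():.3f} at |N| = {curve.peak_n_s:.0f} s")
print(f"sequential/single cutoff at |N| = {compute_cutoff(p):.1f} s")
```

prints

```
k_l=0.796  mu_l=6.667  sigma_l=0.512  mu_s=4.980  sigma_s=0.429  KS=0.0177
peak propensity 0.066 at |N| = 1343 s
sequential/single cutoff at |N| = 268.3 s
```

The fitted weights and (log-second) means/sds recover the generating
mixture; the propensity rises to a peak of 0.066 at about 22 minutes of
accumulated NREM and decays toward zero beyond it; cycles with less than
about 268 s of inter-REM NREM would be labelled sequential.

A full run over a directory of hypnogram TSVs (one epoch per row, columns
`epoch_index` and `state`):

```
rempropensity run --input-dir hypnograms/ --output-dir out/ --seed 1
```

writes `cycles.tsv`, `fits.tsv`, `curves.tsv`, `peaks.tsv`, the
correlation report `table1.tsv` and the REM-fraction report `table2.tsv`.
`rempropensity simulate` generates a synthetic cohort with ground truth;
`rempropensity validate` adds the train/test empirical-propensity table.

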