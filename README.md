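# distoverlap

Distribution-free overlap between empirical distributions.

## The problem

Researchers comparing two (or more) groups usually summarise the difference
with a mean test (t statistic) and a standardized effect size (Cohen's *d*).
Both lean on distributional assumptions — symmetry, unimodality, a common
parametric family — that real data often violate. The **overlapping index**
η offers an assumption-free alternative: it is the area shared by the two
probability density functions,

    η(A, B) = ∫ min(f_A(x), f_B(x)) dx ,

with η = 1 for identical distributions and η = 0 for distributions with
disjoint supports. Its complement δ = 1 − η is a dissimilarity measure, and
η splits into the two error masses of a classifier that assigns each point
to the taller density, connecting it to Bayes misclassification error.

When the densities are unknown, `distoverlap` estimates them by kernel
density estimation on a shared, equally spaced grid (1,024 points by
default, Gaussian kernel, Silverman's normal reference bandwidth) and
integrates the pointwise minimum with the trapezoidal rule — the plug-in
estimator η̂. For Normal distributions with a common σ the index has the
closed form η = 2Φ(−|μ_A − μ_B| / 2σ), whose argument is half of Cohen's
*d*; this anchors the estimator to classical effect sizes and serves as an
oracle in the test suite.

The package is aimed at applied statisticians and psychologists who want a
normalized, interpretable similarity measure: comparing skewed experimental
groups, bootstrap distributions of model parameters (e.g. mediation
indirect effects), or Bayesian priors against posteriors.

## Worked example

Two groups with equal-looking means but unequal spread and shape
(shifted-Gamma populations with means 1.57 and 3.44, sds 1.78 and 4.32,
skewness 1.41 and 1.93; n = 35 and 30):

```python
import distoverlap as dv
from distoverlap.synthetic import make_skewed_groups
from distoverlap.effect_stats import TwoSampleSummary, welch_t, cohens_d_pooled

a, b = make_skewed_groups(seed=1)
pair = dv.overlap(a, b)
s = TwoSampleSummary.from_samples(a, b)
print(f"eta_hat = {pair.eta:.3f}")
print(f"xpoints = {[round(float(x), 3) for x in pair.xpoints]}")
print(f"Welch t = {welch_t(s).statistic:.2f}, d = {cohens_d_pooled(s):.2f}")
print(f"normal-theory eta = {dv.overlap_from_cohens_d(cohens_d_pooled(s)):.3f}")
```

prints

```
eta_hat = 0.515
xpoints = [-0.766, 2.313]
Welch t = -3.38, d = -0.87
normal-theory eta = 0.663
```

Half the density mass is shared even though the Welch test is clearly
significant and *d* calls the effect large. The empirical η̂ (0.515) is
lower than the value the Normal closed form would predict from the same
means and pooled sd (0.663) — equal-variance Normal theory overstates
overlap on skewed, unequal-variance data. The `xpoints` are the abscissas
where the two density curves cross, usable as empirical cut-off scores.

The same analysis from the shell:

```bash
overlap simulate skewed_groups --seed 1 --out groups.csv
overlap run groups.csv --boot 1000 --seed 1 --out report.json
overlap closed-form --mean-a 17.05 --mean-b 18.54 --sd 6.27
```

`overlap run` writes a JSON report with the pairwise η̂ matrix, intersection
points, bandwidths, grid metadata and (with `--boot`) percentile bootstrap
intervals.

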