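# Methods

## Model

The overlapping index of two probability densities is

    η(A, B) = ∫ min(f_A(x), f_B(x)) dx ∈ [0, 1],

equivalently 1 − ½∫|f_A − f_B| (half the L1 distance to 1), and
equivalently the sum of the two misclassification masses

    η = ∫ f_A·1[f_A < f_B] + ∫ f_B·1[f_B ≤ f_A],

where tie regions are assigned to the second density. For two Normals with
common σ, η = 2Φ(−|μ_A − μ_B|/2σ): a strictly decreasing function of
|Cohen's d|. For unequal σ the overlap is still analytic: the log-density
difference is a quadratic whose real roots are the crossing points, and the
overlap is the sum of CDF masses of the pointwise-smaller density between
consecutive crossings (`closed_form.normal_overlap_general`). These closed
forms are used as oracles throughout the tests, never as the estimator.

## Plug-in estimator

With only samples available, each density is replaced by a kernel density
estimate

    f̂(z) = (1/n) Σᵢ K((z − xᵢ)/β)/β

evaluated on one grid shared by all groups, and η̂ is the trapezoidal
integral of the pointwise minimum. All estimation choices:

| parameter | default | why |
|---|---|---|
| kernel K | Gaussian | standard default; Epanechnikov and biweight selectable |
| bandwidth β | Silverman nrd0: 0.9·min(sd, IQR/1.34)·n^(−1/5) | the normal reference rule is known to work with limited bias for this estimator; per-sample, with quartiles by linear interpolation (R type-7 convention, which matters at small n) |
| grid size | 1,024 equally spaced points | published default for the min-integral; refinement to 8,192 changes η̂ by < 1e−3 |
| grid span | pooled data range ± 3·max bandwidth | mirrors the tail cut-off of classic `density` implementations; the Gaussian kernel carries ≈ 0.1% of mass beyond 3β |
| renormalization | ordinates rescaled to unit trapezoidal mass | the grid truncates kernel tails; without rescaling η̂(A, A) < 1 by the lost mass |

Degenerate inputs fail loudly: fewer than 3 observations or zero spread
raise an error naming the group, and overlap of densities on different
grids raises instead of silently re-interpolating. When one of sd and
IQR/1.34 is zero (heavy ties), the bandwidth rule falls back to the other;
only all-identical samples are rejected.

The direct KDE sum is evaluated exactly. For large n·nbins the evaluation
restricts each grid point to observations within the kernel's numerical
support (8.7β for the Gaussian, where the tail is below double-precision
resolution; 1β for the compact kernels), which is identical to the full
sum at machine precision — a unit test pins the two paths to 1e−12.

### Intersection points

Crossings of the two density curves (`xpoints`, usable as empirical
cut-offs) are the linearly interpolated roots of f̂_A − f̂_B between
adjacent grid points with strictly opposite signs. A run of exact zeros
flanked by opposite signs collapses to the midpoint of the run; tangencies
and identical curves yield no points. This tie convention keeps η̂(A, A) = 1
alongside an empty crossing set.

## Uncertainty

`bootstrap_eta` draws B case resamples within each group independently and
re-runs the whole pipeline per replicate — bandwidths and the common grid
are rebuilt, so their sampling variability is propagated ("variance-
faithful"). Intervals are percentile at the requested level; percentile was
preferred over BCa as the simplest defensible default for a bounded
statistic. One integer seed drives a single `numpy` Generator for the whole
replicate stream. B < 200 is rejected as too unstable for quantiles.

Two caveats are inherent to the estimator, not the interval: η̂ carries a
smoothing bias (for well-separated Normals the kernel widens both tails, so
η̂ slightly exceeds η — about +0.008 at n = 500 for N(0,1) vs N(3,1)), and
the percentile interval does not correct bias. Simulated 95% coverage for
that configuration sits at ≈ 0.87, below nominal; see Limitations.

## Synthetic scenarios

`synthetic` generates the four study-shaped inputs used by the tests and
the `overlap simulate` command. Defaults are the scenario conditions, not
tuning knobs:

* **skewed_groups** — shifted-Gamma groups matching target moments
  (mean, sd, skewness) = (1.57, 1.78, 1.41) and (3.44, 4.32, 1.93) with
  n = 35 and 30; the Gamma solves skewness = 2/√shape exactly, then scale
  and shift match sd and mean.
* **exam_scores** — 22 vs 59 observations; right-skewed (Gamma, skewness
  1.0) males with mean 17.05, sd 6.28, Normal females with mean 18.54,
  sd 6.27.
* **bootstrap_params** — two Normal replicate vectors (B = 1,000) centred
  at 0.23 (sd 0.15) and 0.62 (sd 0.26), emulating bootstrap distributions
  of a mediation indirect effect in two groups, whose population overlap is
  available via `normal_overlap_general`.
* **prior_posterior** — Normal(0.5, prior_sd) prior draws against its
  conjugate posterior after 10 observations with mean 0.75 and declared
  data sd 1.05 (chosen so that the strong prior, sd 0.32, yields a
  posterior mean near 0.62 and the weak prior, sd 0.71, near 0.71);
  4,000 draws by default.

What the generators do **not** emulate: measurement discreteness (exam
scores are integers in reality), dependence between bootstrap replicates
and the original fit, and MCMC autocorrelation in posterior draws. Passing
tests therefore show that the estimator recovers population overlap for
clean i.i.d. draws of the stated shapes, not that any specific published
η̂ value is reproduced — the raw datasets behind those values are
unpublished, so they are validated qualitatively (ranges, orderings,
oracle agreement) rather than as point targets.

## Numerical choices

* Trapezoidal integration throughout; η̂ is clipped to [0, 1] after
  integration (clipping only absorbs float-level excursions).
* The error-mass decomposition uses the same grid and indicator masks, so
  err_A + err_B = η̂ holds to summation-order rounding (≪ 1e−10).
* `normal_overlap_general` uses the closed-form quadratic for crossings;
  the equal-σ, unequal-mean case has the single midpoint crossing, and
  identical parameters return 1 directly.
* `numeric_overlap_oracle` refuses fewer than 1e5 grid points; at 1e6
  points its error for smooth densities is ≲ 1e−10.
* Reports print 6 decimals; all comparisons in tests use numeric
  tolerances, never string equality.

## Simulation sizes

Test-suite simulations use: n = 1e5 per group for the closed-form
agreement sweep (tolerance 0.02), 1e6 grid points for the brute-force
Normal oracle (tolerance 1e−6), 100 seeded fixture pairs for the exact
identities, and 100 repeats × B = 500 for bootstrap coverage at n = 500.
The coverage simulation evaluates densities on 256 grid points, which
perturbs η̂ by far less than the interval's quantile resolution.

## Limitations

* Univariate only; the multivariate min-integral is out of scope.
* η̂ inherits KDE smoothing bias: upward for well-separated smooth
  densities, and the Normal-theory closed form applied to skewed data
  overstates overlap relative to η̂ (this gap is itself a tested property).
* Percentile bootstrap coverage falls below nominal where the smoothing
  bias is an appreciable fraction of the sampling sd (≈ 0.87 observed for
  a nominal 0.95 at n = 500, truth 0.134, bias/sd ≈ 0.8); interpret the
  intervals as descriptive uncertainty, not exact confidence statements.
* Bandwidth selection is per-sample and fixed by rule; no cross-validation
  or sensitivity meta-analysis is provided.
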