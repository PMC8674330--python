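# Methods

## The model

For individual $i$ with binary phenotype $y_i \in \{-1, +1\}$ (control /
case), covariates $\mathbf{x}_i$ (age, sex), genotype $G_i \in \{0,1,2\}$
(minor-allele count), methylation $M_i$ and expression $E_i$, the package
fits the three-layer model

$$
\begin{aligned}
P(Y_i = y_i) &= \sigma\!\big(y_i(\beta_0 + \beta_e E_i + \beta_m M_i
    + \beta_g G_i + \boldsymbol\beta_x'\mathbf{x}_i)\big),\\
M_i &= \alpha_0 + \alpha_g G_i + \varepsilon_{1i},
    \qquad \varepsilon_{1i} \sim N(0, \sigma_1^2),\\
E_i &= \gamma_0 + \gamma_g G_i + \gamma_m M_i + \varepsilon_{2i},
    \qquad \varepsilon_{2i} \sim N(0, \sigma_2^2),\\
G_i &\sim \mathrm{Binomial}(2, p),
\end{aligned}
$$

with $\sigma(v) = 1/(1+e^{-v})$ and independent errors.  The parameter
vector is $\theta = (\beta_0, \beta_e, \beta_m, \beta_g, \boldsymbol\beta_x,
\alpha_0, \alpha_g, \gamma_0, \gamma_g, \gamma_m, \sigma_1^2, \sigma_2^2,
p)$.  An error correlation between the two omics layers is not a free
parameter: the conditional-regression structure ($E$ on $M$) absorbs
between-layer correlation through $\gamma_m$, and the likelihood factorizes
as $E \mid M, G$ times $M \mid G$.

## Missing-data marginalization

Phenotype, covariates and genotype are assumed observed for everyone;
methylation and/or expression may be missing per individual, giving four
observation patterns (complete, $-E$, $-M$, $-(E,M)$).  Rather than imputing,
the likelihood contribution of an incomplete individual is the phenotype
probability *conditional on what was observed*, obtained by integrating the
phenotype layer against the normal law of the unobserved layer(s).

The logistic link has no closed-form Gaussian integral, so inside these
marginalized factors it is replaced by the variance-matching normal CDF,
$\sigma(v) \approx \Phi(v/\beta)$ with $\beta = \pi/\sqrt{3}$ (worst-case
absolute error 0.0227 on a dense grid).  Gaussian integrals of
$\Phi(\cdot)$ are closed-form — integrating $\Phi((a + bt)/\kappa)$ against
$t \sim N(\mu, s^2)$ gives $\Phi\!\big((a + b\mu)/\sqrt{\kappa^2 + b^2
s^2}\big)$ — which yields, per pattern:

* $-E$: $\Phi$ at the linear predictor with $E$ replaced by its conditional
  mean $\mu_0 = \gamma_0 + \gamma_g G + \gamma_m M$, scale inflated by
  $\beta_e^2\sigma_2^2$; times the $N(\alpha_0+\alpha_g G, \sigma_1^2)$
  density of the observed $M$.
* $-M$: the same construction with $M$ replaced by its conditional mean
  given $(E, G)$ (posterior variance $\sigma_1^2\sigma_2^2 / (\sigma_2^2 +
  \gamma_m^2\sigma_1^2)$); times the marginal $E \mid G$ density,
  $N(\gamma_0+\gamma_g G + \gamma_m(\alpha_0+\alpha_g G),\;
  \sigma_2^2+\gamma_m^2\sigma_1^2)$.
* $-(E,M)$: both layers integrated out; the scale picks up
  $\beta_e^2\sigma_2^2 + (\beta_e\gamma_m+\beta_m)^2\sigma_1^2$.

Complete individuals keep the exact logistic link.  Every individual
contributes the Binomial(2, p) genotype mass.  Each closed form is verified
in the test suite against Gauss–Hermite / adaptive-quadrature
marginalization oracles to 1e-5 or better, and the product-integral
identity to 1e-8.

## Estimation

All probability terms are composed on the log scale.  The genotype factor
is separable, so $\hat p$ = (mean genotype)/2 exactly and is profiled out.
For fully observed data the likelihood factorizes further and the MLE is
assembled from two ordinary least-squares layers ($\hat\sigma^2$ = RSS/n)
and an unpenalized Newton logistic regression.  Otherwise the conditional
kernels couple all layers and the joint log-likelihood is maximized with
L-BFGS-B using the analytic gradient (derived per pattern and verified
against central finite differences), box constraints
$\sigma^2 \in [10^{-6}, 10^6]$, coefficients in $[-50, 50]$, convergence at
projected-gradient $10^{-8}$ or relative function change $10^{-11}$, and one
jittered restart (fixed secondary seed) on failure.  Starting values come
from complete-case least squares, a lightly ridged complete-case logistic
fit, and the sample allele frequency — cheap, deterministic, near the
basin.

## Testing

The trio test is the likelihood-ratio statistic $\Lambda = 2(\ell_{\hat
\theta} - \ell_{\hat\theta_0})$ with $\beta_e = \beta_m = \beta_g = 0$ under
the null, referred to $\chi^2_3$; duo/single hypotheses constrain the
corresponding subset (df = subset size).  Tiny negative $\Lambda$ (within
$10^{-6}$) is numerical noise and clamped to zero; anything larger triggers
a cross-started refit.  Batch screens adjust across all trios by
Benjamini–Hochberg.  p-values are asymptotic only — the point of the
closed-form marginalization is to avoid resampling.

## The synthetic-data generator

The simulator emulates the reference simulation design and is the test bed
for every operating characteristic:

* **Genotypes.** Controls: Hardy–Weinberg at MAF 0.2.  Cases: the law
  implied by an additive genotype-relative-risk model — penetrances
  $f_0(1, r, 2r-1)$ with $r = 1.2$, $f_0$ solved from prevalence 0.1 — via
  Bayes' rule.  A multiplicative variant ($f_0(1, r, r^2)$) is switchable.
* **Omics.** The two regression layers with
  $(\alpha_0,\alpha_g,\gamma_0,\gamma_g,\gamma_m) = (1.3, 2.4, 1.9, 0.6,
  2.3)$ and unit variances.  The case–control separation of the
  methylation/expression means ("differ by 0.3") enters as +0.3 on *both
  regression intercepts* for cases, so expression inherits the methylation
  shift through $\gamma_m$ in addition to its own +0.3
  (`shift_mode="intercept"`).  This reading was selected because it
  reproduces the reference complete-data power at all three sample sizes
  (0.72/0.96 simulated vs 0.697/0.950 published at per-stratum 100/200),
  whereas shifting the realized values post hoc (+0.3 on each coordinate,
  kept as `shift_mode="post"`) gives 0.87/0.99.
* **Phenotype.** Retrospective quota design by default: exactly `n_case`
  cases and `n_control` controls with stratum-specific genotype law and
  shift; the phenotype-layer Bernoulli probability (with $\beta_0 = 1$,
  $\boldsymbol\beta_x = (0.01, 0.01)$, $\beta_g = 0.1$, $\beta_m = 0.2$,
  $\beta_e = 0.3$) is recorded per individual for diagnostics.  A
  prospective mode (label a Hardy–Weinberg source population by that
  Bernoulli draw and fill the quotas) is provided; the retrospective mode is
  the default because it reproduces the published power surface.
* **Covariates.** Age $\sim N(40, \text{sd } 6)$ — the 6 is read as a
  standard deviation — and sex $\sim$ Bernoulli(0.5).
* **Missingness.** Completely at random: disjoint per-stratum subsets of
  the configured fractions (both-missing, methylation-only,
  expression-only) are blanked, balanced across cases and controls.  MCAR is
  the minimal mechanism consistent with the likelihood, which conditions on
  observedness.

What the generator does **not** emulate: population structure, batch or
cell-type effects, non-normal omics distributions, informative (MNAR)
missingness, or linkage between multiple trios.  Passing tests therefore
demonstrate correctness of the likelihood machinery and calibration under
the stated generative law, not robustness on real cohort data.

## Operating-characteristic studies and problem sizes

Type I error uses the asymptotic 5% threshold; power uses the empirical 5%
cutoff (95th percentile of the null $\Lambda$ sample for the *same* scheme
and sample size), holding type I error exactly at the nominal level for
comparisons.  Default replicate counts are 2000 (null) and 500
(alternative); the acceptance tests use 2000/500 for complete data,
1200/400 per missingness scheme and 800/400 for the miscellaneous and
sample-size-series cells, always reporting binomial Monte-Carlo standard
errors.  Tenfold cross-validation draws test folds from the complete cases
only (stratified, seeded) while every remaining individual — incomplete
ones included — enters the training fit; classification threshold 0.5; ROC
curves sweep a 101-point uniform grid.  Baselines: complete-case deletion,
observed-column-mean imputation, and KNN imputation (k = 5, Euclidean
distance on standardized covariates + genotype + omics) followed by the
complete-data fit.

## Known limitations and one documented discrepancy

* The reference study's two headline performance numbers are mutually
  inconsistent: complete-data power 0.950 at 200+200 implies a
  likelihood-ratio noncentrality near 17, i.e. a per-individual linear
  discriminability of $d' \approx \sqrt{17/100} \approx 0.41$, which caps
  balanced classification accuracy at about $\Phi(d'/2) \approx 58\%$ for
  *any* classifier.  The generator here reproduces the power surface
  (including its degradation ordering under missingness), and its tenfold-CV
  accuracy is accordingly 55–60% — not the published ">80%".  The
  corresponding accuracy check is kept in the suite and fails; it documents
  the discrepancy rather than papering over it.
* Parameter-recovery bias checks run with the case shift set to zero: the
  shift is a deliberate model violation used to create between-group
  signal, and under it the omics intercepts are estimated as
  stratum-averaged values rather than the generating ones.
* No interaction terms between omics layers; binary phenotypes only;
  single-SNP, single-CpG trios.
* With an entire omics layer 100% missing, only identified parameter
  combinations (e.g. $\gamma_0 + \gamma_m\alpha_0$) are estimable; the
  optimizer still converges but individual layer parameters are then not
  interpretable.
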