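# Methods

## Model and inference

The package models one serum sample at a time against its plate's
beads-only background. Counts are binomial given a per-peptide
read-pull probability $\theta_i$; $\theta_i$ has a Beta prior whose
mean is the beads-only mean $\mu_{i0}$ scaled by the sample attenuation
$c$ and the peptide fold change $\phi_i$, and whose variance is the
beads-only between-sample variance $\sigma^2_{i0}$. A spike-and-slab
prior on $\phi_i$ ($\phi_i = 1$ with probability $1-\pi$; otherwise
$\phi_{\min} + \Gamma(a_\phi, b_\phi)$) makes the enrichment indicator
$Z_i$ the parameter of interest. Only enrichment is modelled
($\phi \ge 1$): antibody reactivity pulls reads, never suppresses them;
apparent depletion of non-reactive peptides is absorbed by $c$.

Hyperparameter defaults encode the applied regime: $\pi \sim
\mathrm{Beta}(2, 300)$ (a fraction of a percent of peptides reactive,
but diffuse enough to support plates with many hits), fold-change slab
$1 + \Gamma(1.25,\ \text{rate }0.1)$ (mode just above the minimum,
heavy right tail, mean 13.5), and $c \sim \mathrm{Beta}(80, 20)$
(attenuation typically 0.5–1, mean 0.8; exactly 1 in mock IPs). The
pre-filter removes peptides whose initial fold-change estimate exceeds
15 from every column (library sizes recomputed) and reports them with
posterior probability 1; leaving such peptides in destabilizes the
chain without changing their call.

Sampling is Gibbs with four blocks:

1. $(Z_i, \phi_i)$ jointly, per peptide, with $\theta_i$ integrated out
   through the beta-binomial marginal: a flip proposal draws $\phi$
   from the prior slab (so the slab density cancels in the
   Metropolis–Hastings ratio), followed by two within-slab refreshes
   for enriched peptides — an independence draw from the slab and a
   multiplicative random walk on $\phi - \phi_{\min}$ (log-normal step,
   sd 0.25, with the Jacobian correction). The collapsed update is
   valid because $\theta$ is redrawn from its full conditional
   immediately afterwards, and all peptides update in parallel since
   they are conditionally independent given $(c, \pi)$.
2. $\theta_i \mid \cdot \sim \mathrm{Beta}(a_i + Y_i,\ b_i + n - Y_i)$
   (conjugate), with $(a_i, b_i)$ evaluated at the current $(c, \phi_i)$.
3. $c$ by univariate slice sampling on $(0,1)$ (stepping-out width
   0.02, capped at 30 steps, shrinkage on rejection).
4. $\pi \mid Z \sim \mathrm{Beta}(a_\pi + \sum Z,\ b_\pi + P - \sum Z)$
   (conjugate).

Defaults are a single chain of 10,000 post-burn-in iterations after
1,000 burn-in, seeded and fully reproducible. With no data ($n = 0$)
the chain provably samples the prior; the test suite verifies the
recovered prior means of $c$, $\pi$ and the slab, and cross-checks the
full posterior against the identical hierarchy run in JAGS on a shared
instance (posterior probabilities agree to < 0.1 absolute, fold changes
to < 5%).

Parameterizations where $f_a$ would be non-positive (variance at or
above $\mu(1-\mu)$) have zero model density; proposals into that region
are rejected and the slice sampler treats them as off-support. $\theta$
is clipped to $[10^{-12}, 1-10^{-12}]$ inside density evaluations.
Initialization follows plug-in maximum likelihood: $\theta$ at observed
proportions, $Z$ at the twice-expected-count rule, $c$ at the
through-origin regression slope over non-enriched peptides, $\phi$ at
attenuation-corrected count ratios; boundary values of $c$ (=1) and
$\pi$ (=0) are moved inside their open supports by offsets of $10^{-4}$
and $1/P$ — the offsets only need to enter the support, their magnitude
is otherwise immaterial.

### Reported summaries

`post_prob` is the ergodic mean of $Z_i$; excluded (pre-filtered)
peptides carry exactly 1. `phi_hat` is the mean of $\phi_i$ over
iterations with $Z_i = 1$ — the fold change *given* reactivity — since
the unconditional mean is shrunk toward 1 by exactly the enrichment
uncertainty that `post_prob` already reports; peptides never sampled as
enriched report 1.

## Beads-prior estimation

Three routes estimate $(a_{i0}, b_{i0})$ from beads-only proportions:
method of moments; per-peptide Beta maximum likelihood (L-BFGS-B, box
constraints $[10^{-6}, 10^6]$, MOM start, MOM fallback on failure,
proportions clipped to $[10^{-10}, 1-10^{-10}]$ because the Beta
likelihood is undefined at the boundary); and the recommended
dispersion-derived route, $\sigma^2_{i0} = \tau_i \hat\theta_{i0}^2$
with empirical-Bayes tagwise $\tau_i$. Degenerate cases: an exactly
zero (or infeasible) sample variance is replaced by the binomial-scale
variance $\mu(1-\mu)/(\bar n + 1)$ at the mean library size — no
overdispersion is invented for peptides whose replicates agree — and
all-zero peptides get half a pseudo-read of mean, $\mu_0 = 1/(2\bar n)$.
Every route ends with the guard raising $a$ to at least 1 with $b$
recomputed to preserve the mean (the mean is far better identified
from million-read counts than the variance).

## Dispersion estimation and exact test

The common dispersion maximizes the summed conditional negative-
binomial log-likelihood given per-peptide totals, computed on counts
linearly scaled to the geometric-mean library size (for equal sizes the
conditional law is free of the mean). Tagwise values maximize the
weighted likelihood $\ell_i(\tau) + w\,\bar\ell(\tau)$ on an 85-point
log-spaced grid over $[10^{-6}, 10]$ with three-point parabolic
refinement; the shrinkage weight $w$ defaults to 10 prior degrees of
freedom (conventional moderation strength), and tagwise → common as
$w \to \infty$. TMM normalization uses trim fractions 0.3 (M) and 0.05
(A) with the beads sample of median library size as reference, factors
normalized to geometric mean 1.

The exact test conditions on a peptide's combined equalized total $z$:
under the null the serum pseudo-count is beta-binomial
$(z,\ 1/\tau,\ N/\tau)$ for $N$ beads samples; below dispersion
$10^{-4}$ this degenerates to the binomial (Poisson-limit) conditional
law, verified against exact rational enumeration. Two-sided p-values
double the smaller tail (capped at 1); one-sided conversion halves them
in the enrichment direction and reflects otherwise; BH controls FDR.
Pseudo-counts are rounded to the nearest integer before conditioning —
with million-read libraries within a factor of two this changes
p-values negligibly. The whole path is cross-checked against edgeR's
classic exact test (Spearman > 0.9 on p-values, log-FC correlation
> 0.99, common dispersion within 30%).

## Synthetic data generator

The generator emulates the statistical structure of real plates rather
than any particular library. Background means are normalized
log-normal draws (σ = 1.5 in log space, giving roughly three orders of
magnitude between the 1st and 99th percentile of background
proportions, as observed in mock IPs). Per-peptide overdispersion
(squared CV of the read-pull probability between mock IPs) is
$\Gamma(2,\ \text{rate }20)$ — mean 0.1, i.e. a between-sample CV
around 30%, comparable to biological-replicate variability in count
sequencing — plus an abundance-linked floor $2\times10^{-6}/\mu$ so
even the rarest peptides stay overdispersed relative to binomial
sampling at million-read depth (low-abundance peptides are noisier in
practice). Library sizes are uniform over $[10^6, 2\times10^6]$ reads.

The default plate is 8 beads-only + 12 serum columns: one beads-only
sample run as serum (a built-in null), one technical-replicate pair
(two columns sharing the same $(Z, \phi, c)$ with fresh probability and
count noise — replicate wells share parameters, not realizations), and
nine independent serum columns. Each serum column has 50 spiked
peptides, 10 in each fold-change bin (1,2], (2,4], (4,8], (8,16],
(16,32], drawn uniformly within the bin (the bin boundaries are fixed;
the within-bin law is a choice). Serum attenuation is drawn from its
$\mathrm{Beta}(80,20)$ prior. Because each column is a collection of
independent binomials, the matrix's library sizes are the realized
column sums, which is also what the estimators consume.

What the generator does *not* emulate: sequencing-level artifacts (PCR
duplication, mapping error), correlated reactivity across related
peptides, and plate/batch effects. Passing tests therefore demonstrate
correctness of the inference under the assumed generative mechanism
and realistic marginal structure, not robustness to those artifacts.

For tests of the evaluation design (null round-robins, calibration),
plates are simulated from a beads prior *estimated* off a first
synthetic plate through the default empirical-Bayes route — the same
two-stage procedure a simulation study uses when seeding parameters
from a real plate. Simulating instead from raw heavy-tailed priors
makes the spike-and-slab flag occasional background outliers that lie
beyond the estimable dispersion tail; that regime measures robustness
to dispersion misspecification, not calibration.

## Evaluation machinery

ROC and PR curves are interpolated onto a shared 501-point grid on
[0,1] (linear interpolation; at tied recall the best attainable
precision is kept; PR curves are anchored at recall 0 with perfect
positive-predictive value), averaged point-wise across datasets, with
AUCs by the trapezoid rule on the interpolated points. Fold-change-bin
curves pool enriched peptides of the bin against all non-enriched
serum-column peptides; beads columns are excluded. The FDR-matched
posterior cutoff is the smallest threshold whose call set keeps the
realized false-discovery proportion at or below the target (1 when
unattainable). Power curves are logistic regressions of detection on
log2 fold change, reporting the fold change at 50% detection; complete
separation is flagged and reported from the separating boundary.
Ranked-list concordance is operationalized as top-k set overlap with
ties broken by peptide id (stable and deterministic); other concordance
definitions would differ only in tie treatment.

## Problem sizes

Default chains are 1,000 + 10,000 iterations; a 1,000-peptide sample
runs in roughly 15 seconds. The shipped benchmark uses two plates of
1,000 peptides with 8 beads-only + 3 serum columns each — large enough
that bin-wise AUCs are estimated from ~60 spiked and ~2,850 null
peptide scores per plate, small enough to run interactively. Test
chains use 2,000–8,000 iterations, which bounds Monte-Carlo error on
posterior probabilities near 0.01.

## Known limitations

* The beads prior is plugged in, not jointly sampled; uncertainty in
  $(\mu_{i0}, \sigma^2_{i0})$ is ignored, which matters most on plates
  with very few mock IPs.
* One chain per serum sample; reactivity shared across samples is not
  borrowed (a joint multi-sample chain is deliberately out of scope).
* The exact test's linear pseudo-count equalization is an
  approximation to quantile adjustment; for library sizes within a
  factor of ~2 the difference is negligible.
* Tagwise dispersion shrinkage can understate the variability of
  extreme-dispersion peptides on small plates, making occasional
  background outliers look enriched; the round-robin utilities exist
  precisely to quantify this on any given plate.
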