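# Methods

## Model family

All three generative models start from the stationary behaviour of the
stochastic logistic model (SLM) with multiplicative environmental noise,

dxᵢ/dt = xᵢ/τᵢ (1 − xᵢ/Kᵢ) + √(σᵢ/τᵢ) xᵢ ξᵢ(t),

interpreted in the Itô sense. Under Itô the stationary density solves the
Fokker–Planck equation with drift x/τ(1 − x/K) and diffusion (σ/τ)x², giving
a Gamma density ∝ x^{(2−σ)/σ − 1} e^{−2x/(σK)}: shape α = (2 − σ)/σ, rate
β = 2/(σK). This is the reason the Itô convention is the right one here —
Stratonovich would shift the polynomial exponent and break the α ↔ σ
dictionary the whole package is built on. `simulate_slm` integrates the SDE
by Euler–Maruyama and is tested against the analytic Gamma on a
(σ, K) grid; the growth timescale τ only sets the relaxation clock and is
ignored by every stationary computation.

Compositionality turns S independent Gamma species into a Scaled Dirichlet
distribution on the simplex (2S parameters). Two macroecological laws
collapse this to a fittable model:

* **Taylor's law** σ²ᵢ = A·x̄ᵢ^ζ fixes αᵢ = x̄ᵢ^{2−ζ}/A, βᵢ = x̄ᵢ^{1−ζ}/A.
  Only the ζ = 1 (Dirichlet) and ζ = 2 (Symmetric Scaled Dirichlet, all
  shapes equal to 1/A) limits are implemented; empirical gut data sit at
  ζ ≈ 2.
* **The MAD** supplies the x̄ᵢ themselves: Log-Laplace
  e^{−|log x̄ − μ|/λ}/(2λx̄) by default, Log-Normal as the alternative.

Sampling closes the models: multinomial at the per-sample depth N_r for MD
and MSSD (strict compositionality — column sums equal depths exactly),
per-species Poisson(N_r vᵢ) for the PSLG (compositional on average only;
its mean abundances are renormalised to sum to one before sampling). The
MSSD is invariant under rescaling of its rates, so its location parameter μ
drops out and it carries exactly two free parameters (λ, A). Scaled
Dirichlet sampling is by normalisation of independent Gamma draws, which is
exact; the sampler is tested against quadrature CDFs of the density at
S = 2 and 3.

Generation follows a five-step recipe: fit (μ, λ, A) from the table with no
cutoff; draw S mean abundances from the fitted MAD; build (α, β) through the
Taylor constraint; draw one composition per sample; draw counts at the
table's own depths; apply the cutoff last, to the finished counts.

## Cutoffs and patterns

Relative-abundance cutoffs κ ∈ {4.5×10⁻⁷, 9×10⁻⁶, 1.8×10⁻⁴} (low, medium,
high) mimic false-positive removal: entries with vᵢⱼ < κ are zeroed after
count generation and the surviving counts are *not* renormalised (a
`renormalize` flag exists, default off), so presence/absence, occupancy and
diversity follow the thresholded table directly. Relative abundances are
always counts divided by the per-sample classified-read total.

Patterns: per-species mean abundance and occupancy; Taylor (mean, unbiased
n−1 variance) points with zeros counted as true zeros and species below 50%
occupancy excluded by default (their variance is detection noise);
α diversity per sample and pooled γ; the abundance–occupancy curve (mean
occupancy in 20 log-spaced abundance bins, empty bins dropped, bin edges
recorded in the output); the SAD (log-binned histogram, either pooled
"metacommunity" scope or per-sample histograms averaged on a common grid —
both are exposed because either reading is defensible); and the metagenomic
species–area relation (unique species in a growing random aggregate of
samples, normalised by γ, against cumulative classified reads, averaged
over 50 random orderings by default, seed-controlled).

## Fitting

**MAD.** Per-family maximum likelihood on log x̄: Laplace (μ = median,
λ = mean absolute deviation) vs Normal (μ = mean, λ = SD). Family selection
uses BIC = k ln n − 2 lnL with k = 2 for both, computed from the
log-transformed data — the 1/x Jacobian is common to the families and on the
log scale both BICs are positive at microbiome scales, which is what makes
the ratio convention (BIC_LN/BIC_LL > 1 favours Log-Laplace) well defined. A
sign guard rejects the ratio otherwise and ΔBIC = BIC_LL − BIC_LN is always
reported as the fallback. Zeros are excluded (count logged).

**Taylor's law.** OLS of log variance on log mean; the free fit estimates
(ζ, A), the constrained fit pins ζ and takes log A as the mean residual
offset. Both R² values and their ratio are reported.

**Finite-depth bias and the debiased amplitude.** At depth N a species with
mean v carries ≈ v/N of read-sampling variance on top of its compositional
variance A·v². Near the detection threshold the sampling term dominates, so
the raw free-fit slope on counts sampled at N = 10⁵ comes out ≈ 1.89 rather
than 2, and the raw amplitude is inflated — by the sampling term and, for
heavy-tailed MADs where one species can hold a large share of the
community, by the common-mode variance of the normalising total
(first order: a factor 1 + Σwⱼ² − 2wᵢ on species i, w the mean-abundance
weights). Three estimators address this, in increasing order of robustness:

1. `taylor_points(..., sampling_correction=True)` subtracts the estimated
   within-sample variance v(1−v)/(N−1) — this alone restores the free slope
   to 2.00 ± 0.02 at the reference conditions;
2. `debiased_taylor_points` additionally divides out the first-order
   compositional factor;
3. `estimate_amplitude` abandons the regression entirely for ζ = 2: every
   species shares the Gamma shape α = 1/A, and on the log scale
   Var(log vᵢ) = ψ′(α) + C with C the common mode, which is directly
   estimable as the median cross-species covariance of log abundances over
   "core" species (always present, share < 0.2). Inverting the trigamma
   gives α̂. This survives even cohorts where one species holds 99% of the
   reads, where the first-order factor fails.

`fit_model` (and the `CompositionalEcologyModel` front end) uses the MAD MLE
for (μ, λ) and, with `debias=True` (default), estimator 3 for the ζ = 2
amplitude; the raw OLS fit is always retained as the pattern-level
diagnostic in the returned `TaylorFit`. Recovery at S = 500, R = 200,
depths 10⁵–10⁶: median λ̂ within 5% and Â within 20% of truth (typically
within 4%). Uncertainties are nonparametric bootstrap standard errors over
species (1000 resamples by default in `bootstrap_se`, 200 in `fit`).

## Model comparison

For each candidate model: fit at κ = 0, generate `n_realizations` matched
cohorts (S = γ of the table, same R, the empirical depth vector verbatim),
apply each κ to data and simulation alike, compute each pattern, and score
with 1 − SS_res/SS_tot against the empirical curve (model curves are
interpolated onto the empirical abscissa, clamped at the ends). The cell
score is the mean over realizations; 500 realizations by default, a few
dozen suffice for the tests. Occupancy is scored through rank pairing:
empirical and simulated species are each sorted by mean abundance (ties
broken by occupancy, making the pairing label-independent) and compared
occupancy-to-occupancy. Diversity is scored on the sorted vector of
per-sample α values with γ appended. Seeding is per model name, so the
report is invariant to the order models are listed.

Scores can be arbitrarily negative — a washed-out species–area curve under
the high cutoff routinely produces large negative values — and are undefined
(raised as errors) when the empirical curve has no variance, e.g. when every
species is present everywhere.

## Synthetic cohorts

`healthy_profile()` (S = 500, R = 91, σ = 0.8) and `unhealthy_profile()`
(S = 800, R = 202, σ = 1.2) emulate a healthy and a dysbiotic cohort with
shared λ = 1.41 and log-uniform depths in [10⁵, 10⁶]. The sample counts
match the cohort sizes of the gut shotgun meta-analysis the package's
defaults emulate; the σ values bracket the healthy/dysbiotic boundary σ = 1
(equivalently A = 1), where the Gamma abundance-fluctuation distribution
switches from modal to zero-diverging; λ matches the fitted MAD scale of
those cohorts; μ = −9 places the MAD bulk at ~10⁻⁴ relative abundance so
that a 500-species pool is compositionally consistent (the realized
community total is of order one). `paired_cohorts` shares the MAD draw
between the two profiles (common random numbers, the smaller pool a prefix
of the larger) — with independent draws the heavy-tailed MAD's
across-realization variability swamps the σ contrast in α diversity.

What the generator does *not* emulate: species interactions, longitudinal
autocorrelation, classification error structure beyond what cutoffs remove,
and any taxonomic identity. Tests passing on these cohorts demonstrate
estimator and protocol correctness under the stated generative assumptions,
not the adequacy of those assumptions for any particular real dataset.

## Numerical choices and limitations

* Logs are natural throughout; λ values are on the natural-log scale.
* Euler–Maruyama requires dt ≤ 0.1 τ (enforced); trajectories are clipped
  away from zero to absorb rare discretisation overshoots; non-finite
  excursions raise with advice to reduce dt.
* Gamma draws are clipped at the smallest positive float before
  normalisation, which matters only for absurdly small shapes.
* The trigamma inversion is bracketed in [10⁻⁴, 10⁴]; outside that range
  the amplitude estimate saturates. With fewer than 4 usable core species
  it falls back to the regression estimator.
* MSSD and PSLG are near-twin models (fixed vs on-average total reads);
  their pattern scores are statistically close at realistic depths, and
  occupancy is the pattern that separates them best (the PSLG tends to
  underestimate occupancy, lacking the multinomial's hard total).
* The heavy-tailed Log-Laplace MAD has no finite mean at λ > 1: single
  realizations can be dominated by one species, which is both a real
  feature of gut communities and the main source of across-realization
  score dispersion. Mean scores over realizations remain well defined but
  converge slowly for diversity-type patterns.
* Single-cohort Taylor-slope estimates for the MD at small A rest on few
  occupancy-filtered species and are noisy; median-over-replicates is the
  stable summary.
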