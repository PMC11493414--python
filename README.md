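# macrobiota

Macroecological modelling of gut-microbiome count tables: constrained
compositional generative models, the emergent patterns they are scored
against, and an R²-based model-comparison protocol for healthy versus
dysbiotic communities.

## The problem

Shotgun metagenomics reduces a gut microbial community to a species × sample
table of read counts. Three confounders stand between that table and any
ecological statement: read sampling (rare species are missed), false-positive
species (removed with relative-abundance cutoffs κ), and compositionality
(abundances are forced to sum to one). Yet such tables show robust
macroecological regularities — a heavy-tailed **mean abundance distribution**
(MAD), **Taylor's law** σ²ᵢ = A·x̄ᵢ^ζ with ζ ≈ 2, and characteristic
abundance–occupancy, species-abundance, species–area and diversity patterns.

`macrobiota` implements the modelling chain that connects these patterns to a
stochastic logistic model (SLM) of population dynamics,

dxᵢ/dt = xᵢ/τᵢ (1 − xᵢ/Kᵢ) + √(σᵢ/τᵢ) xᵢ ξᵢ(t),

whose stationary abundance-fluctuation distribution is Gamma with shape
αᵢ = (2 − σᵢ)/σᵢ and rate βᵢ = 2/(σᵢKᵢ). Normalising S independent Gamma
species onto the simplex gives the **Scaled Dirichlet** distribution;
constraining its 2S parameters with Taylor's law (αᵢ = x̄ᵢ^{2−ζ}/A,
βᵢ = x̄ᵢ^{1−ζ}/A) and the MAD leaves at most three free parameters
(μ, λ, A). Convolving with read sampling yields three generative models of
count tables:

| model | composition | sampling | ζ | free parameters |
|-------|-------------|----------|---|-----------------|
| MD    | Dirichlet | multinomial | 1 | μ, λ, A |
| MSSD  | Symmetric Scaled Dirichlet | multinomial | 2 | λ, A |
| PSLG  | independent Gammas (compositional on average) | Poisson | 2 | μ, λ, A |

The Taylor amplitude doubles as an ecological dial: σ = 2A/(1 + A), the
width of environmental growth-rate fluctuations. σ < 1 gives a modal
abundance-fluctuation distribution (stable, healthy-like species); σ > 1 a
zero-diverging one (high turnover and local extinction, dysbiotic-like).

## Worked example

```python
import macrobiota as mb

# a synthetic healthy-like cohort: 400 species, 91 samples, sigma = 0.8
table, truth = mb.generate_cohort(mb.healthy_profile(S=400, R=91), seed=42)

res = mb.CompositionalEcologyModel(table, model="mssd").fit(n_boot=200, seed=0)
print(res.summary())
```

```
Compositional ecology model fit
==============================================
model:            MSSD  (zeta = 2)
table:            S = 400, R = 91, gamma = 400
free parameters:  lam, A  (2)
----------------------------------------------
MAD family:       log_laplace  (BIC ratio LN/LL = 1.012)
lambda (MAD scale)      1.3998  +/- 0.0556
A (TL amplitude)        0.6536  +/- 0.0101
sigma (noise)           0.7905  (< 1: healthy-like)
----------------------------------------------
TL free exponent        2.0089  (R2 free 0.9927)
TL fixed exponent       2.0000  (R2 fixed 0.9927, ratio 1.0000)
TL species used            388
MAD species used           400  (0 zero excluded)
```

The generator's ground truth was λ = 1.41, σ = 0.8: the fit recovers both
(λ̂ = 1.40 ± 0.06, σ̂ = 0.79), selects the Log-Laplace MAD by BIC, and
confirms ζ = 2 scaling (R² ratio 1.000). `res.simulate(n)` then draws
matched cohorts (same species pool, samples and read depths), and
`res.compare(...)` scores candidate models against the table pattern by
pattern and cutoff by cutoff — e.g. with `models=("mssd", "md")` the MSSD
row dominates the abundance–occupancy score at every κ (0.993–0.998 vs
0.507–0.963 for the MD) on the cohort above, while both models reproduce the
SAD, which is exactly why the SAD carries little discriminating power.

The same pipeline is scriptable from a shell:

```bash
macrobiota generate --profile paired --seed 1 --out cohorts/
macrobiota fit --input cohorts/cohort_H.tsv --model mssd --out fit_H.json
macrobiota compare --input cohorts/cohort_H.tsv --models mssd,pslg,md \
    --kappas paper --n-real 500 --seed 2 --out scores_H.tsv
```

Count tables are plain TSV (species rows, sample columns, integer counts);
cutoffs default to κ ∈ {4.5×10⁻⁷, 9×10⁻⁶, 1.8×10⁻⁴}.

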