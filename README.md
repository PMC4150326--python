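# ecohurdle

Hurdle occurrence–abundance mixed models for synthetic analyses of land-use
impacts on tropical-forest communities.

## The problem

Compiled multi-study biodiversity datasets record, per study, the abundance
of each sampled taxon at a network of sites spanning different land uses.
Synthesising such data into a global picture of how individual species
respond to human pressure raises several entangled methodological problems:

* Most records are zeros, and abundance measures are heterogeneous and
  effort-dependent, so occurrence and abundance must be modelled in two
  stages (a *hurdle*): presence/absence with a binomial-logit GLMM, and
  natural-log abundance given presence with a Gaussian LMM, both with
  crossed random intercepts for study, site-within-study and taxon.
* One of the pressures — vegetation offtake — is not observed directly but
  extracted from satellite NDVI time series as **iNDVI**, the integrated
  area between the 16-day composite curve and its minimum over the three
  years up to and including sampling, after quality filtering,
  interpolation, and screening of unflagged cloud spikes.
* Model criticism must ask whether residuals carry phylogenetic signal
  (Pagel's λ on a Grafen-scaled taxonomy tree) or within-study spatial
  autocorrelation (per-study Moran's I with a binomial meta-test).

No such compiled dataset ships with this package. Instead, `ecohurdle`
implements the complete analysis as a tested pipeline and pairs it with a
**synthetic-data generator** whose ground truth is known exactly, so every
stage — effort correction, occurrence derivation, iNDVI extraction,
backward stepwise model selection, R²_GLMM, λ and Moran diagnostics, and
the derived community-abundance index — can be validated end to end.

## The model

For record *i* (taxon *t* at site *s* of study *j*):

```
logit P(present_i) = x_i' beta + u_j + v_s + w_t          u ~ N(0, σ²_study)
log(abund_i | present) = x_i' gamma + ...  + eps_i        eps ~ N(0, σ²)
```

Fixed effects: land use × taxonomic group, plus human population density
(log(x+1)), forest cover and iNDVI (all standardised), their pairwise
interactions, interactions with group, and pair × group three-ways.
Estimation is maximum likelihood — a Laplace approximation for the
binomial stage (exact for the Gaussian stage) with analytic gradients —
and the minimum adequate model is found by backward stepwise elimination
under marginality, each drop tested by likelihood-ratio χ².

The **community-abundance index** for group *g* in land use *L* is

```
CI(g, L) = [invlogit(b0_g + Δocc) / invlogit(b0_g)] × exp(Δabund)
```

where `Δocc`/`Δabund` are the linear-predictor contrasts versus primary
forest and `b0_g` is the group's primary-forest occurrence logit; it is 1
in primary forest by construction.

## Worked example

```python
from ecohurdle import GeneratorConfig, run_pipeline

config = GeneratorConfig(n_studies=8, sites_per_study=(8, 14),
                         taxa_pool_size=120, taxa_per_study=(6, 12), seed=7)
result = run_pipeline(config, outdir="example_run")
print(result.r2.to_string(index=False))
print(result.index.head(6).to_string(index=False))
print("occurrence lambda:", round(result.phylo["occurrence"]["lambda_hat"], 3),
      " Moran fraction:", result.autocorr["occurrence"]["fraction"])
```

prints

```
  response  marginal  conditional
occurrence  0.113482     0.205852
 abundance  0.130453     0.521053
        group             land_use    value
        birds       primary_forest 1.000000
        birds secondary_vegetation 1.504204
        birds      wood_plantation 1.380312
invertebrates       primary_forest 1.000000
invertebrates secondary_vegetation 0.239552
invertebrates      wood_plantation 0.269425
occurrence lambda: 0.0  Moran fraction: 0.125
```

Reading this: the pressures explain ~11% of occurrence variation on their
own (marginal R²) and ~21% once study/site/taxon effects are added
(conditional); in this simulated world, birds that persist outside primary
forest do well (index > 1) while invertebrate community abundance drops to
~24–27% of its primary-forest value; residuals carry no phylogenetic
signal and one of eight studies is flagged for spatial autocorrelation
(about what chance produces at α = 0.05).

`run_pipeline` also writes the full report bundle (term-test table shaped
like a stepwise-ANOVA table, coefficients, variance components, relative
effects, community index, per-study Moran results, phylogenetic-signal
JSON, and a run manifest) under `example_run/`.

The same pipeline is scriptable from the shell:

```bash
ecohurdle run-all --seed 7 --outdir example_run
ecohurdle simulate --seed 7 --outdir example_run   # or stage by stage
```

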