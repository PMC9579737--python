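# floradyn

Trait-based design and temporal-dynamics analysis of sown flower-strip
plant communities.

Flower strips — sown herbaceous margins in crop fields — are created to
support arthropods and the services they deliver. Whether a seed mixture
actually produces, and keeps, a functionally diverse plant community over
several years depends on its initial species richness and functional
diversity. `floradyn` packages the full quantitative workflow for studying
that question: it designs seed assemblages crossing species richness with
functional dispersion, computes trait-based diversity metrics from vegetation
surveys, runs name-shuffling null models, fits AIC-ranked candidate model
sets with full model averaging, and ships a mechanism-level succession
simulator so the entire pipeline can be exercised and validated without
field data.

It is aimed at community ecologists working with species × trait tables and
long-format percent-cover surveys.

## The metrics and models

For a community with relative abundances $p_i$ and a mixed-type Gower
dissimilarity $d_{ij} \in [0, 1]$ between species:

- **Gini–Simpson diversity** $D = 1 - \sum_i p_i^2$ and **Simpson's
  evenness** $E = (1 / \sum_i p_i^2) / S$ with $S$ the species richness;
- **Rao's quadratic entropy** $Q = \sum_{ij} d_{ij}\, p_i p_j$ (a
  `convention="divc"` option uses $d_{ij}^2/2$, the form used by the
  redundancy framework's reference implementations);
- **functional redundancy** $FR = D - Q$;
- **functional dispersion** $FDis = \sum_i p_i \lVert x_i - c \rVert$, the
  abundance-weighted mean distance to the abundance-weighted centroid
  $c = \sum_i p_i x_i$ in a principal-coordinates embedding of the Gower
  matrix (Cailliez-corrected when non-Euclidean);
- **community-weighted means** $CWM = \sum_i p_i t_i$ of numeric traits;
- **standardised effect sizes** $SES = (FDis_{obs} - \overline{FDis_{null}})
  / sd(FDis_{null})$ from a null that shuffles species names on the trait
  matrix (1000 iterations by default), preserving trait covariance and
  community structure;
- **multimodel inference**: all marginality-respecting combinations of the
  predictors and their interactions with time since sowing, fitted by
  maximum likelihood as (generalized) linear mixed models with plot nested
  in transect as random intercepts; candidates ranked by AIC, those with
  ΔAIC < 4 selected, coefficients full-averaged (zero substitution) with
  95% confidence intervals, plus marginal/conditional pseudo-R².

Gaussian mixed models delegate to statsmodels `MixedLM`; Poisson mixed
models use an in-package Laplace-approximation fitter (cross-checked against
`lme4::glmer` in the test suite).

## Worked example

```python
import floradyn as fd
import numpy as np

# synthetic study: 151-species pool, 8 designed assemblages, 48 plots, 4 years
bench = fd.make_benchmark(fd.SimConfig(seed=0))

# sown functional dispersion and redundancy of the designed mixtures
report = fd.verification_report(bench.designs, bench.pool)
print(report[["assemblage", "richness", "fdis", "redundancy"]].round(3))

# temporal dynamics of realized diversity
met, results = fd.run_dynamics_analysis(bench.survey, bench.pool, bench.designs)
print(results["fdis"]["full"].coefficients.round(3))
```

This prints the design verification table (high-FD assemblages out-disperse
the low-FD ones at equal richness; redundancy rises with richness in the
high-FD series):

```
  assemblage  richness   fdis  redundancy
0      HFHS1        29  0.784       0.590
1      HFHS2        29  0.785       0.589
2      HFLS1         9  0.800       0.479
3      HFLS2         9  0.797       0.482
4      HFMS1        14  0.795       0.532
5      HFMS2        14  0.801       0.524
6      LFMS1        14  0.748       0.595
7      LFMS2        14  0.732       0.616
```

and the full-averaged model for functional dispersion:

```
                           term  estimate    se  abs_z  ci_lower  ci_upper
                      Intercept     0.741 0.064 11.604     0.616     0.866
             initial_fd[T.high]    -0.094 0.058  1.613    -0.207     0.020
     initial_richness[T.medium]     0.043 0.043  0.979    -0.043     0.128
       initial_richness[T.high]     0.031 0.036  0.842    -0.041     0.102
                           time    -0.106 0.020  5.256    -0.146    -0.066
        initial_fd[T.high]:time     0.058 0.020  2.823     0.018     0.098
initial_richness[T.medium]:time     0.004 0.008  0.481    -0.013     0.021
  initial_richness[T.high]:time     0.002 0.006  0.366    -0.010     0.014
```

Realized functional dispersion declines over the four years (negative
`time` slope), and for this seed the decline is significantly attenuated in
assemblages sown with high functional dispersion (positive
`initial_fd[T.high]:time`, CI excluding zero). The attenuation by initial
species richness appears as a positive `initial_richness:time` interaction
across replicate simulations (the parameter-recovery test measures its
detection rate over 100 replicates); in any single run it may be weak, as
here. Numbers vary with the seed.

The same stages are available from the shell:

```bash
floradyn simulate --seed 0 --out bundle/     # write pool, designs, survey
floradyn all --seed 0 --out results/         # metrics, SES, fits, invasion
```

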