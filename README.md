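# caprigen

Bayesian genetic analysis of parity-wise binary abortion traits in
pedigreed dairy-goat herds.

Abortion is a major source of reproductive loss in intensive goat
production. Whether selection against it is worthwhile depends on how
heritable the liability to abort is in each parity and how strongly the
parities are genetically connected. `caprigen` provides the complete
analysis chain for that question:

- **pedigree algebra** — reading and validating animal/sire/dam pedigrees,
  inbreeding coefficients (Meuwissen–Luo), the numerator relationship
  matrix `A` and its sparse inverse (Henderson's rules with inbreeding);
- **threshold and linear animal models** — single-chain Gibbs samplers for
  univariate and multivariate models on the liability scale
  (`y = 1{Xb + Za + e > 0}`, `a ~ N(0, A ⊗ G0)`), with latent-liability
  augmentation for binary records, numba-compiled sweeps, and group moves
  that repair the notoriously slow scale mixing of single-site samplers;
- **posterior summaries** — means, posterior standard deviations, shortest
  95% HPD intervals, effective sample sizes, trace export;
- **genetic parameters** — draw-wise heritabilities `h² = g/(g+1)` and
  genetic/phenotypic correlations, presented as the familiar trait × trait
  grid (h² on the diagonal, genetic correlations above, phenotypic below);
- **model comparison** — doe-stratified k-fold cross-validation of the
  four variants (linear/threshold × univariate/multivariate) by Pearson
  r(y, ŷ) on held-out records;
- **risk factors** — logistic regressions of abortion status on year,
  season and age class with odds ratios, Wald intervals and joint factor
  tests;
- **a synthetic-herd generator** — multi-generation pedigrees with a 15:1
  doe-to-buck mating ratio and liability-scale records with configurable
  heritabilities, correlations, incidences and record attrition, so the
  whole pipeline is testable without proprietary herd data.

## Worked example

```python
from caprigen import (SimulationConfig, simulate_dataset, ModelSpec,
                      GibbsConfig, run_gibbs, derive_parameters,
                      parameter_matrix, render_matrix)

# the default synthetic study herd: ~3,000 phenotyped does over three
# generations, liability h2 (0.25, 0.11, 0.19), genetic correlations
# (0.23, 0.29, 0.48), incidences near (0.15, 0.18, 0.15)
cfg = SimulationConfig(seed=101)
ds = simulate_dataset(cfg)
print(ds.records.groupby("parity")["outcome"].agg(["count", "mean"]))

spec = ModelSpec(traits=(1, 2, 3), scale="threshold")
chain = GibbsConfig(n_iter=20_000, burn_in=2_000, thin=20, seed=11)
samples = run_gibbs(ds.records, ds.pedigree, spec, chain)
grid = parameter_matrix(derive_parameters(samples))
print(render_matrix(grid))
```

Output (the first block from the `groupby`, the second from
`render_matrix`; about 90 seconds on one core):

```
        count      mean
parity
1        3084  0.161479
2        2539  0.181568
3        1844  0.162148

	1	2	3
1	0.30±0.07(0.16:0.45)	0.41±0.17(0.08:0.70)	-0.01±0.23(-0.47:0.34)
2	0.08±0.04(-0.00:0.16)	0.16±0.05(0.07:0.27)	0.11±0.31(-0.56:0.54)
3	-0.06±0.06(-0.17:0.05)	0.06±0.06(-0.06:0.16)	0.26±0.11(0.05:0.45)
```

Reading the grid: the diagonal holds liability-scale heritabilities
(posterior mean ± posterior SD with the 95% HPD interval) — parities 1–3
come out at 0.30, 0.16 and 0.26 against generating values 0.25, 0.11 and
0.19. Above the diagonal are genetic correlations (wide HPDs: with binary
records the genetic/residual split of the covariance is weakly identified
even at this scale), below it phenotypic correlations, which are much
sharper.

The same pipeline is scriptable from the shell:

```bash
caprigen simulate --seed 1 --out runs/sim
caprigen pedstats --pedigree runs/sim/pedigree.csv --out runs/ped
caprigen fit --pedigree runs/sim/pedigree.csv \
             --phenotypes runs/sim/phenotypes.csv --seed 1 --out runs/fit
caprigen cv  --pedigree runs/sim/pedigree.csv \
             --phenotypes runs/sim/phenotypes.csv --seed 1 --out runs/cv
caprigen risk --phenotypes runs/sim/phenotypes.csv --out runs/risk
```

`docs/methods.md` describes the models, priors (and why threshold models
need proper ones), the group moves, the generator's assumptions, and known
limitations.

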