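# triselect

Bayesian compositional analysis of within-home-range (third-order) habitat
selection for three-habitat landscapes.

Movement ecologists comparing how animals use habitat types across study
sites face two linked problems: habitat use and availability are
*compositions* (proportions summing to 1, points in the "ecological
triangle"), and classic selection ratios `w_h = u_h / a_h` overemphasize
rare habitats.  `triselect` implements the additive alternative — the
**marginality vector**, the displacement on the simplex from an animal's
available to its used composition — together with a Bayesian
multinomial-logit model of habitat use that supports it:

```
n_{s,i}  ~  Multinomial(N_{s,i}, p_{s,i})
log(p_{s,i,h} / p_{s,i,3})  =  f_h(d_{s,i,1}, d_{s,i,2}) + eps_{s,i,h}
eps_{s,i,h}  ~  Normal(0, sigma^2),          h in {1, 2}
```

where animal *i* in site *s* has `N` relocations split into counts `n` over
(shrub, pole stage, coppice-with-standards), `d` is its fixed home-range
availability composition, CWS (h = 3) is the reference habitat, and the
per-individual Gaussian residual `eps` absorbs extra-multinomial variance
from temporally autocorrelated GPS fixes.  The linear predictor
`f_h = a0 + a1 d_shrub + a2 d_pole` comes in a *pooled* form (selection
identical everywhere) and a *site-specific* form (coefficients per site);
the two are compared by conditional DIC with a bootstrap SE over
individuals.  Priors: `a ~ N(0, variance 1000)`, `sigma^2 ~ U(0, 100)`.

From a fitted posterior the package derives predicted use clouds and
marginality vectors for arbitrary availabilities (functional responses),
pairwise-site log-ratio significance maps over a discretized triangle,
posterior-predictive goodness-of-fit checks, Ward-clustering selection of
representative animals, and ternary figures.  A GPS preprocessing chain
(PDOP and seasonal filtering, minimum-convex-polygon home ranges,
availability from categorical 10 m rasters) and a synthetic-data generator
with known ground truth make every stage testable end to end.

## Worked example

```python
import numpy as np
from triselect import (
    preset_scenarios, simulate_dataset, sample_posterior,
    compare_dic, gelman_rubin, predict_use, make_composition,
)

# 3 sites x 20 animals x 900 fixes with genuinely site-dependent selection
scenario = preset_scenarios()["site_contrast"]
records, truth = simulate_dataset(scenario, seed=1)

post_pooled = sample_posterior(records, form="pooled", seed=2)
post_sites  = sample_posterior(records, form="site_specific", seed=3)
print(gelman_rubin(post_sites).max())          # 1.0389... (chains mixed)

comp = compare_dic(post_pooled, post_sites, records, seed=4)
print(f"deltaDIC = {comp.delta_dic:.1f} (SE {comp.se:.1f})")
# deltaDIC = 7.4 (SE 1.8)

cloud = predict_use(post_sites, "CH", make_composition([0.5, 0.3, 0.2]))
print(np.round(cloud.mean(axis=0), 3))         # [0.589 0.165 0.246]
```

`deltaDIC = DIC(pooled) - DIC(site_specific)`; a positive difference several
SE from zero says habitat selection genuinely differs among sites, so the
site-specific model's predictions (the `cloud` of posterior use
compositions — here shrub selected above its 50% availability at site CH)
are the ones to interpret.

The same workflow is available from the shell:

```sh
triselect simulate --preset site_contrast --seed 1 --out-dir runs/sim
triselect report --records runs/sim/use_records.csv --seed 2 --out-dir runs/report
```

which writes use-record tables, posterior draws, PPC tables, log-ratio maps
and a JSON manifest (seeds, R-hats, DIC table) per run.

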