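# gpbench

Genomic prediction — estimating phenotypes or breeding values of genotyped
individuals from genome-wide SNP markers — is the workhorse of modern
livestock and crop breeding.  `gpbench` is a self-contained benchmark
toolkit for comparing **local convolutional neural networks (LCNN)**
against the established predictors of the field on simulated breeding
populations:

* **Linear models** — GBLUP with the VanRaden genomic relationship matrix
  `G = ZZ′ / (2 Σⱼ pⱼ(1−pⱼ))`, extended GBLUP with the pairwise-epistasis
  kernel `G ∘ G`, and BayesA (Gibbs sampling, scaled-t marker prior).
* **Neural networks** — multilayer perceptron (MLP), convolutional network
  (CNN), and the LCNN, whose *local convolutional layer* slides windows of
  `k` adjacent markers along the genome like a convolution but gives every
  window its own weights and intercept.  Adjacent markers on a SNP array
  share no functional relation, so a region-specific filter matches the
  genetics better than a shared one: a shared kernel-10 filter has 11
  parameters, an LCL slightly more than one per SNP, and a 64-node fully
  connected layer 64× more than the LCL.
* **Simulation** — founder haplotypes with tunable local LD, one round of
  random mating with Poisson recombination on the genetic map, and six
  trait architectures (10 / 1,000 additive, epistatic, or linked-epistatic
  QTL with 3×3 interaction tables), heritability scaling, and correlated
  multi-trait sets.

Everything is generated in memory — no external data needed.  Panels can
also be read from PLINK `.raw` text files or VCF.

## Worked example

Simulate a panel, a trait, fit GBLUP and the LCNN on the same 80/20 split,
and score both on the held-out individuals:

```python
import gpbench as gp

panel = gp.simulate_panel(
    gp.PanelConfig(n_individuals=1200, n_markers=3000), seed=1)
arch = gp.sample_architecture(panel, n_qtl=1000, kind="additive",
                              effect_distribution="equal", seed=2)
phen = gp.simulate_trait(panel, arch, seed=3)          # h2 = 0.5
split = gp.make_split(panel.n_individuals, validation_size=150, seed=4)

grm = gp.vanraden_grm(panel)
gblup = gp.GBLUP(phen.trait(0)[split.fitting_ids], grm,
                 train_ids=split.fitting_ids).fit()
print(gblup.summary())

X, y = panel.dosages.astype(float), phen.trait(0)
lcnn = gp.NetworkModel(y[split.train_ids], X[split.train_ids],
                       gp.lcnn_baseline(), y_val=y[split.validation_ids],
                       X_val=X[split.validation_ids]).fit(gp.TrainConfig(seed=5))

for name, pred in [("GBLUP", gblup.predict(split.test_ids)),
                   ("LCNN", lcnn.predict(X[split.test_ids]))]:
    r = gp.predictive_ability(pred, y[split.test_ids])
    print(f"{name}: predictive ability {r:.3f} "
          f"(standardized {gp.standardized_predictive_ability(r, 0.5):.3f})")
```

prints

```
GBLUP mixed-model fit (REML)
========================================
grand mean mu                  980.24139
sigma_g^2                      840.12973
sigma_e^2                      709.89476
lambda (sigma_e^2/sigma_g^2)     0.84498
h2 (REML)                         0.5420
restricted log-likelihood     -3444.4621
n trained / total              960 / 1200
GBLUP: predictive ability 0.504 (standardized 0.713)
LCNN: predictive ability 0.242 (standardized 0.343)
```

REML recovers the simulated heritability (0.54 vs 0.5), and GBLUP sits
essentially at the theoretical ceiling `√h² = 0.707` once standardized.
The LCNN loses at this small fitting size — networks are data-hungry, and
the ordering flips only as training panels grow and for locally
interacting (linked-epistatic) traits, which is exactly the trend the
repeated benchmark reproduces (`gpbench.run_benchmark`, and the trend
tests in `tests/test_acceptance.py`).

## Command line

```bash
gpbench simulate  --config config.yaml --seed 1 --out runs/sim
gpbench fit       --genotypes runs/sim/panel.raw --phenotypes runs/sim/trait_1.csv \
                  --model gblup --out runs/fit
gpbench predict   --genotypes runs/sim/panel.raw --fit-dir runs/fit --out pred.csv
gpbench benchmark --config config.yaml --seed 1 --repeats 10 --out runs/bench
```

Every output directory contains the resolved config (with seed and config
hash) that reproduces the run.

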