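# Methods

This note documents the models, the simulator, the numerical choices and
the limits of what the bundled tests demonstrate.

## The prediction problem

Given `n` individuals genotyped at `p` biallelic SNPs (dosages coded
0/1/2) and phenotypes for a training subset, predict the phenotypes of
held-out individuals.  Performance is *predictive ability*: the Pearson
correlation between predictions and observed phenotypes on the test set.
For a trait with heritability `h²` the expected ceiling is `√h²` (the
genetic value itself correlates `√h²` with the phenotype), so the
*standardized* predictive ability `r/√h²` is comparable across
heritabilities.

## Simulator

**Genotypes.** A panel is bred in two stages.  (1) Founder haplotypes: a
latent Gaussian AR(1) chain per chromosome, `z_j = a·z_{j−1} +
√(1−a²)·ε_j`, thresholded at `Φ⁻¹(f_j)` with per-marker target
frequencies `f_j ~ U(allele_freq_range)`.  This is a first-order Markov
chain whose marginal allele frequencies are exact and whose
adjacent-marker correlation rises monotonically with the persistence
`a = ld_strength`; chromosomes are independent.  (2) One round of random
mating between diploid founders (haplotypes paired in seeded order): each
offspring draws two parents uniformly with replacement and receives one
gamete from each, built as a crossover mosaic with Poisson(chromosome
length in Morgans) crossovers placed uniformly on the genetic map.

Defaults are the study conditions used throughout: 470 founder haplotypes
(235 founder lines), `allele_freq_range = (0.05, 0.95)`, `ld_strength =
0.8`, equidistant maps of 1 Morgan per chromosome.  The desk-scale panel
is 2,000 × 3,000 on 10 chromosomes; a full-scale 10,000 × 34,595
configuration is provided (`maize_config()`) but is optional.  The
simulator reproduces *local* LD and family structure from a finite
founder pool — the features a windowed predictor exploits — but not
coalescent-exact LD, mutation, selection, a realistic site-frequency
spectrum, or multi-generation pedigrees.  Benchmark results on it
therefore support *orderings between methods*, not absolute predictive
abilities of any real panel.

**Traits.**  Additive QTL assign a linear effect per allele copy;
epistatic QTL are marker pairs with a full 3×3 effect table over the nine
dosage combinations.  Linked-epistatic pairs lie at most
`max_link_distance = 5` marker indices apart, interpreted as index
distance on the ordered map within a chromosome (the array is ordered and
the constraint is stated in SNP counts).  Pairs are sampled disjointly.
Effect sizes are `equal` (all 1), `gaussian` (standard normal per entry),
or `gamma` (shape 0.4, scale 1, random sign — a heavy-tailed option; the
shape is our choice, and the absolute scale is irrelevant because of the
heritability rescaling below).

**Heritability.**  Residuals are i.i.d. `N(0, σe²)` with
`σe² = Var(g)·(1−h²)/h²`, where `Var(g)` is the realized population
variance of the genetic values in the panel (not a theoretical
expectation), so the realized `h²` is tight around the target; `h² = 1`
gives zero residuals exactly.

**Correlated traits.**  All traits share one set of 1,000 additive QTL.
Per-trait effect vectors are linear mixtures of i.i.d. standard-normal
vectors; the mixture composes the Cholesky factor of the equicorrelation
target with an empirical whitening step (the raw genetic values are
decorrelated on the realized panel before the target is imposed).  A
plain Cholesky mixture in effect space yields the target correlation only
in expectation, and under LD plus founder kinship the effective number of
independent QTL is far below 1,000, inflating the spread of realized
correlations well beyond i.i.d. sampling error; whitening makes the
*sample* genetic correlation equal the target exactly, which is what a
trait-shuffling simulator aims for.

## Linear models

**GBLUP.**  `y = 1μ + g + e`, `g ~ N(0, σg²G)` with the VanRaden GRM
computed from allele frequencies of the *full* panel (train and test
together — the single-G convention; stated explicitly because it affects
predictions).  REML maximizes the restricted likelihood over
`δ = σe²/σg²` by bounded search on `log₁₀δ ∈ [−10, 10]` after a single
eigendecomposition of `G_train` (the spectral approach of rrBLUP's
`mixed.solve`; `n` is small at desk scale).  Predictions for unphenotyped
individuals use the genomic cross-covariance block,
`ĝ = G[:, train](G_train + δI)⁻¹(y − μ̂)`, which is mathematically
equivalent to masking test phenotypes inside one mixed model.  `fit()`
optionally accepts a fixed `δ`; the RR-BLUP equivalence (identical
predictions to marker-ridge with per-marker variance `σg²/c`) is exact at
any ratio and is exercised as an oracle test at interior ratios, where
the p×p ridge system is well conditioned.  Note that on pure-noise
phenotypes with `n < p` REML does *not* drive `σg² → 0` — a full-rank
genomic term can absorb noise — so the full-shrinkage limit is a
statement about `δ → ∞`, not about the REML optimum.

**EGBLUP.**  Adds `g₂ ~ N(0, σ₂²H)` with `H = G ∘ G` (Hadamard square),
the standard pairwise-epistasis kernel.  The two ratios
`λᵢ = σᵢ²/σe²` are profiled on a log-spaced grid (`10⁻⁴ … 10²`) and
refined by Nelder-Mead; each evaluation is one Cholesky factorization of
the train block.  Pinning `λ₂ = 0` reproduces GBLUP exactly (nesting).

**BayesA.**  Gibbs sampler with the standard full conditionals (normal
for μ and each effect, scaled-inverse-χ² for the per-marker and residual
variances).  Hyperparameters follow the BGLR-style rule: marker prior
`ν = 4` with scale `S` set so the prior marker variance explains `R² =
0.5` of the phenotypic variance given `Σ 2pⱼ(1−pⱼ)`; residual prior
`ν_e = 4` with mode at `(1−R²)·Var(y)`.  Defaults are 5,000 iterations
with 1,000 burn-in; the benchmark harness uses 1,500/300, which is
sufficient for posterior-mean prediction at desk scale.  Chains are
deterministic given a seed; a non-finite state aborts with the iteration
index.

## Networks

Three classes share ReLU hidden activations, a linear output per trait,
dropout 0.3 after each hidden layer (inverted dropout, never on the input
— dropping raw SNPs would destroy locality), minibatch Adam (batch 64,
learning rate 1e−3 — framework-default values; hyperparameter changes
have minor effects here) on the MSE, and seeded Glorot-uniform
initialization:

* **MLP** — fully connected layers only (baseline: two hidden layers of
  64 nodes).
* **CNN** — one shared-filter convolution in front of the FCLs (baseline:
  kernel 10, stride 10, 1 filter — one filter is the only count
  consistent with the 11-parameter arithmetic of a kernel-10 filter), no
  pooling.
* **LCNN** — same windowing, but window `w` owns its weights and
  intercept: `out[b,w] = ReLU(Σᵢ W[w,i]·x[b, s·w+i] + b_w)`.  Trailing
  markers beyond the last full window are dropped ("valid" rule), which
  keeps the per-window arithmetic exact and avoids padding artifacts.
  A conv layer is the weight-tied special case of the local layer, and
  the parameter count is `n_windows·(k+1)` — slightly more than one
  parameter per SNP at `k = s`.

Baseline parameter counts at `p = 34,595`: MLP 2,218,369 (≈2.2 million),
LCNN 263,714, CNN 225,676 — the count ordering MLP > LCNN > CNN is the
robust statement.

**Training protocol.**  Phenotypes are centered per trait on the training
set (the offset is restored at prediction); genotypes enter as raw 0/1/2.
Two modes: *early-stop* trains up to 50 epochs, evaluates validation
predictive ability (Pearson r, averaged over traits) after each epoch and
restores the weights of the best epoch (earliest on ties); *fixed* runs
exactly 25 epochs and ignores validation data entirely.  Multi-trait
heads use the unweighted sum of per-trait MSEs.

## Evaluation protocol

80% of the panel is the fitting set; ANNs split it further into training
and validation (epoch selection only), linear models use all of it.  On
10,000 individuals with 1,000 validation samples this is the
7,000/1,000/2,000 split.  The training-size sweep pairs fitting sizes
(100, 250, 500, 1,000, 2,000, 3,000, 4,000, 6,000, 8,000) with validation
sizes (20, 50, 100, 200, 300, 400, 500, 750, 1,000); all remaining
individuals are the test set.  `run_benchmark` repeats the whole
procedure with fresh random splits (repeat `r` splits with seed
`master + r`; model `m`, numbered from 1, uses seed
`master + 10000·m + r`), fits every model on identical splits, and
reports per-cell means with a normal-theory 95% CI
(`mean ± 1.96·SE`) across repeats.  Undefined correlations
(zero-variance predictions) are recorded as missing, never as 0, and a
single model failure is recorded per cell without aborting the sweep.
No code path receives test phenotypes before scoring.

## Problem sizes used by the bundled checks

The test suite runs the trend checks at desk scale, chosen once as the
package's own study conditions: panels of 2,600 × 3,000 (fitting sizes
100–2,000), 10 repeats per ordering; heritability-monotonicity at fitting
size 1,000 over h² ∈ {0.1, 0.5, 1.0}; REML recovery at n = 2,000,
p = 3,000 over 10 trait draws; calibration checks at n = 10,000 (realized
h²) and n = 5,000 (genetic correlations).  `scripts/acceptance.py`
recomputes the parameter accounting at the full p = 34,595 and the
simulator calibrations on a fresh 5,000 × 3,000 panel.

## Known limitations

* Founder LD is a parametric stand-in; absolute predictive abilities are
  not comparable to any real landrace panel, only method orderings are.
* Single generation, no selection, no fixed effects, no missing
  phenotypes, no dominance-only traits, no G×E.
* EGBLUP's 2-D REML grid search is exact enough at desk scale but cubic
  in the training size; no approximations for large n are provided.
* The networks are plain NumPy: correct and adequate at desk scale, with
  no GPU path or performance engineering for p ≫ 10⁵.
* Heritability and reliability estimation exist only on the linear-model
  side; network results objects report diagnostics (per-epoch loss,
  validation r, selected epoch) instead.
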