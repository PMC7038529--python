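# Methods

`gpbench` simulates complex quantitative traits on SNP genotypes and
benchmarks six genomic-prediction machines — two parametric
whole-genome regressions (GBLUP, Bayes B), two tree ensembles (random
forests, gradient boosting), and two neural networks (a multilayer
perceptron and a one-dimensional CNN) — under replicated k-fold
cross-validation. This note records the models, the defaults and why,
the numerical choices, and what the synthetic data can and cannot show.

## Genotype simulation

Real dense bovine SNP-chip panels are access-restricted, so the package
generates a stand-in: `n` individuals × `m` biallelic SNPs split evenly
over `n_chromosomes`, coded 0/1/2 as counts of an arbitrary reference
allele. Each SNP's minor-allele frequency is uniform on `maf_range`
(default 0.05–0.5) with random allele orientation. Haplotypes follow a
first-order Markov copula inside LD blocks of `block_length` SNPs
(default 20): a latent uniform is carried from the previous SNP with
probability `within_block_corr` (default 0.7) or redrawn, and the
allele is the indicator `u < p`. This preserves exact marginal allele
frequencies — so genotypes (two independent haplotypes) are in
Hardy–Weinberg proportions — while adjacent-SNP correlation rises with
the block parameter. Missing calls (default rate 0.01) are injected
uniformly at random.

What the generator does **not** emulate: realistic recombination maps
and long-range LD decay, population structure and relatedness (there are
no families — every individual is an unrelated draw), allele-frequency
spectra shaped by ascertainment, and genotyping error. Benchmarks run on
this panel therefore probe each method's response to architecture
(additive vs. non-additive, few vs. many causal loci), not its behaviour
under pedigree structure or real LD — expect absolute correlations here
to exceed what marker-based prediction achieves on real livestock data.

## Quality control

SNPs are dropped if they map to an excluded chromosome (default `{X}`),
have MAF < 0.05, missing rate > 0.05, or an exact Hardy–Weinberg test
p-value < 1e-6. The HWE test enumerates the Levene–Haldane distribution
of heterozygote counts given the allele counts and sums all tables no
more probable than the observed one (plain exact test, no mid-p). A
chi-square approximation was deliberately avoided: standard QC tooling
uses the exact test, and the exact version is well-behaved at the rare
genotypic classes the filter targets. Rules are applied jointly, so rule
order never changes the surviving set. Residual missing calls after QC
are imputed to the SNP's rounded mean code — downstream fitters need
complete matrices, and with ≤5% missingness the choice is immaterial;
the pre-imputation mask is retained.

## Trait simulation

Causal loci (QTN) are placed either uniformly at random or clustered:
one third of the QTN are randomly sampled cores, each contributing the
triplet {core−1, core, core+1} in map order; clusters never overlap or
straddle chromosomes, and when `n_qtn` is not divisible by three the
set is topped up with random singletons to the exact count.

Effects per QTN `k` with reference-allele frequency `p_k`:

- additive `a_k ~ N(0, 1)`;
- dominance `d_k ~ N(0, sd 0.5)` (zero for purely additive traits);
- allele-substitution effect `alpha_k = a_k + d_k (q_k − p_k)`;
- each QTN interacts with its three downstream neighbours in genome
  order (3·n_qtn − 6 pairs: 294 at 100 QTN, 2994 at 1000), and each
  pair carries four epistatic effects (A×A, A×D, D×A, D×D) with
  magnitude ~ Gamma(shape 0.1, scale 10) and an independent ± sign.

Interaction covariates are Hadamard products of the additive (0/1/2)
and dominance (0/1/0) codings, so A×A ∈ {0,1,2,4}, A×D and D×A ∈
{0,1,2}, D×D ∈ {0,1}. The dominance draws are used as sampled, with no
|d| > |a| constraint: with sd(d) = 0.5 against sd(a) = 1, many loci are
effectively overdominant, and imposing a hard constraint would distort
the stated distribution.

**Variance calibration.** The generating distributions fix the shape of
each genetic component but not its share of phenotypic variance, so
each component is centred and rescaled by a constant to make its
empirical variance equal its target fraction of a unit phenotypic
variance (targets: additive 0.30/0/0; non-additive 100 QTN
0.10/0.10/0.50; non-additive 1000 QTN 0.02/0.02/0.68); residuals are
i.i.d. N(0, 1 − H²_B). Components are *not* orthogonalized: the
realized partition reports raw ratios Var(component)/Var(phenotype),
and realized covariances between components (the additive, dominance
and epistatic covariates share loci) make single-replicate ratios
wander a few percent around the targets; across seeds they average to
the targets, which is how the calibration checks are run. The raw
unscaled draws remain available through the effect tables.

Randomness is split into six sub-streams (placement, additive,
dominance, epistatic signs, epistatic magnitudes, residuals) derived
from one architecture seed, so e.g. switching placement mode never
perturbs the effect draws.

## Parametric predictors

**GBLUP.** `y = 1μ + g + e`, `g ~ N(0, G σ²_g)`, with the genomic
relationship matrix `G = ZZ′/m` from centred standardized genotypes
`z = (x − 2p)/√(2pq)`. Two modes:

- `closed_form` (default): with the variance ratio
  `λ = σ²_e/σ²_g` fixed from a supplied heritability (the simulation's
  broad-sense target, since the trait generator knows it), μ is the GLS
  mean and `ĝ = G_tt (G_tt + λI)⁻¹ (y − 1μ̂)`; held-out individuals get
  `ĝ_test = G_test,train (G_tt + λI)⁻¹ (y − 1μ̂)`. This is exactly
  ridge regression on standardized markers with penalty `mλ`, which the
  tests exploit as an independent oracle.
- `gibbs`: sampler in the eigenbasis of G (where the conditional of the
  genetic values is diagonal), scaled-inverse-χ² priors (ν = 5, scales
  from the phenotypic variance split), full-scale chain 100 000
  iterations / 10 000 burn-in / thin 10, desk-scale default 6 000 /
  1 000 / 5. Prediction uses the closed form at the posterior-mean
  variance ratio.

A ridge of 1e-8 is added to G's diagonal before factorization (G is
PSD only up to rounding).

**Bayes B.** Marker-effect regression `y = μ + Xb + e` where each
effect is null with prior probability π (default 0.95, fixed) or, with
probability 1 − π, normal with marker-specific variance
`σ²_bj ~ scaled-inv-χ²(ν, s²)` (marginally a t prior; ν = 5). The prior
scale `s²` defaults to the value that makes the implied genetic
variance half the phenotypic variance given π, ν and the summed marker
variances. Inference is single-site Gibbs (numba-compiled kernel):
per marker, `σ²_bj` is refreshed (posterior draw if currently included,
prior draw otherwise), the inclusion indicator is sampled exactly from
the marginal likelihood ratio with b_j integrated out — no
Metropolis step — and the effect is drawn from its normal full
conditional; μ and σ²_e have standard conjugate updates. These
hyperpriors are declared stand-ins for an unpublished reference
configuration; sensitivity to π is exposed in the config. A run is
flagged as divergent if σ²_e exceeds 10× the phenotypic variance.

## Machine-learning predictors

- **Random forest** (scikit-learn): `ntree = 500`, `mtry = min(2000,
  m)` features per split, minimum node size 5 — the tuned values of the
  benchmarked protocol, with the `min` guard so small panels remain
  valid. OOB MSE is reported from out-of-bag predictions.
- **Gradient boosting** (xgboost): depth-3 trees, learning rate 0.10,
  80% subsampling per iteration; a fixed 20% holdout of the training
  fold drives early stopping after 50 non-improving rounds (a fixed
  holdout rather than per-iteration out-of-bag evaluation, for
  reproducibility), best iteration retained.
- **MLP** (numpy): hidden layers (64, 32) with ReLU then softplus
  ("softReLU" = log(1 + eˣ)), dropout (0.1, 0.1), linear output;
  minimizes mean squared error with l2 penalties on all weights and
  biases via mini-batch SGD (batch 32, learning rate 0.01, momentum
  0.5, weight decay 1e-5), 200 epochs full scale.
- **CNN** (numpy): 16 length-5 filters at stride 3 over the SNP axis
  with ReLU, max-pool 2/2, dropout 0.3, a 32-unit softplus dense layer
  with dropout 0.3, a single softplus unit, and a linear output; SGD
  with batch 64 and the MLP's optimizer settings. The two dropout
  layers sit after the pool and after the 32-unit dense layer. The
  scalar softplus bottleneck makes optimization slow and seed-sensitive
  under plain SGD; the output-side weights are initialized in the
  unit's responsive region (bias 0.5, unit output weight) to avoid a
  dead start, but at small sample sizes the CNN remains the weakest and
  most variable method — consistent with its reference behaviour.

Networks standardize inputs per column and the response internally
(predictions are returned on the original scale); trees see raw 0/1/2
codes, which are scale-invariant. All four methods run single-threaded
with seeded generators, so identical configs reproduce identical fits.
Per-epoch training MSE is accumulated from the minibatch losses
(pre-update, with dropout active, as training frameworks report it);
validation MSE comes from a full pass over a held-out 10% split.

`tune_hyperparameters` evaluates an explicit grid exhaustively by OOB
error (forests) or five-fold CV MSE; the full-scale search grids are
shipped as presets, and defaults are the tuned configurations above.

## Evaluation

`make_cv_folds` builds random k-fold partitions (fold sizes within 1)
per replicate; every method in a run sees identical train/test splits,
asserted by a per-split hash. Predictor sets: `causal` (exactly the QTN
columns — the idealized setting where causal loci are known) or
`markers` (all SNPs with QTN columns removed — the realistic marker
panel). Held-out predictions are scored by Pearson correlation and MSE
against the total genetic value (additive + dominance + epistatic) for
simulated traits, or against observed phenotypes otherwise; total
rather than additive-only genetic value is the default target because
the non-additive scenarios are designed to reward methods that capture
interaction variance (a switch selects the phenotype target). A method
failure or a constant prediction vector yields a flagged record, not an
aborted run; in trend summaries a constant predictor counts as zero
predictive ability. Summaries report replicate-level means with 95%
t-intervals over replicate means (folds within a replicate are
dependent, so fold-level records are averaged first).

## Desk-scale protocol and problem sizes

Full-scale settings (n ≈ 12k–80k individuals, m ≈ 58k SNPs, 100k-draw
chains) are supported in configuration but the shipped protocol runs at
desk scale, the package's reference study size: n = 2000, m = 5000,
MCMC chains 6000/1000/5, neural-network training 100 epochs in the
benchmark runs, five replicates of five-fold CV, causal-locus
predictors. At this scale the qualitative findings replicate as trends:
purely additive traits favour GBLUP/Bayes B over all four ML methods;
under mixed additive + dominance + epistatic action gradient boosting
is top or tied-top; and random forests lose accuracy as the causal
count grows from 100 to 1000. The RF benchmark fixes `mtry = 100` in
both QTN arms so the two runs share one configuration. Absolute
correlations at desk scale are not comparable to full-scale values —
only orderings are asserted.

## Known limitations

- The LD model is block-local; methods that exploit long-range LD are
  not differentiated from those that cannot.
- Bayes B's π is fixed (no hyper-prior update), and closed-form GBLUP
  takes its variance ratio from the known simulation heritability
  rather than REML; both choices favour transparency and exact oracle
  testing over adaptivity.
- The CNN is faithful to its reference architecture but that
  architecture is fragile under plain SGD at small n; conclusions about
  "deep learning" from desk-scale runs are conclusions about this
  specific small network.
- `hwe_test` enumerates all compatible heterozygote counts; it is exact
  but O(allele count) per SNP, intended for panels up to a few tens of
  thousands of markers per call, not biobank scale.
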