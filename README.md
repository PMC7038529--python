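# gpbench

Simulation and benchmarking of genomic-prediction methods for complex
traits. The package is for quantitative geneticists and breeders who
want to know *which prediction machine to trust for which genetic
architecture*: it simulates phenotypes on SNP genotypes with additive,
dominance and two-locus epistatic gene action, then compares two
parametric whole-genome regressions — GBLUP and Bayes B — against four
machine-learning regressors — random forests, gradient boosting, a
multilayer perceptron and a 1-D convolutional network — under
replicated five-fold cross-validation, scoring held-out predictive
correlation and mean squared error.

## Models in brief

**GBLUP** fits y = 1μ + g + e with g ~ N(0, G σ²g), where
G = ZZ′/m is the genomic relationship matrix from standardized
genotypes z = (x − 2p)/√(2pq); prediction for unphenotyped individuals
uses the train/test blocks of G. **Bayes B** regresses y = μ + Xb + e
with a two-component mixture prior: each marker effect is null with
probability π or drawn from a t-type prior (ν, s²), sampled by
single-site Gibbs. The trait simulator places QTN (random or clustered
triplets), draws a ~ N(0,1), d ~ N(0, 0.5 sd), allele-substitution
effects α = a + d(q − p), and epistatic effects with
Gamma(0.1, 10)-distributed magnitudes over the four Hadamard-product
codings A×A, A×D, D×A, D×D; each component is calibrated to a target
share of unit phenotypic variance (e.g. h²a = 0.30 purely additive, or
0.10/0.10/0.50 with broad-sense H²B = 0.70). Details, defaults and
numerical choices are in [docs/methods.md](docs/methods.md).

## Worked example

```python
import gpbench as gp

# 2000 individuals x 5000 SNPs in LD blocks, then QC
g = gp.simulate_genotypes(gp.GenotypeSimConfig(seed=11))
g, report = gp.apply_qc(g)

# non-additive trait: 100 clustered QTN, variance split 0.1/0.1/0.5
arch = gp.ArchitectureConfig(gene_action="nonadditive", n_qtn=100,
                             target_h2_a=0.10, target_h2_d=0.10,
                             target_h2_I=0.50, seed=22)
trait = gp.simulate_trait(g, arch)
print(trait.realized_partition)

# five-fold CV, causal-locus predictors, all six methods
plan = gp.make_cv_folds(g.n, k=5, replicates=1, seed=31)
cfgs = {"gblup": gp.GBLUPConfig(h2=arch.broad_h2),
        "mlp": gp.MLPConfig(epochs=100), "cnn": gp.CNNConfig(epochs=100),
        "rf": gp.RFConfig(mtry=100)}
table = gp.run_benchmark(g, trait, ["gblup", "bayesb", "rf", "gb", "mlp", "cnn"],
                         plan, mode="causal", configs=cfgs)
print(table.records.groupby("method")["r"].mean().sort_values(ascending=False))
```

Output from this exact script:

```
{'h2_a': 0.0949, 'h2_d': 0.0949, 'h2_I': 0.4743, 'H2_B': 0.664}
method
gb        0.872
gblup     0.790
bayesb    0.734
mlp       0.722
rf        0.720
cnn       0.565
```

The realized variance partition sits within a few percent of the
0.10/0.10/0.50 targets (components share loci, so realized covariances
shift single-replicate ratios slightly). Under non-additive gene action
gradient boosting leads, the parametric methods remain competitive, and
the small CNN — faithful to its reference architecture but fragile
under plain SGD — trails the field. Under a purely additive
architecture the ordering flips: GBLUP and Bayes B lead all four
machine-learning methods.

There is also a CLI (`gpbench run --config cfg.yaml --seed 7 --out dir`)
with subcommands `simulate-genotypes`, `qc`, `simulate-trait`,
`benchmark` and `summarize`; every run writes truth files, tidy metric
tables, a summary with 95% confidence intervals, and a manifest with
content hashes (re-running a config reproduces outputs bit-identically).

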