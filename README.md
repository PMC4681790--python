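# mbpower

Spike-in power benchmarking of multivariate differential-abundance tests
for microbiome (and other feature-count) profiles.

## The problem

A typical two-group microbiome comparison asks a single question first:
*do these two sets of samples differ in composition at all?*  The data
make that hard — tens of thousands of features (OTUs, genes, functional
categories) measured on a few dozen samples, with heavily right-skewed
abundances, widespread sparsity, and blocks of mutually correlated
features.  Many multivariate statistics have been proposed, and their
power differs wildly depending on *which* features change and by how
much.

`mbpower` is a benchmarking framework for exactly that question.  It
provides:

* a **synthetic community generator** that reproduces the skew,
  sparsity and correlation structure of real surface-microbiome OTU
  tables (log-normal abundance body with a Pareto upper tail, monotone
  presence curves, latent-factor correlation blocks);
* **spike-in disease models**: select a feature set by abundance
  category — `rare`, `medium`, `common`, or `correlated` with a
  reference feature — until its cumulative baseline share of total
  abundance reaches a target (1% or 10%), then multiply those features
  by a fold *k* in the case samples;
* **six families of global test statistics** `T(X, labels)`, larger
  meaning more evidence of a group difference:
  * modified Metastats: per-feature Welch *t*-tests (Fisher's exact
    test for sparse counts) pooled by a Benjamini–Hochberg step-up;
    the statistic is the number of rejected features;
  * penalized logistic regression (lasso / ridge / elastic net), λ by
    ten-fold cross-validated deviance; statistic
    `P(χ²_df ≤ D₀ − D_λ)` with df = number of nonzero coefficients
    (ridge: `D₀ − D_λ` itself);
  * distance-based multivariate regression (MDMR): PERMANOVA pseudo-F
    `[tr(HGH)/(m−1)] / [tr((I−H)G(I−H))/(n−m)]` on a Gower-centered
    Minkowski distance matrix (p ∈ {0.25, 0.5, 1, 2, 4});
  * principal component regression: cross-validated
    `R² = 1 − PRESS/TSS` of the 0/1 indicator on top-k PC scores
    (k ∈ {5, 10, 50, all});
  * partial least squares regression: the same CV-R² with
    covariance-maximizing (NIPALS) components;
  * Hill-number diversity profiles
    `^qD = (Σ p_i^q)^(1/(1−q))`: the statistic is `max_q |t_q|` over a
    family of orders q;
* **empirical null calibration**: split the unspiked table's samples at
  random into two halves N times, collect the statistic, and set the
  rejection threshold so that a fraction α (default 5%) of the null
  statistics lies at or above it;
* **power estimation**: the fraction of random case/control replicates
  in which the spiked statistic crosses the calibrated threshold, with
  standard errors over repeated assessments.

## Worked example

```python
from mbpower import run_benchmark

config = {
    "seed": 7,
    "community": {"n_features": 200, "n_samples": 88,
                  "correlation_blocks": [[30, 0.8]], "sparsity_curve": None,
                  "depth_dispersion": 0.8, "seed": 7},
    "group_size": 44,
    "calibration": {"n_resamples": 200, "alpha": 0.05},
    "power": {"n_replicates": 50, "n_repeats": 3},
    "techniques": [{"technique": "mdmr", "minkowski_p": 1},
                   {"technique": "plsr", "n_components": 5}],
    "disease_models": [{"category": "common", "target_fraction": 0.10,
                        "folds": [1, 2, 3]}],
}
results = run_benchmark(config)
agg = results[results["repeat"] == "mean"]
print(agg[["technique_id", "model", "fold", "power", "se"]].to_string(index=False))
```

prints

```
technique_id      model  fold    power       se
     mdmr_p1 common_0.1   1.0 0.046667 0.017638
     plsr_k5 common_0.1   1.0 0.033333 0.006667
     mdmr_p1 common_0.1   2.0 1.000000 0.000000
     plsr_k5 common_0.1   2.0 1.000000 0.000000
     mdmr_p1 common_0.1   3.0 1.000000 0.000000
     plsr_k5 common_0.1   3.0 1.000000 0.000000
```

Read: at fold 1 no spike is applied, so both techniques reject at about
the calibrated 5% level (the type I error); doubling the abundance of a
`common` feature set holding 10% of the community is already detected
essentially always at these settings.  `se` is the standard error of
the power over the three repeated assessments.

The same pipeline is available from a shell:

```bash
mbpower simulate  --config config.yaml --out table.tsv
mbpower calibrate --config config.yaml --out-dir nulls/
mbpower power     --config config.yaml --out results.tsv
mbpower report    --results results.tsv --best-per-family --out report.tsv
```

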