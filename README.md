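# survsel

Variable selection for high-dimensional, highly collinear right-censored
survival data. The package implements and benchmarks:

- **Penalized Cox models** — lasso, elastic net, ridge, and two-stage
  adaptive lasso (ridge-initialized weights `w_j = 1/|beta_j|`), fitted by
  a Numba coordinate-descent solver with active-set Newton acceleration,
  tuned by 10-fold cross-validation of the Verweij–van Houwelingen
  partial-likelihood deviance.
- **Spike-and-slab Cox models** fitted to the posterior mode by EM —
  SSVS (Gaussian mixture `(1-g) N(0,tau^2) + g N(0,(c*tau)^2)` with
  `c = 1/tau`), spike-and-slab lasso (double-exponential mixture with
  fixed slab scale `s1` and CV-tuned spike scale `s0`), and the
  group-structured variant with group-shared inclusion probabilities
  `p_k ~ beta(a,b)`.
- **Random survival forest** (scikit-survival, log-rank splitting) with
  minimal-depth variable selection via maximal subtrees and an
  out-of-bag concordance error.
- **Posterior thresholding rules** — the CI rule (normal interval
  excludes 0), BIC thresholding on the descending-|beta| prefix order
  (`BIC_j = -2(l(beta_(1:j)) - l(0)) + j log n`, top-50 prefilter), and a
  greedy-forward modified BIC rule.
- **A survival-data simulator** — blocks of AR(rho)-correlated standard
  normal covariates, sparse negative effects drawn from a LOW
  `[-0.4, -0.1]` or HIGH `[-1.0, -0.5]` range, exponential event times
  with a 4-year baseline median, and exponential censoring calibrated by
  Monte-Carlo bisection to a target (50%) censoring rate. Four built-in
  designs (`survsel.DESIGNS`): n=450, p=200, rho=0.9, blocks of 50,
  q ∈ {5,10} × {LOW, HIGH}.
- **A benchmark harness** scoring every method × selection rule over
  seeded replicates with TPR/TNR/FPR (denominators q and p−q, so
  TNR + FPR = 1; the divide-by-p variant is available behind a flag).

## CLI

```sh
# simulate one replicate of a built-in design (writes CSV + truth sidecar)
survsel simulate --design 1 --seed 7 --out data.csv

# fit a model (10-fold CV where applicable)
survsel fit --method lasso    --data data.csv --seed 1 --out fit.json
survsel fit --method gsslasso --data data.csv --groups groups.csv --s1 1.0 \
    --seed 1 --out fit.json

# apply a selection rule to a stored fit
survsel select --rule ci --alpha 0.05 --fit fit.json --data data.csv --out sel.json
survsel select --rule mbic --jmax 50  --fit fit.json --data data.csv --out sel.json

# run a benchmark from a config file
survsel benchmark --config bench.yaml --out results/
```

`bench.yaml` keys: `designs` (ids 1–4), `methods`
(`lasso|elastic_net|adaptive_lasso|ridge|rsf|ssvs|sslasso|gsslasso`),
`rules` (per-method lists), `reps`, `seed_base`, `method_kwargs`,
`folds`, `j_max`. Outputs: `replicates.csv` (long format),
`summary_wide.csv` (designs × method/rule/metric), `summary.csv`,
`manifest.json`.

Dataset CSVs have columns `time,event,x1..xp` (event ∈ {0,1}; missing
values as empty cells or `NA`). Analysis is complete-case only
(`survsel.cli_io.complete_case_filter`); no imputation is performed.

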