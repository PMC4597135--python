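# selfprior

Bayesian observer modelling of how people perceive the outcome of their own
goal-directed actions. The package simulates a visuomotor "stop the ball"
task, applies trial- and subject-level exclusion rules, fits per-subject
Gaussian observer models by maximum likelihood, compares a 2-parameter
(no-shift) and a 3-parameter (evidence-shift) model by BIC, derives
normalized prior widths and prior accuracy, and runs the group-level
statistical battery (t-tests, exact sign test, ANCOVA with Type-III sums of
squares, Spearman and partial Spearman correlations, Bonferroni correction).

## Model

In target-centred pixel coordinates, a trial's performance error is
`p = stop_x - target_x` and its estimation error is `e = point_x - stop_x`.
The observer combines a goal-centred prior `Normal(0, sigma_prior^2)` with
shifted sensory evidence `Normal(p + shift, sigma_evidence^2)` by
reliability weighting `w = sigma_e^2 / (sigma_p^2 + sigma_e^2)`, so

    e | p  ~  Normal(-w * p + (1 - w) * shift,  ((1 - w) * sigma_e)^2)

The regression slope of estimation on performance errors equals `-w`, which
gives a closed-form MLE through the OLS parameterisation; the numerical
optimiser is verified against it. The normalized prior
`sigma_prior / (sigma_prior + perf_sd)` is 0.5 when the prior matches the
true performance spread; prior accuracy is its absolute deviation from 0.5.

## CLI

```bash
selfprior simulate --seed 1 --out trials.csv            # demo cohort (2x52 trials, 20+20 subjects)
selfprior preprocess trials.csv --out clean.csv --report excl.json
selfprior fit clean.csv --out fits.json
selfprior metrics clean.csv --fits fits.json --out measures.csv
selfprior analyze measures.csv --covariates lde,mean_est_time --out stats.json
selfprior run --seed 1 --out results/                   # end to end
selfprior report --trials trials.csv
```

`simulate --config cohort.json` accepts a JSON cohort spec (see
`selfprior.synthetic.CohortSpec`); the default demo cohort links patients'
daily dose (LDE) monotonically to their prior width so the end-to-end
dose-prior correlation is recoverable by construction. Every output embeds
the config hash and seed; reruns with the same seed are byte-identical.

## Layout

- `src/selfprior/synthetic.py` — task simulator and cohort specs
- `src/selfprior/preprocess.py` — exclusion rules, error computation
- `src/selfprior/bayes.py` — likelihood, closed-form + numerical MLE, BIC
- `src/selfprior/metrics.py` — per-subject regression and prior metrics
- `src/selfprior/stats.py` — inferential tests and table summaries
- `src/selfprior/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, CSV/JSON I/O
- `src/selfprior/data/table1.csv` — packaged patient demographics fixture
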