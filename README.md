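# panelmsm

Marginal structural models for a time-varying binary exposure and a
repeatedly measured continuous outcome in longitudinal panel data.

The package implements, end to end:

- **synthetic cohorts** with exposure–confounder feedback, a person-level
  frailty linking attrition to the outcome trajectory, informative
  loss to follow-up, and death as a competing terminal event — with the
  true always- vs never-exposed slope difference known by construction
  (`panelmsm.simulate`);
- **panel preparation**: two-item exposure coding, eligibility filters,
  household-size equivalization with log transforms, last observation
  carried forward, and censoring indicators that never treat death as
  censoring (`panelmsm.prep`);
- **stabilized inverse-probability weighting**: per-wave logistic
  propensity and censoring models, stabilized IPTW/IPCW, cumulative
  products, percentile truncation (cap or exclude), and positivity/
  balance diagnostics (`panelmsm.weights`, `panelmsm.engine`);
- **the weighted growth model** with exposure, time and exposure × time
  terms (working-independence WLS and a weighted mixed-effects estimator),
  the excess-years-of-aging-per-decade statistic, and regime trajectory
  prediction (`panelmsm.growth`);
- **person-level bootstrap** confidence intervals with weight
  re-estimation inside each replicate (`panelmsm.bootstrap`);
- **sensitivity scenarios**: recode-missing-exposure (secure/insecure),
  complete case, time-invariant health covariates in the treatment
  weights, and an alternative childhood-SES covariate
  (`panelmsm.sensitivity`);
- a **CLI** tying the stages into one reproducible, config-driven run
  (`panelmsm.cli`).

## Run the tests

```bash
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which re-runs the
statistical acceptance criteria (parameter recovery across 50 synthetic
cohorts, weight behaviour, balance restoration, bootstrap coverage at
150 × 150 scale, oracle equivalences, determinism). Expect roughly
20 minutes on one CPU.

## CLI

```bash
# full demo pipeline on a simulated cohort
panelmsm all --seed 1 --out out/demo --boot 200

# individual stages (each reads/writes tidy CSV)
panelmsm simulate --seed 1 --out out/s1
panelmsm prep --config config.yaml --out out/s1
panelmsm weights --config config.yaml --out out/s1 --truncation-mode cap
panelmsm fit --config config.yaml --out out/s1 --boot 1000
panelmsm sensitivity --config config.yaml --out out/s1
panelmsm report --config config.yaml --out out/s1
```

A YAML config can override any section of the defaults (see
`panelmsm.cli.DEFAULT_CONFIG`): simulation parameters, prep rules, weight
truncation, the growth-model estimator, bootstrap settings and the list of
sensitivity scenarios. The resolved config is serialized into the output
directory; identical config + seed reproduces the bundle bit for bit.

## Data model

The interchange format is a tidy CSV, one row per person-wave, with a JSON
column dictionary sidecar (`panelmsm.schema`). Status is one of
`active`/`lost`/`dead` and is absorbing; rows exist up to and including
the first terminal wave; measurements are never present after death.
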