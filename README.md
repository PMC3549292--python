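# diastress

An agent-based diathesis-stress simulator of depressive symptom dynamics,
with threshold-based diagnostic classification and the standard
epidemiologic analyses of the resulting episode data.

Each simulated agent carries a continuous vulnerability (*diathesis*, drawn
lognormally) and experiences an independent lognormal stress level every
day. Daily stress activation (stress × diathesis) adds to an internal
stress burden while adaptation removes a diathesis-dependent fraction of
the previous day's burden:

```
burden[t] = burden[t-1] + stress[t]·d − burden[t-1] / (1 + c·d)
```

Symptom levels are the trailing 14-day mean of the burden. A diagnostic
threshold plus a remission-stringency cut (hysteresis) dichotomizes the
continuous symptom trace into episodes. Classic epidemiologic signatures —
declining incidence over time, recurrence risk rising with episode history,
elevated baseline symptoms predicting onset, and decelerating recovery —
all emerge from this stationary underlying process once the threshold is
applied.

## Package layout

| module | role |
| --- | --- |
| `diastress.stress_environment` | i.i.d. lognormal daily stress draws, per-agent seeded substreams |
| `diastress.agent_dynamics` | burden recursion and 14-day symptom moving average (scalar + vectorized) |
| `diastress.episode_classifier` | threshold/hysteresis state machine, episode segmentation, baseline state |
| `diastress.cohort_simulator` | cohort simulation, per-agent summary records, CSV round-trip |
| `diastress.epi_analysis` | in-repo Kaplan-Meier estimator, onset/recurrence/baseline/recovery analyses, parameter sweep |
| `diastress.cli` | `diastress` command-line interface |

## CLI

```bash
# simulate a cohort with the default parameterization
diastress simulate --n-agents 20000 --seed 1 --out cohort.csv

# run the four epidemiologic analyses (add --plot for PNG figures)
diastress analyze cohort.csv --outdir analysis/

# one-at-a-time parameter sweep
diastress sweep --n-agents 5000 --param threshold --values 10,15,20 --out sweep.csv

# full default run (100,000 agents, ~2 min) printing the headline statistics
diastress reproduce-paper --seed 1
```

Defaults: diathesis SD 0.20, stress SD 0.75, adaptation constant 3.0,
threshold 15, remission stringency 0.5, 3652-day horizon. A flat YAML
config file can supply any of these (`--config config.yaml`); flags
override file values. Runs are deterministic given the seed, with
per-agent substreams so results do not depend on cohort size or ordering.

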