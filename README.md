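# cagerank

Home-cage dominance analysis for group-housed male mice: from coded
behavioral event streams to directed sociomatrices, Glicko dominance
ratings, wound/gland/tube-test phenotype scores, and convergent /
discriminant validity statistics — plus a synthetic cage-study generator so
the whole pipeline is testable without coded video data.

## What it does

| Module | Role |
| --- | --- |
| `cagerank.ethogram` | Data model and CSV readers/validators for coded behavior events and instantaneous scans; contest extraction (aggression-initiator wins; submission scored for the mouse submitted to); Cohen's kappa for coder agreement |
| `cagerank.network` | Directed frequency/binary sociomatrices per cage; density, directional consistency (DC), in-/out-strength |
| `cagerank.glicko` | From-scratch Glicko-1 rating engine (default rating 2200, RD 300); net-change scores from aggression (`glicko_agg`) and submission (`glicko_sub`) contest streams |
| `cagerank.phenotypes` | 9×9 pelt-wound grid scores (severity × area × 0.25, anterior/mid/posterior averages), tube-test scores and trial bookkeeping, preputial-gland-to-body-length ratio, scan time budgets, proportion of scans alone |
| `cagerank.validity` | Standardization, strain/group-size residualization (mixed model with random cage intercept), correlation PCA with the eigenvalue-over-1 rule, ML factor analysis with varimax rotation and 0.45 loading threshold, factor-score regressions, tube-PC discriminant mixed model, Pearson correlations with Fisher-z CIs, 5-s submission-response scan with Bonferroni-contrasted logistic model (threshold 0.05/6 = 0.0083) |
| `cagerank.simulate` | Generative cage-study model: despotic aggression, down-rank targeting, submission responses within a latency window, 1-min-per-5-min all-occurrence thinning, 5-min scans, and dominance/strain-linked phenotypes with ground truth |
| `cagerank.pipeline` / `cagerank.cli` | Stage orchestration and the `cagerank` command-line tool |

## Run the tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (exact
combinatorial values, an independent Glicko-1 oracle transcription,
parameter-recovery and structure-recovery simulations, and null calibration
of the Bonferroni contrasts); the full suite takes ~8 minutes on one CPU.

## CLI

```bash
# generate a synthetic study (CSV bundle: cages/events/scans/phenotype inputs)
cagerank simulate --out data/ --seed 1 --cages-per-arm 6

# run everything against that bundle
cagerank all --data data/ --out results_run/ --seed 1

# or configure via YAML (sim block optional; constants are named keys)
cagerank all --config run.yaml
```

Example `run.yaml`:

```yaml
out_dir: results_run
seed: 1
alpha: 0.05
contrast_family_size: 6
loading_threshold: 0.45
eigenvalue_cutoff: 1.0
response_window_s: 5
sim:
  seed: 1
  n_cages_per_arm: 6
  despotism: 0.8
```

Stage subcommands (`ingest`, `network`, `rate`, `phenotypes`, `validity`,
`report`) run subsets against the same directory layout. Outputs include
per-cage sociomatrix CSVs, `metrics.csv`, `ratings.csv`, `phenotypes.csv`,
factor loadings / regression / contrast tables, and `validity_report.json`.

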