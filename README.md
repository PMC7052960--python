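# markovcea

Decision-tree + Markov cohort cost-effectiveness analysis of bone-metastasis
imaging strategies in recurrent prostate cancer.

A cohort of patients with biochemical recurrence is split by an imaging
decision tree (true/false positives and negatives from per-modality
sensitivity/specificity) and evolved through a five-state annual-cycle Markov
model — m0-BCR, m1-BCR, m0-CRPC, m1-CRPC and death — with age-dependent
background mortality from a period life table, a one-cycle tunnel state for
corrected false negatives, and a configurable pathway for false positives.
On top of the engine:

- **diagnostics** — Se/Sp/PPV/NPV/accuracy with exact Clopper–Pearson CIs,
  Cochran's Q on correctness indicators, McNemar post hoc tests, Cohen's kappa;
- **cea** — ICERs, efficiency frontier with strict and extended dominance,
  net monetary benefit, cost-effectiveness acceptability curves;
- **sensitivity** — one-way DSA (tornado) over 95% CI / SD ranges and a
  seed-reproducible Monte Carlo PSA (binomial transition/accuracy draws,
  moment-matched beta utilities, moment-matched gamma costs);
- **synthetic** — exact-count or sampled trial generators, gamma cost logs
  and Gompertz life tables, so the whole pipeline runs with no downloads;
- **lifetable** — loading, validation, lookup and life expectancy.

The bundled default life table (`src/markovcea/data/fr_male_2017_standin.csv`)
is a Gompertz–Makeham stand-in calibrated to published 2017 French male
summary statistics (life expectancy 79.4 at birth, 23.2 at 60); drop in the
real national table via `--lifetable` or the `lifetable` config key.

## Command line

```sh
markovcea base-case --reading onsite --out-dir results   # outcomes + frontier
markovcea base-case --reading central --out-dir results
markovcea dsa      --reading onsite --out-dir results    # tornado table
markovcea psa      --reading onsite --iterations 1000 --seed 1 --out-dir results
markovcea validate --out-dir results                     # no-imaging life expectancy
markovcea simulate-trial --mode exact_counts --out-dir results
```

All commands accept `--config config.yaml` (overriding any default
parameter; see `markovcea.config.default_config()` for the schema) and
`--lifetable path.csv`.  Result tables are tab-separated text; every run
writes a `manifest.json` with the config digest, seed and output paths.

Misdiagnosis handling is configurable under the `model:` section:
`fp_policy` (`persistent-m1` default, or `merge-m0`), `fp_cost` / `fn_cost`
(names of cost fields), `fn_tunnel` (`m1-row` or `m0-survival`),
`counting_method` (`life-table`, `beginning`, `end`) and
`joint_progression` (`combine` or `product`).

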