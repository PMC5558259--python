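# grstrial

A tested, reusable implementation of the computational chain behind a small
two-arm trial that communicates a 19-locus coronary-artery-disease genetic
risk score (GRS):

- **`grstrial.snp_score`** — weighted GRS construction from effect-allele
  dosages, risk-allele counts, and normalization (z-score, empirical
  percentile) against a reference-cohort distribution.
- **`grstrial.risk_engine`** — coefficient-table-driven Framingham-style
  10-year and 30-year risk equations, a log-link relative-risk regression of
  incident events on GRS z-score (adjusted for age and sex, sandwich SEs),
  and multiplicative genetic updating of the 10-year risk with a cap.
- **`grstrial.trial_design`** — eligibility screening (10-year threshold
  inclusive at 6%, 30-year strict at 20%, allowed-ethnicity set, exclusion
  flags), permuted-block randomization (default blocks of 8), and the
  three-visit trial ledger.
- **`grstrial.outcome_stats`** — carry-forward/exclusion rules for
  questionnaires, lipids (with a no-imputation sensitivity mode) and clinic
  measurements; Hodges–Lehmann shift estimates with rank-sum-inversion CIs
  (exact for small samples, tie-corrected normal approximation otherwise);
  Fisher-exact medication comparisons; and the two pre-specified subgroup
  analyses (high GRS vs. the full control arm; positive attitude toward
  medications in both arms).
- **`grstrial.synthetic_data`** — Hardy–Weinberg reference cohorts with a
  configurable per-SD relative-risk truth (default 1.18), and trial
  simulators with configurable arm effects, high-GRS interactions,
  retention (default 82% / 69%), and item missingness. Everything is a pure
  function of (config, seed).
- **`grstrial.cli_io`** — TSV/VCF genotype adapters with allele flipping,
  JSON configuration, and the end-to-end pipeline/CLI.

The bundled weight table fixes the 19-locus list (including the six proxy
relations) but ships **documented placeholder weights** — the numeric
per-allele log odds ratios are not redistributable. The 30-year coefficient
table is likewise a documented illustrative default. Both are
user-overridable files; all statistical machinery is exercised on synthetic
data.

## CLI

```sh
grstrial config init                       # print every default constant
grstrial simulate --what fixtures --seed 5 --out fixtures/
grstrial score --genotypes fixtures/genotypes.tsv \
    --reference fixtures/reference.json --out scores.csv
grstrial randomize --ids ids.txt --block-size 8 --seed 1 --out arms.csv
grstrial risk --covariates cov.csv --out risk.csv
grstrial all --config fixtures/config.json --out out/
```

`grstrial all` runs score → normalize → risks/eligibility → randomization
(or ingest of provided assignments) → carry-forward → outcome and subgroup
reports, and writes a `run_log.json` with the seed, config hash, and
per-stage counts; reruns are byte-identical.

## Layout

```
src/grstrial/           package (one module per pipeline stage)
src/grstrial/data/      bundled weight table and coefficient tables (text)
tests/                  pytest suite; tests/test_acceptance.py holds the
                        acceptance criteria at their stated tolerances
scripts/acceptance.py   acceptance report generator
```
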