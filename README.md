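# moha

Mode-of-HIV-acquisition (MOHA) attribution for adolescents living with
HIV, distinguishing **vertical** (parent-to-child) from **sexual**
acquisition.

The package implements a data-driven reference standard — an ordered
logic-tree classifier over harmonized self-reported sexual, family and
treatment history — and uses it to validate simple ART-initiation-age
cutoff classifiers (ages 10–15) with sensitivity, specificity,
predictive values, |sens − spec| and two-point ROC AUC. Because the
motivating cohort data are not public, a seeded synthetic-cohort
generator with known true labels makes the full pipeline reproducible
and testable offline.

## Layout

| module | role |
| --- | --- |
| `moha.io_model` | typed records (participants, wave records, medical records) and validated CSV I/O |
| `moha.harmonization` | collapse wave-level measures into per-participant derived factors (OR-across-waves, youngest-age rules, discordant disclosure, parental history) |
| `moha.cutoff_classifier` | ART-initiation-age cutoff allocation (init at/above cutoff → sexual) |
| `moha.logic_tree` | the gateway + ordered branch predicates (S1–S6, V1–V9, SLOW), switching, exit/affirmatory reporting |
| `moha.diagnostics` | confusion matrices, validation metrics, two-point ROC AUC, optimal-cutoff flags |
| `moha.synthetic_cohort` | seeded cohort generator and parameter-recovery harness |
| `moha.cli` / `moha.reporting` | `moha` command line, summary tables, run manifests |

## CLI

```sh
moha simulate --seed 1 --n 1000 --mothers 214 --out sim/
moha allocate --cohort sim/ --out alloc/            # harmonize + both classifiers
moha validate --alloc alloc/ --out val/             # metrics vs the tree reference
moha report   --run val/                            # print the metrics table
```

`moha allocate` automatically applies the adapted tree variant
(discordance and presumed-orphan branches disabled, sexual gateway
forced) to participants flagged as the single-wave young-mothers
sample; `--mothers-variant` forces it for everyone. Real data can enter
at the allocate stage as three CSVs (`participants.csv`, `waves.csv`,
`medical.csv`; empty cells are missing, booleans are 0/1 — see
`moha/io_model.py` for the column dictionary).

Every stage writes a `manifest.json` (config snapshot, seed, file
hashes, row counts); a full run from one seed is hash-identical.

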