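# lofproxy

Graded loss-of-function proxy analysis for strain-panel transcriptomes.

Natural expression variation across a genetically diverse strain panel can be
used as a dose-proxy for gene loss of function: strains in the lowest
expression quartile of a focal gene act as a partial-knockdown model and are
compared against a true-knockout contrast. `lofproxy` implements that
workflow end to end:

- **`synthetic`** — strain-panel and knockout expression simulators with
  planted, recoverable structure (focal gradient, coupled gene modules,
  per-stratum TF correlations, null genes) and a ground-truth table.
- **`dataio`** — TSV expression/metadata/probe-table I/O, probe selection
  (cross-hybridization filter, Shapiro–Wilk normality, dynamic range), and
  cross-platform renormalization (global z-score, rescaled to mean 8 / SD 2).
- **`stratify`** — focal-gene ranking, linear fold difference, percentile
  ranks, and HIGH/LOW/MID strata with published group-size presets
  (`paper-chow` = 12/12 of 42, `paper-hfd` = 11/10 of 37).
- **`corr`** — vectorized genome-wide Pearson screen against the focal gene,
  Benjamini–Yekutieli step-up FDR, sign summaries over named gene panels.
- **`enrichment`** — preranked GSEA (weighted Kolmogorov–Smirnov running sum,
  gene-sampling permutation null, NES, BY across sets) and hypergeometric
  over-representation analysis; GMT reader/writer.
- **`tfshift`** — per-TF Pearson correlations to a pathway-average profile
  within each stratum, Fisher-z correlation-shift tests (Δr = r_low − r_high,
  significance stars), Welch-t TF differential expression, and
  direction-concordant TF overlap across models.
- **`convergence`** — shared/unique classification of significant pathways
  across contrasts and within-set Spearman rank concordance.
- **`cli`** — YAML-config orchestration with reproducibility metadata.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, type-I error calibration, planted-structure recovery) at their
stated tolerances.

## CLI

Simulate a demo dataset (three arms share strain/gene ids) and run the whole
pipeline:

```sh
lofproxy simulate --out demo --seed 1 --arms cd,hfd,ko
lofproxy run-all --config demo/run_config.yaml
```

Outputs land in `demo/results/`: strata tables, the correlation screen,
ranked lists, GSEA/ORA tables, TF shift and differential-expression tables,
the TF overlap list, and a convergence report — each run stamped with a
config hash; identical config + seed reproduces byte-identical artifacts
(timestamps only in `run.log`).

Individual stages are independently invokable:

```sh
lofproxy screen  --matrix m.tsv --focal GENE --out screen.tsv
lofproxy gsea    --matrix m.tsv --focal GENE --gmt sets.gmt --preset paper-chow --out gsea.tsv
lofproxy ora     --hits hits.txt --universe universe.txt --gmt sets.gmt --out ora.tsv
lofproxy tfshift --matrix m.tsv --focal GENE --tf-list tfs.txt --gmt sets.gmt --out shifts.tsv
lofproxy report  --contrast cd=gsea_cd.tsv --contrast ko=gsea_ko.tsv --out report.json
```

## Input formats

- expression matrix: TSV, first column sample id, header of gene symbols,
  log2 values (`--orientation genes-rows` accepted for transposed exports);
- sample metadata: TSV with `sample`, `strain`, `diet` (CD/HFD/NA),
  `genotype` (WT/KO/NA);
- gene sets: GMT (name, description, members);
- TF list / gene panels: plain text, one symbol per line;
- probe table: TSV with `probe_id`, `gene`, `cross_hyb`, then sample columns.
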