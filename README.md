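# camur

Rule-based case/control classification of gene-expression matrices with
iterative feature elimination and a queryable knowledge base of the
extracted rules.

The learner induces models of the form

```
(ENSG00000167676.3 < 16.15) OR (ENSG00000166819.10 < 15.28) => Tumoral
```

from a samples-by-genes FPKM matrix (RIPPER-style: FOIL-gain growth,
reduced-error pruning, a description-length budget, stratified k-fold
cross-validation scoring). The engine then repeatedly removes combinations
of the genes used by accepted models and re-learns, surfacing alternative,
equally valid classifiers instead of a single one. Every accepted model is
persisted in a SQLite knowledge base that answers five extraction queries:
features list, literals/conjunctions list, rules list, literal statistics,
and feature pairs.

## Input format

A plain CSV with a header row; one row per sample. First column: sample
identifier. Last column: class label (e.g. `Tumoral` / `Normal`). Every
column in between: one gene's non-negative expression value. A European
dialect (`;` delimiter, `,` decimals) is available via `--european`.

## Command line

```sh
camur validate data.csv                 # structural + content validation
camur summary data.csv                  # per-class counts and percentages
camur synth --fixture redundant6 --out-dir fixtures/
camur synth --spec spec.json --out data.csv --truth truth.json
camur run data.csv --mode loose --max-iter 100 --min-f 0.8 --kb out.db --seed 7
camur query out.db features             # also: conjunctions, rules,
camur query out.db pairs --out pairs.csv  #       literal-stats, pairs
camur report out.db 1 --out report.md   # static results-page report
```

`camur run` writes a JSON run manifest (config, per-iteration records,
stop reason) next to the knowledge base; runs are fully deterministic for
a fixed `--seed`.

Exit codes: 0 success, 2 I/O problem, 3 data problem, 4 configuration
problem.

## Library

```python
from camur import (load_matrix, run_camur, EngineConfig, KnowledgeBase,
                   generate_dataset, SyntheticSpec, InformativeGroup)

m = load_matrix("data.csv")
result = run_camur(m, EngineConfig(mode="loose", seed=7))
kb = KnowledgeBase("out.db")
kb.add_run(result, m)
print(kb.query_features_list().rows)
```

The `camur.synth` module generates FPKM-like log-normal matrices with
planted (optionally redundant) discriminative genes and known ground
truth, so the full pipeline is testable without any external data.

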