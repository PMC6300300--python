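# sigtarget

Drug-target prediction from perturbation transcriptomics: correlate
drug-treatment differential-expression signatures with gene-knockdown
signatures across cell lines, combine correlation/network/annotation
features with learned rankers, re-rank the genomic top candidates with
externally supplied docking scores, and evaluate with best-known-target
rank statistics. A synthetic benchmark generator with planted direct and
indirect drug-target correlation structure makes every stage testable
offline.

## What it computes

Per (drug *d*, candidate gene *g*, cell line *c*), six features:

| feature | meaning |
| --- | --- |
| `f_cor` | signed Pearson correlation between the drug signature and *g*'s knockdown consensus |
| `f_PC` | degree-corrected enrichment of *g*'s interaction partners among the knockdowns most correlated with the drug (fold form, top-X list; X = 100 by default) |
| `f_CS` | mean correlation of the drug signature with the cell's controls (low = "active" cell) |
| `f_DE_mean` / `f_DE_max` | mean / max absolute Z of *g*'s partners in the drug signature |
| `f_loc` | cellular localization encoding: intracellular +1, transmembrane/extracellular -1, unknown 0 |

Rankers: single-feature rankers with lowest-rank-across-cells
aggregation (`dir`, `ind`, `max`, `mean`), a most-active-cell variant
(`cs`), a logistic-regression baseline (`lr`), and two random-forest
architectures — `rf-otf` (drug-specific forest over drugs sharing the
query's cell set, features concatenated per cell) and `rf-2l` (pooled
per-cell forest whose probabilities are aggregated per gene and fed to a
second forest) — evaluated with leave-one-drug-out cross-validation.
Structural re-ranking reorders the genomic top-100 by ascending docking
score (absent scores = no structure; such candidates are appended in
genomic order) and calls hits below the per-drug median score.

## CLI

```bash
sigtarget simulate --out bench/ --seed 1 --n-drugs 50 --n-kd-genes 200
sigtarget features --data bench/ --out features.tsv --x 100
sigtarget rank --features features.tsv --model rf-2l \
    --targets bench/drug_targets.tsv --out ranks.tsv --seed 1
sigtarget rerank --ranks ranks.tsv --scores docking.tsv --out rerank.tsv
sigtarget evaluate --ranks ranks.tsv --targets bench/drug_targets.tsv \
    --out report.json
```

On-disk formats: GCT 1.2 for signature matrices; TSV for sample
metadata, the interaction edge list, drug-target and localization maps,
docking scores, feature tables and rankings.

## Layout

- `src/sigtarget/types.py`, `io.py` — domain types, GCT/TSV readers and writers
- `src/sigtarget/features.py` — the six feature families
- `src/sigtarget/ranking.py` — single-feature, logistic and random-forest rankers, LOOCV
- `src/sigtarget/rerank.py` — docking-score re-ranking + mock score provider
- `src/sigtarget/evaluation.py` — top-k / mean-rank / normalized-rank ROC / permutation baseline / hypergeometric enrichment
- `src/sigtarget/simulate.py` — planted synthetic benchmark generator
- `src/sigtarget/refdata.py` + `data/` — bundled published benchmark tables
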