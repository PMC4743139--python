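# oxyreq

Naive Bayes prediction of bacterial oxygen requirement — aerobe, anaerobe,
or facultative anaerobe — from the presence/absence of Pfam-A protein
domains in a genome.

The method:

1. **Feature selection** — a Pfam-A domain is *class-associated* when it is
   present in ≥ 65% of a class's genomes, its in-class frequency exceeds the
   pooled frequency of the other classes, and a two-tailed two-sample
   t-test on the 0/1 indicators gives p < 0.05. The selected domains with
   their per-class presence frequencies form the *likelihood file*.
2. **Prediction** — Bernoulli naive Bayes with a flat prior: each domain
   contributes its presence likelihood p(domain | class) when present and
   1 − p when absent, clamped into [0.1, 0.9] by a pseudo-count so that a
   single observation can never zero out a class. Computation is done in
   log space.
3. **Network topologies** — either a flat three-class prediction
   (*one-step*), or a nested dichotomy (*two-step*): first
   respiration-capable (aerobe ∪ facultative) vs. anaerobe, then aerobe vs.
   facultative for the genomes predicted respiration-capable. An
   *aa-only* mode drops facultative genomes for a pure aerobe/anaerobe
   dichotomy.
4. **Evaluation** — leave-one-out cross-validation with feature selection
   and likelihood estimation redone in every fold, confusion tables, and
   one-vs-rest Matthews Correlation Coefficient per class.

## CLI

```sh
# synthesize a labeled matrix with planted class structure
oxyreq simulate --out-matrix matrix.tsv --out-labels labels.tsv \
    --classes "aerobe=175,anaerobe=112,facultative=91" --seed 1

# build a matrix from hmmscan tblout/domtblout files (one per genome)
oxyreq build-matrix scans/*.tbl --out matrix.tsv

# leave-one-out cross-validation + evaluation report
oxyreq loocv --matrix matrix.tsv --labels labels.tsv \
    --mode two-step --out-dir run/

# train on everything and classify new profiles
oxyreq train --matrix matrix.tsv --labels labels.tsv \
    --mode two-step --out-dir model/
oxyreq predict --model-dir model/ --matrix new_profiles.tsv --out pred.tsv
```

`--mode` is `one-step`, `two-step` (default) or `aa-only`; selection and
smoothing parameters are exposed as `--threshold`, `--alpha`, `--welch`,
`--pseudo-count`, `--pc-mode`.

All file formats are plain TSV: the presence matrix (`genome_id` header
column, one 0/1 column per domain), a two-column label map, and the
likelihood file (`domain`, `associated_class`, one frequency column per
class, plus `t`/`p` selection statistics).

## Layout

| module | contents |
| --- | --- |
| `oxyreq.core_io` | domain types (matrix, schemes, likelihood table) and TSV / hmmscan readers & writers |
| `oxyreq.feature_selection` | class frequencies, counts-based t-test, class-associated domain selection |
| `oxyreq.bayes_net` | posterior computation, one-/two-step models, leave-one-out cross-validation |
| `oxyreq.evaluation` | confusion tables, one-vs-rest MCC, misclassification rate, report writer |
| `oxyreq.synthetic_data` | seeded generator of labeled matrices with planted class-conditional Bernoulli structure |
| `oxyreq.cli` | `oxyreq` command-line entry point |
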