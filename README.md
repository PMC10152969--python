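# tcrbench

A benchmarking harness for T-cell receptor–peptide-MHC (TCR–pMHC)
binding predictors.

Predicting whether a T cell's receptor recognizes a given peptide-MHC
complex is a central problem of computational immunology, and many
sequence-based predictors exist. Their reported performance, however,
depends heavily on how the evaluation data were assembled: public
binding collections are dominated by a handful of heavily screened
epitopes, negatives must be synthesized because only binding pairs are
observed, and a test peptide that also occurs in training ("seen")
poses a much easier task than a novel one ("unseen"). `tcrbench`
provides the data machinery to audit any predictor under controlled
versions of exactly these conditions:

- **Harmonization** of heterogeneous resource exports (VDJdb-, IEDB-,
  McPAS-, ImmuneCODE-, TBAdb-, 10X-style tables) into one schema
  (CDR3α, CDR3β, peptide, MHC), with amino-acid quality control and
  cross-resource deduplication.
- **Dataset variants**: a *base* set (9-mer peptides, CDR3β length
  10–18, HLA-A\*02-presented, deduplicated on CDR3β × peptide); a
  *balanced* set in which every peptide contributes 5–10 examples; an
  *imbalanced* set in which the most frequent peptide (mfp) keeps all
  its records while the rest are balanced — separating the effect of
  imbalance from the effect of size.
- **Two 5-fold splitting regimes**: *uniform* (each peptide spread
  over all folds — test peptides are seen) and *strict* (peptide-
  disjoint folds — test peptides are unseen), with a dominance cap
  guaranteeing no fold is more than half one peptide.
- **Within-fold negatives** at 1:1, generated by rearranging the
  fold's TCR–peptide pairs so that the negative class has the *same*
  peptide marginal as the positive class — peptide frequency alone
  carries no label signal.
- **Evaluation** of any predictor implementing a two-method contract
  (`fit(train_table)`, `predict(records) -> scores in [0,1]`):
  per-fold ROC-AUC, PR-AUC (average precision), accuracy, and a
  per-peptide accuracy table against training occurrence. Scores from
  external tools plug in through a score-column adapter.

Imbalance is quantified by the normalized Shannon entropy of the
peptide occurrence fractions c_i over the K unique peptides:

    Balance = −(1 / log K) · Σ_{i=1..K} c_i log c_i

1 means perfectly even; values toward 0 mean domination by few
peptides.

A synthetic-data generator (Zipf-distributed peptide frequencies,
random CDR3β sequences, optional planted per-peptide binding motifs
with known ground truth) makes the entire pipeline runnable and
testable without downloading anything.

## Worked example

A full synthetic benchmark run from one config file
(`examples/synthetic_benchmark.yaml`: 20 peptides, 1200 positive
pairs, every CDR3β carrying its peptide's 3-mer motif):

```
$ tcrbench run examples/synthetic_benchmark.yaml
```

The manifest reports, per stage, records in → out and the stage's key
numbers: the built base set has balance 0.9667; negatives double the
table (1200 → 2400 rows at 1:1); the calibrated 3-mer nearest-neighbor
baseline under **uniform** (seen-peptide) splitting reaches

```
roc_auc_mean  0.9826   pr_auc_mean  0.9713   accuracy_mean  0.9588
```

Rerunning the last stages on the same base set with the **strict**
(unseen-peptide) split collapses the same predictor to chance:

```
$ tcrbench split    scratch/run/base.tsv --method strict --k 5 --seed 1 --out folds.tsv
$ tcrbench negatives folds.tsv --seed 2 --out labeled.tsv
$ tcrbench evaluate  labeled.tsv --predictor kmer_nn --k 5 --out metrics.json
kmer_nn: ROC-AUC 0.500±0.000, PR-AUC 0.500±0.000, accuracy 0.500
```

That contrast — strong apparent skill on seen peptides, chance on
unseen ones — is the central diagnostic the harness exists to make
routine: a predictor that only interpolates within peptides it has
seen shows exactly this signature. The per-peptide accuracy table
(`per_peptide_accuracy.tsv`) joins each test peptide's accuracy with
its training occurrence, exposing how performance concentrates on
frequent peptides.

The same stages are available as library functions
(`tcrbench.harmonize`, `build_base`/`build_balanced`/`build_imbalanced`,
`uniform_split`/`strict_split`, `generate_negatives`,
`crossval_evaluate`) for use in notebooks and scripts.

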