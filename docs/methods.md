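# Methods

This note documents the models, procedures, defaults and design
choices behind `tcrbench`, in the order the pipeline runs them.

## Data model and harmonization

Every table in the pipeline is a pandas DataFrame with the fixed
columns `cdr3_alpha, cdr3_beta, peptide, mhc, source, label`; absent
fields are empty strings so tables round-trip losslessly through TSV.
`Dataset` wraps a frame with a name and a provenance record (filters,
seeds, parent dataset), and row order is part of the contract: all
seeded sampling iterates in deterministic order (resource registration
order, then file row order), so a rerun reproduces the same bytes.

Resource dialects are declared in `SchemaMap` config blocks (YAML),
not hardcoded readers; example maps for six common public resources
ship with the package. Reading drops rows that lack a peptide or lack
both CDR3 chains. Quality control strips whitespace, uppercases, and
keeps only sequences over the 20 canonical amino-acid letters —
case-folding before the alphabet check because real exports mix cases.
Merging concatenates resources in registration order and deduplicates
on the full observation tuple `(cdr3_alpha, cdr3_beta, peptide, mhc)`,
keeping the first occurrence; this is the most conservative
deduplication key (two records differing only in MHC resolution are
both kept), and the key is recorded in provenance.

## Dataset variants

`build_base` keeps records with a present CDR3β of length 10–18, a
9-mer peptide, and an MHC annotation in the HLA-A\*02 allele group,
then deduplicates on `(cdr3_beta, peptide)`. These bounds are the
intersection of what common sequence-based predictors accept, and the
single allele group removes MHC variation as a confounder. Allele
strings are normalized before prefix-matching (`HLA-A2` and
`HLA-A02:01` both normalize to starred notation); records with no MHC
annotation cannot be verified against the allele criterion and are
excluded (counted in the log). Without the `*` separator only a
letters-only gene name is parsed unambiguously; digit-bearing gene
names (e.g. DRB1) require the starred form.

`build_balanced` removes peptides with fewer than
`min_examples_per_peptide` (default 5) positives and downsamples
peptides above `downsample_cap` (default 10) to exactly the cap,
uniformly without replacement. Each peptide draws from its own RNG
keyed by `(seed, frequency rank)`, so the picks for one peptide do not
depend on which other peptides were downsampled — this makes the
imbalanced build (below) agree exactly with the balanced build on
shared peptides. Downsampled-away records are returned as a
`ReferencePool`, not discarded: their CDR3β sequences are the fallback
TCRs of negative generation. Records removed by the *minimum* filter
do not enter the pool — they were filtered, not downsampled.

`build_imbalanced` exempts the most frequent peptide (recomputed from
the input, ties broken lexicographically) from both the minimum and
the cap; everything else follows the balanced rules. The pair of
datasets isolates peptide imbalance from dataset size: the imbalanced
variant is larger and strictly less balanced whenever the mfp exceeds
the cap.

## Splitting

`uniform_split(dataset, k, seed)` excludes peptides with fewer than k
records (they cannot place one record in every fold), shuffles each
retained peptide's records, and deals them round-robin with a
per-peptide rotating starting offset (offset = peptide frequency rank
mod k) so remainder records spread over folds instead of accumulating
in fold 0. Per-peptide fold counts are therefore always within
floor(n/k)..ceil(n/k).

`strict_split` assigns whole peptides to folds: seeded shuffle (which
randomizes ties), stable sort by count descending, then greedy
assignment of each peptide to the currently smallest fold. Fold size
is measured as the *post-cap effective size*: a fold whose dominant
peptide outweighs the sum R of its other peptides counts as 2R,
because the dominance cap will shrink it to that. Measuring raw size
instead would leave any peptide holding more than 1/k of all records
permanently alone in its fold (fold sizes of the others never catch
up), making the cap unsatisfiable — and the most frequent peptide in
real collections does hold more than 1/k of the records. After
assignment, each fold is capped: while the dominant peptide's count
c_max exceeds R, it is downsampled (seeded, without replacement) to R,
after which it is exactly half the fold; the loop handles the rare
case where capping promotes a new dominant peptide. Dropped records
join the reference pool. A fold left with fewer than two peptides is
an error (the cap cannot be satisfied), reported with the fold index.

`validate_split` re-checks every invariant (disjointness, dominance,
floor/ceil bounds, index consistency) and lists violating peptides; it
never mutates.

## Negative generation

Within each fold, the peptide column is rearranged over the fold's
TCRs: a seeded shuffle with rejection-resampling (default budget 100
rounds) assigns each TCR a peptide that (a) differs from every peptide
that TCR binds anywhere in the positive dataset, (b) does not form a
known positive pair, and (c) has not already been generated. The
rearrangement (rather than independent resampling) preserves the
peptide marginal of the negatives exactly, which is what makes the
peptide-frequency diagnostic meaningful. Excluding *all* of a TCR's
known binding partners — not just its fold-local ones — is a cheap
strengthening of the assumption that a rearranged pair is unlikely to
bind.

Two completion mechanisms handle the end game. First, a swap repair:
a leftover peptide that is invalid for every pending TCR is exchanged
with an already-assigned slot when both directions are legal. Second,
the reference pool: positives still unmatched keep their peptide and
draw a pool TCR (a CDR3β removed during downsampling or the strict
cap) under the same constraints, so the negative peptide marginal is
preserved even in dominated folds. If negatives still cannot be
completed the fold is degenerate (e.g. near-single-peptide) and the
generator raises an error reporting the shortfall, rather than
silently under-delivering. The positive:negative ratio defaults to
1:1 and generalizes to 1:n by replicating the slot list.

## Balance statistic

Balance = −(1/log K) Σ c_i log c_i with c_i the peptide occurrence
fractions. The logarithm base cancels between numerator and
normalizer. K = 1 makes the normalizer zero; a single peptide is
returned as balance 1.0 (trivially "even") with a warning, since both
limits (perfect evenness and total domination) are defensible and the
caller should know the value is degenerate.

## Evaluation harness

`crossval_evaluate` runs leave-one-fold-out evaluation: for each fold,
a fresh predictor is fitted on the union of the other folds (negatives
included — they were generated within folds, so training and test
negatives never mix) and scored on the held-out fold. Row identity is
asserted to never overlap between train and test. Metrics per fold:

- **ROC-AUC** — probability a random positive outscores a random
  negative, ties counted half (midrank convention); computed via
  scikit-learn and cross-checked in the tests against a brute-force
  pairwise oracle.
- **PR-AUC** — average precision (step-wise sum of precision times
  recall increment), not trapezoidal interpolation, which is known to
  be biased for PR curves.
- **Accuracy** at a fixed 0.5 threshold. Binary-output predictors are
  supported; their ROC/PR curves degrade gracefully to three points.

Aggregates are arithmetic mean ± sample standard deviation over folds;
no cross-fold model selection enters the aggregate. The per-peptide
table pools each test peptide's correct/total counts over folds and
joins its mean training-positive occurrence — the axes of
frequency-versus-accuracy diagnostics.

### Baselines

- `peptide_freq`: scores by the peptide's training frequency, ignoring
  the TCR. On shuffle-generated negatives this must sit at ROC-AUC
  0.5; deviation indicates a leak in negative generation.
- `kmer_nn`: indexes training binders per peptide by CDR3β 3-mer
  multisets; the raw score is the maximal normalized multiset overlap
  Σ min(q_m, b_m) / max(|q|, |b|) over the query peptide's binders
  (identical binder → 1.0, no shared 3-mer → 0.0, unseen peptide →
  0.5). With `calibrated=True`, raw overlaps are Platt-scaled
  per peptide (falling back to a global fit below 10 training rows or
  with one class), using leave-one-out overlaps so a training positive
  never matches its own index entry. Per-peptide calibration matters
  because the null level of a maximum over binders grows with the
  number of binders indexed; it also means frequently observed
  peptides get better-estimated thresholds — the mechanism by which
  accuracy increases with training occurrence.
- `memory`: scores 1.0 exactly for training positive pairs — exposes
  pair-level leakage between folds.
- `constant`, and `external` (reads a score column written by any
  outside tool, enabling evaluation of published deep models without
  re-implementing them).

## Synthetic data generator

The generator emulates the statistical structure of real binding
collections: peptide frequencies follow a truncated Zipf law over
ranks (exponent 0 = uniform; exponents around 1–2 reproduce the
heavy concentration on a few epitopes seen in public data), CDR3β
sequences are uniform random strings of length 10–18 framed by the
conserved C…F (flag-controlled, default on), peptides are 9-mers, and
MHC is fixed to HLA-A\*02:01 so generated tables pass the base-set
filters unchanged. An optional binding signal plants a per-peptide
3-mer motif into a positive record's CDR3β with probability
`motif_strength`, by overwriting a window (not inserting, so lengths
stay in range) at a random interior position; motifs are distinct
across peptides and returned as ground truth. Negatives are never
generated here — synthetic data flows through the same splitting and
negative-generation path as real data.

What the generator does *not* emulate: V(D)J-recombination sequence
statistics, germline-biased k-mer composition, cross-reactive motif
sharing between similar peptides, batch effects between resources,
and label noise. Consequently, passing tests demonstrate the
correctness and leak-freedom of the *pipeline machinery* and the
qualitative direction of its diagnostics (seen ≫ unseen for
peptide-conditional predictors; chance when no signal is planted) —
not the absolute performance any predictor would reach on real
repertoire data.

## Pipeline and reproducibility

`run_pipeline` executes source → build → split → negatives → evaluate
from one declarative YAML config, writing every intermediate TSV, a
JSON manifest with per-stage record counts and output digests, and the
metrics. One global seed fans out to per-stage seeds via
`numpy.random.SeedSequence(seed, spawn_key=(stage_index,))` (reduced
mod 2^31), so a single integer pins the whole run while stages remain
statistically independent; any stage may also pin its own seed.
Negative generation derives one seed per fold (stage seed + fold
index).

## Problem sizes in tests and the acceptance script

The shipped checks use synthetic datasets of 1200–2500 positive
records over 10–25 peptides with 5 seeds per stochastic claim (10 for
the shuffle diagnostic), chosen so every claim is measured on folds
of several hundred records — large enough that chance-level ROC-AUC
is resolved well within ±0.05 — while a full run stays around a
minute. The imbalance-dependency check uses zipf exponent 1.5 and
motif strength 0.5: a partially deterministic motif means a rarely
observed peptide's motif may be missing or sparsely represented in
training, which is exactly the training-occurrence effect the
per-peptide table is designed to expose.

## Known limitations

- Harmonization reads flat delimited exports only; paired-chain
  resources that encode both chains in one cell need pre-flattening.
- The strict split balances fold sizes greedily; it does not attempt
  optimal bin-packing, and fold sizes can differ by up to the largest
  (post-cap) peptide block.
- MHC normalization targets class I HLA naming; unparseable strings
  are compared verbatim.
- The k-mer baseline is a diagnostic, not a competitive predictor; it
  exists to exercise the harness and to make the seen/unseen contrast
  assertable.
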