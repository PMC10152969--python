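"""K-fold partitioning of positive binding data under two regimes.

``uniform``
    Each peptide's records are spread across all k folds (seeded
    shuffle, round-robin deal with a rotating starting offset), so a
    test-fold peptide is always *seen* during training.  Peptides with
    fewer than k records cannot put one record in every fold and are
    excluded.
``strict``
    Peptides are assigned whole to folds (seeded greedy bin-packing),
    so folds are peptide-disjoint and every test peptide is *unseen*.
    Because whole peptides travel together, a frequent peptide could
    dominate its fold; any fold whose most frequent peptide exceeds
    half the fold's entries has that peptide downsampled until it
    accounts for exactly half.  Records dropped by this cap join the
    reference pool used during negative generation.

The contrast between the two regimes is the benchmark's core probe of
predictor generalization to unseen peptides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import Dataset, SplitError

logger = logging.getLogger(__name__)

#: Fold value of records not assigned to any fold.
EXCLUDED = -1


@dataclass
class FoldAssignment:
    """Record-to-fold mapping for one k-fold scheme.

    ``fold`` is indexed like the dataset's frame; values are fold
    indices 0..k−1 or :data:`EXCLUDED`.  For strict splits,
    ``pool_index`` lists the records removed by the dominance cap
    (a subset of the excluded records) destined for the reference pool.
    """

    method: str
    k: int
    seed: int
    fold: pd.Series
    pool_index: pd.Index = field(default_factory=lambda: pd.Index([]))

    def fold_index(self, f: int) -> pd.Index:
        return self.fold.index[self.fold == f]

    @property
    def excluded_index(self) -> pd.Index:
        return self.fold.index[self.fold == EXCLUDED]

    def apply(self, dataset: Dataset) -> pd.DataFrame:
        """Return the dataset frame with an integer ``fold`` column."""
        df = dataset.df.copy()
        df["fold"] = self.fold.reindex(df.index).astype(int)
        return df


def _ranked_peptides(counts: pd.Series) -> list[str]:
    # count descending, peptide lexicographic: the deterministic order
    # used for rotating offsets and rng draw sequencing.
    return list(counts.index)


def uniform_split(dataset: Dataset, k: int, seed: int) -> FoldAssignment:
    """Distribute every retained peptide's records across all k folds.

    Peptides with fewer than k records are excluded (they cannot reach
    every fold).  Within a peptide, records are shuffled (seeded) and
    dealt round-robin starting at a per-peptide rotating offset so
    remainder records do not accumulate in fold 0.  The resulting
    per-fold counts of a peptide with n records are all in
    [floor(n/k), ceil(n/k)].
    """
    if k < 2:
        raise SplitError("k must be >= 2")
    counts = dataset.peptide_counts()
    retained = counts[counts >= k]
    if retained.empty:
        raise SplitError(f"no peptide has >= {k} examples")
    rng = np.random.default_rng(seed)
    fold = pd.Series(EXCLUDED, index=dataset.df.index, dtype=int)
    for offset, pep in enumerate(_ranked_peptides(retained)):
        idx = dataset.df.index[dataset.df["peptide"] == pep].to_numpy()
        rng.shuffle(idx)
        for j, rec in enumerate(idx):
            fold.at[rec] = (offset + j) % k
    n_excl = int((fold == EXCLUDED).sum())
    if n_excl:
        logger.info("uniform_split: excluded %d records of %d peptides with < %d examples",
                    n_excl, int((counts < k).sum()), k)
    return FoldAssignment(method="uniform", k=k, seed=seed, fold=fold)


def strict_split(dataset: Dataset, k: int, seed: int) -> FoldAssignment:
    """Assign whole peptides to folds so fold peptide-sets are disjoint.

    Peptides are shuffled (seeded, randomizing ties), stably sorted by
    count descending, and each assigned to the currently smallest fold,
    where a fold's size is its *post-cap effective* size: a fold whose
    dominant peptide outweighs the rest counts as 2·(sum of the rest),
    since the dominance cap will shrink it to that.  (Measuring raw
    size instead would leave any peptide holding more than 1/k of the
    records alone in its fold, making the cap unsatisfiable.)
    Then, per fold, while the most frequent peptide's count exceeds the
    summed count R of the fold's other peptides, it is downsampled
    (seeded, uniform without replacement) to R — after which it is
    exactly half of the fold.  Dropped records go to ``pool_index``.
    """
    if k < 2:
        raise SplitError("k must be >= 2")
    counts = dataset.peptide_counts()
    rng = np.random.default_rng(seed)
    peptides = np.array(counts.index)
    rng.shuffle(peptides)
    order = sorted(peptides, key=lambda p: -counts[p])  # stable: ties stay shuffled

    fold_of_pep: dict[str, int] = {}
    totals = np.zeros(k, dtype=int)
    maxima = np.zeros(k, dtype=int)

    def effective(f: int) -> int:
        rest = totals[f] - maxima[f]
        return int(totals[f] if maxima[f] <= rest else 2 * rest)

    for pep in order:
        f = int(np.argmin([effective(i) for i in range(k)]))
        fold_of_pep[pep] = f
        totals[f] += counts[pep]
        maxima[f] = max(maxima[f], counts[pep])

    fold = dataset.df["peptide"].map(fold_of_pep).astype(int)
    fold.index = dataset.df.index
    pool_records: list = []

    for f in range(k):
        in_fold = fold == f
        pep_counts = dataset.df.loc[in_fold, "peptide"].value_counts()
        if len(pep_counts) < 2:
            raise SplitError(
                f"fold {f} holds {len(pep_counts)} peptide(s); the half-fold "
                f"dominance cap cannot be satisfied"
            )
        # Cap loop: downsampling the dominant peptide may promote a new
        # dominant one; iterate until stable (rarely more than once).
        while True:
            pep_counts = pep_counts.sort_index().sort_values(
                ascending=False, kind="stable")
            top_pep = pep_counts.index[0]
            c_max = int(pep_counts.iloc[0])
            rest = int(pep_counts.iloc[1:].sum())
            if c_max <= rest:
                break
            idx = fold.index[(fold == f)
                             & (dataset.df["peptide"] == top_pep)].to_numpy()
            keep = rng.choice(len(idx), size=rest, replace=False)
            mask = np.zeros(len(idx), dtype=bool)
            mask[keep] = True
            dropped = idx[~mask]
            fold.loc[dropped] = EXCLUDED
            pool_records.extend(dropped.tolist())
            pep_counts[top_pep] = rest
    fa = FoldAssignment(
        method="strict", k=k, seed=seed, fold=fold,
        pool_index=pd.Index(pool_records),
    )
    if pool_records:
        logger.info("strict_split: dominance cap moved %d records to the reference pool",
                    len(pool_records))
    return fa


class SplitValidationReport(NamedTuple):
    passed: bool
    violations: list[str]


def validate_split(dataset: Dataset, fa: FoldAssignment) -> SplitValidationReport:
    """Check every invariant of a fold assignment against its dataset.

    Never mutates.  Violations name the offending peptide or fold.
    """
    violations: list[str] = []
    if not fa.fold.index.equals(dataset.df.index):
        raise SplitError("fold assignment index does not match dataset index")
    assigned = fa.fold[fa.fold != EXCLUDED]
    if not assigned.between(0, fa.k - 1).all():
        violations.append("fold indices outside 0..k-1")

    df = dataset.df.assign(_fold=fa.fold)
    active = df[df["_fold"] != EXCLUDED]
    if fa.method == "strict":
        pep_folds = active.groupby("peptide")["_fold"].nunique()
        for pep in pep_folds.index[pep_folds > 1]:
            violations.append(f"peptide {pep} spans {pep_folds[pep]} folds")
        for f, grp in active.groupby("_fold"):
            top = grp["peptide"].value_counts().iloc[0]
            if 2 * top > len(grp):
                violations.append(
                    f"fold {f}: dominant peptide holds {top}/{len(grp)} records"
                )
    elif fa.method == "uniform":
        for pep, grp in active.groupby("peptide"):
            n = len(grp)
            per_fold = grp["_fold"].value_counts().reindex(
                range(fa.k), fill_value=0)
            lo, hi = n // fa.k, -(-n // fa.k)
            if not per_fold.between(lo, hi).all():
                violations.append(
                    f"peptide {pep}: fold counts {per_fold.tolist()} outside "
                    f"[{lo}, {hi}]"
                )
    else:
        violations.append(f"unknown split method {fa.method!r}")
    return SplitValidationReport(passed=not violations, violations=violations)
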