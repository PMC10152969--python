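"""Evaluation harness: balance statistic, metrics, cross-validation.

The balance statistic is the normalized Shannon entropy of the
per-peptide occurrence fractions,

    Balance = −(1/log K) · Σ_i c_i log c_i ,

with K the number of unique peptides and c_i peptide i's share of the
records; 1 means perfectly even, values toward 0 mean domination by
few peptides.  The base of the logarithm cancels.

Predictor performance is measured per cross-validation fold by
ROC-AUC, PR-AUC (average precision) and accuracy at a fixed 0.5
threshold, plus a per-peptide accuracy table joined with each
peptide's training-set occurrence — the diagnostic that reveals
whether a predictor's apparent skill is concentrated on frequent
peptides.

Any predictor enters through :class:`PredictorContract`: ``fit`` on a
labeled training table, ``predict`` scores in [0, 1] for
(CDR3β, peptide) rows.  Reference baselines are provided: a
peptide-frequency-only predictor (diagnostic of the negative-pair
shuffle design), a CDR3β 3-mer nearest-neighbor predictor (minimal
learnable model), a pair-memorization predictor, a constant predictor,
and a wrapper for scores produced by external tools.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "BalanceReport", "balance", "dataset_balance",
    "roc_auc", "pr_auc",
    "PredictorContract", "EvalResult", "crossval_evaluate",
    "baseline_peptide_frequency", "baseline_kmer_nn",
    "baseline_memory", "baseline_constant", "external_scores",
]


# --------------------------------------------------------------------
# balance statistic
# --------------------------------------------------------------------

@dataclass(frozen=True)
class BalanceReport:
    """Normalized Shannon entropy of peptide occurrence fractions."""

    k: int
    fractions: tuple[float, ...]
    balance: float


def balance(counts: Sequence[float] | Mapping[str, float]) -> BalanceReport:
    """Compute the balance statistic from per-peptide positive counts.

    counts may be a sequence or a peptide→count mapping; all counts
    must be positive.  K = 1 is degenerate (log K = 0): by convention a
    single peptide is perfectly "even" and returns 1.0 with a warning.
    """
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts,
        dtype=float,
    )
    if values.size == 0 or values.sum() <= 0:
        raise ValueError("balance requires at least one positive count")
    if (values <= 0).any():
        raise ValueError("all counts must be positive")
    c = values / values.sum()
    k = int(values.size)
    if k == 1:
        warnings.warn("balance of a single peptide is 1.0 by convention")
        return BalanceReport(k=1, fractions=(1.0,), balance=1.0)
    h = float(-(c * np.log(c)).sum() / np.log(k))
    return BalanceReport(k=k, fractions=tuple(c), balance=h)


def dataset_balance(dataset) -> BalanceReport:
    """Balance of a Dataset's positive records."""
    df = dataset.df
    pos = df[df["label"] == 1] if "label" in df.columns else df
    return balance(pos["peptide"].value_counts().to_dict())


# --------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------

def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    return s, y


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve: the probability that a random positive
    outscores a random negative, ties counted half (midrank)."""
    s, y = _check_scores_labels(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(y, s))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve, computed as average
    precision (sum of precision at each threshold weighted by the
    recall increment; no interpolation)."""
    s, y = _check_scores_labels(scores, labels)
    if y.sum() == 0:
        raise ValueError("pr_auc needs at least one positive")
    return float(average_precision_score(y, s))


# --------------------------------------------------------------------
# predictor contract and baselines
# --------------------------------------------------------------------

@runtime_checkable
class PredictorContract(Protocol):
    """What the harness requires of a predictor.

    ``fit`` receives a labeled training table (columns cdr3_beta,
    peptide, label at minimum).  ``predict`` returns one finite score
    in [0, 1] per row of its argument and must be deterministic after
    fit.
    """

    def fit(self, train: pd.DataFrame) -> None: ...

    def predict(self, records: pd.DataFrame) -> np.ndarray: ...


class PeptideFrequencyBaseline:
    """Scores a pair by its peptide's frequency among training
    positives, ignoring the TCR entirely.

    On shuffle-generated negatives the peptide marginals of the two
    classes coincide, so this predictor should hover at ROC-AUC 0.5 —
    a diagnostic that the negative-generation design leaks no
    peptide-frequency signal.
    """

    def __init__(self) -> None:
        self._freq: dict[str, float] = {}
        self._default = 0.5

    def fit(self, train: pd.DataFrame) -> None:
        pos = train[train["label"] == 1]
        counts = pos["peptide"].value_counts()
        if counts.empty:
            raise ValueError("training table has no positives")
        scaled = counts / counts.max()
        self._freq = scaled.to_dict()
        self._default = float(scaled.mean())

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        return np.array(
            [self._freq.get(p, self._default) for p in records["peptide"]],
            dtype=float,
        )


def _kmers(seq: str, k: int) -> Counter:
    return Counter(seq[i:i + k] for i in range(len(seq) - k + 1))


class KmerNNBaseline:
    """Nearest-neighbor predictor on CDR3β k-mer multisets.

    fit indexes the training positives' CDR3β 3-mer multisets per
    peptide.  The raw score of (query CDR3β, peptide) is the maximal
    normalized multiset overlap — Σ_m min(q_m, b_m) / max(|q|, |b|) —
    over the peptide's training binders: identical to a binder gives
    1.0, no shared k-mer gives 0.0.  A peptide never seen in training
    scores 0.5 (no evidence either way).

    With ``calibrated=True`` the raw overlap is passed through Platt
    scaling (logistic regression on the training table's own leave-one-
    out overlaps vs labels), producing probability-like scores for
    which the harness's fixed 0.5 accuracy threshold is meaningful.
    Calibration is per peptide where the peptide has enough training
    rows of both classes (the null level of a max-overlap depends on
    how many binders are indexed for that peptide), with a global
    fallback otherwise; unseen peptides still score 0.5.
    """

    #: minimum training rows of a peptide for its own Platt fit.
    MIN_CALIBRATION_ROWS = 10

    def __init__(self, k: int = 3, calibrated: bool = False) -> None:
        self.k = k
        self.calibrated = calibrated
        self._index: dict[str, list[tuple[Counter, int, str]]] = {}
        self._platt: LogisticRegression | None = None
        self._platt_per_pep: dict[str, LogisticRegression] = {}

    def fit(self, train: pd.DataFrame) -> None:
        pos = train[train["label"] == 1]
        self._index = {}
        for pep, grp in pos.groupby("peptide"):
            self._index[pep] = [
                (km, sum(km.values()), s)
                for s, km in ((s, _kmers(s, self.k)) for s in grp["cdr3_beta"])
            ]
        if self.calibrated:
            # Leave-one-out raw scores: a training positive must not be
            # matched against its own index entry, or calibration sees
            # artificial 1.0 overlaps and lands its threshold far above
            # anything a held-out record can reach.
            raw = self._raw_scores(train, loo_positives=True)
            y = train["label"].to_numpy(dtype=int)
            if len(np.unique(y)) < 2:
                raise ValueError("calibration needs both classes in training")
            self._platt = LogisticRegression(C=1e3)
            self._platt.fit(raw.reshape(-1, 1), y)
            self._platt_per_pep = {}
            peps = train["peptide"].to_numpy()
            for pep in self._index:
                sel = peps == pep
                if sel.sum() < self.MIN_CALIBRATION_ROWS:
                    continue
                y_p = y[sel]
                if len(np.unique(y_p)) < 2:
                    continue
                lr = LogisticRegression(C=1e3)
                lr.fit(raw[sel].reshape(-1, 1), y_p)
                self._platt_per_pep[pep] = lr

    def _raw_one(self, cdr3b: str, peptide: str, skip_self: bool = False) -> float:
        binders = self._index.get(peptide)
        if binders is None:
            return 0.5
        q = _kmers(cdr3b, self.k)
        nq = sum(q.values())
        best = 0.0
        skipped = not skip_self
        for bm, nb, seq in binders:
            if not skipped and seq == cdr3b:
                skipped = True
                continue
            shared = sum(min(c, bm[m]) for m, c in q.items() if m in bm)
            denom = max(nq, nb)
            if denom and shared / denom > best:
                best = shared / denom
        return best

    def _raw_scores(self, records: pd.DataFrame,
                    loo_positives: bool = False) -> np.ndarray:
        if loo_positives:
            is_pos = (records["label"] == 1).to_numpy()
        else:
            is_pos = np.zeros(len(records), dtype=bool)
        return np.array(
            [self._raw_one(t, p, skip_self=sp)
             for t, p, sp in zip(records["cdr3_beta"], records["peptide"], is_pos)],
            dtype=float,
        )

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        raw = self._raw_scores(records)
        if not self.calibrated or self._platt is None:
            return raw
        out = self._platt.predict_proba(raw.reshape(-1, 1))[:, 1]
        peps = records["peptide"].to_numpy()
        for pep, lr in self._platt_per_pep.items():
            sel = peps == pep
            if sel.any():
                out[sel] = lr.predict_proba(raw[sel].reshape(-1, 1))[:, 1]
        unseen = ~records["peptide"].isin(self._index.keys()).to_numpy()
        out[unseen] = 0.5
        return out


class MemoryBaseline:
    """Scores 1.0 iff the exact (CDR3β, peptide) pair occurred as a
    training positive — pure memorization, useful to expose pair
    leakage between folds."""

    def __init__(self) -> None:
        self._pairs: set[tuple[str, str]] = set()

    def fit(self, train: pd.DataFrame) -> None:
        pos = train[train["label"] == 1]
        self._pairs = set(zip(pos["cdr3_beta"], pos["peptide"]))

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        return np.array(
            [1.0 if pair in self._pairs else 0.0
             for pair in zip(records["cdr3_beta"], records["peptide"])],
            dtype=float,
        )


class ConstantBaseline:
    """Returns one fixed score for every pair."""

    def __init__(self, value: float = 0.5) -> None:
        if not 0.0 <= value <= 1.0:
            raise ValueError("score must lie in [0, 1]")
        self.value = value

    def fit(self, train: pd.DataFrame) -> None:
        pass

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        return np.full(len(records), self.value)


class ExternalScoreBaseline:
    """Adapter for scores produced by an external tool (TITAN,
    NetTCR-2.0, ERGO, DLpTCR, ImRex, ...): reads a score column the
    tool wrote instead of computing anything."""

    def __init__(self, score_column: str = "score") -> None:
        self.score_column = score_column

    def fit(self, train: pd.DataFrame) -> None:
        pass

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        if self.score_column not in records.columns:
            raise ValueError(f"missing external score column {self.score_column!r}")
        s = records[self.score_column].to_numpy(dtype=float)
        if not np.isfinite(s).all() or (s < 0).any() or (s > 1).any():
            raise ValueError("external scores must be finite and in [0, 1]")
        return s


def baseline_peptide_frequency() -> PredictorContract:
    return PeptideFrequencyBaseline()


def baseline_kmer_nn(k: int = 3, calibrated: bool = False) -> PredictorContract:
    return KmerNNBaseline(k=k, calibrated=calibrated)


def baseline_memory() -> PredictorContract:
    return MemoryBaseline()


def baseline_constant(value: float = 0.5) -> PredictorContract:
    return ConstantBaseline(value)


def external_scores(score_column: str = "score") -> PredictorContract:
    return ExternalScoreBaseline(score_column)


PREDICTOR_FACTORIES: dict[str, Callable[[], PredictorContract]] = {
    "peptide_freq": baseline_peptide_frequency,
    "kmer_nn": baseline_kmer_nn,
    "kmer_nn_calibrated": lambda: baseline_kmer_nn(calibrated=True),
    "memory": baseline_memory,
    "constant": baseline_constant,
    "external": external_scores,
}


# --------------------------------------------------------------------
# cross-validation harness
# --------------------------------------------------------------------

@dataclass
class EvalResult:
    """Cross-validated performance of one predictor.

    per_fold: one row per fold with roc_auc, pr_auc, accuracy.
    summary: mean and sample sd of each metric over folds.
    per_peptide: accuracy per test peptide joined with that peptide's
    mean training-positive occurrence (the axes of frequency-vs-
    accuracy diagnostics).
    """

    per_fold: pd.DataFrame
    summary: dict[str, float]
    per_peptide: pd.DataFrame


def crossval_evaluate(
    table: pd.DataFrame,
    predictor_factory: Callable[[], PredictorContract],
    k: int | None = None,
    threshold: float = 0.5,
) -> EvalResult:
    """Run k-fold cross-validation of a predictor on a labeled table.

    ``table`` must carry columns cdr3_beta, peptide, label ∈ {0, 1}
    and fold (negatives already generated within folds).  For each
    fold f a fresh predictor is fitted on all folds ≠ f and scored on
    fold f.  The test rows are never part of the training frame
    (asserted by row identity).
    """
    for col in ("cdr3_beta", "peptide", "label", "fold"):
        if col not in table.columns:
            raise ValueError(f"evaluation table lacks column {col!r}")
    folds = sorted(int(f) for f in table.loc[table["fold"] >= 0, "fold"].unique())
    if k is not None and len(folds) != k:
        raise ValueError(f"expected {k} folds, table has {len(folds)}")

    rows = []
    pp_rows = []
    for f in folds:
        test = table[table["fold"] == f]
        train = table[(table["fold"] != f) & (table["fold"] >= 0)]
        if test["label"].nunique() < 2:
            raise ValueError(f"fold {f}: test set lacks one of the classes")
        overlap = test.index.intersection(train.index)
        assert overlap.empty, f"fold {f}: {len(overlap)} rows leak into training"
        predictor = predictor_factory()
        try:
            predictor.fit(train)
            scores = np.asarray(predictor.predict(test), dtype=float)
        except Exception as exc:
            raise RuntimeError(f"predictor failed on fold {f}: {exc}") from exc
        if scores.shape != (len(test),):
            raise RuntimeError(f"predictor returned wrong shape on fold {f}")
        y = test["label"].to_numpy(dtype=int)
        pred = (scores >= threshold).astype(int)
        rows.append({
            "fold": f,
            "roc_auc": roc_auc(scores, y),
            "pr_auc": pr_auc(scores, y),
            "accuracy": float((pred == y).mean()),
            "n_test": len(test),
        })
        train_occ = train[train["label"] == 1]["peptide"].value_counts()
        hits = pd.DataFrame({
            "peptide": test["peptide"].to_numpy(),
            "correct": (pred == y),
        })
        for pep, grp in hits.groupby("peptide"):
            pp_rows.append({
                "fold": f,
                "peptide": pep,
                "n_test": len(grp),
                "n_correct": int(grp["correct"].sum()),
                "train_occurrence": int(train_occ.get(pep, 0)),
            })

    per_fold = pd.DataFrame(rows)
    summary: dict[str, float] = {}
    for m in ("roc_auc", "pr_auc", "accuracy"):
        summary[f"{m}_mean"] = float(per_fold[m].mean())
        summary[f"{m}_sd"] = float(per_fold[m].std(ddof=1)) if len(per_fold) > 1 else 0.0

    pp = pd.DataFrame(pp_rows)
    per_peptide = (
        pp.groupby("peptide")
        .agg(n_test=("n_test", "sum"), n_correct=("n_correct", "sum"),
             train_occurrence=("train_occurrence", "mean"))
        .reset_index()
    )
    per_peptide["accuracy"] = per_peptide["n_correct"] / per_peptide["n_test"]
    per_peptide = per_peptide.sort_values(
        ["train_occurrence", "peptide"], ascending=[False, True]
    ).reset_index(drop=True)
    return EvalResult(per_fold=per_fold, summary=summary, per_peptide=per_peptide)
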