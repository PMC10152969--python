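"""Within-fold negative-pair generation by rearranging TCR-peptide pairs.

Benchmark datasets contain only observed (positive) binding pairs.
Non-binding examples are synthesized inside each cross-validation fold
by permuting the fold's peptide column over its TCRs: every negative
keeps a fold TCR and receives a peptide that TCR is not known to bind.
Because the peptide column is rearranged rather than resampled, the
negative peptide marginal mirrors the positive one, so peptide
frequency alone carries no label signal — the property that makes the
benchmark's imbalance diagnostics meaningful.

When rearrangement cannot place a peptide (e.g. one peptide dominates
the fold), TCRs removed during earlier downsampling steps — the
:class:`ReferencePool` — stand in as additional reference TCRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import NEGATIVE, SCHEMA_COLUMNS, Dataset, NegativeGenerationError, empty_frame

logger = logging.getLogger(__name__)


@dataclass
class NegativeGenParams:
    """Parameters of negative generation.

    ratio is (positive, negative): (1, 1) yields one negative per
    positive.  max_attempts bounds the rejection-resampling rounds of
    the peptide-column shuffle before the reference-pool fallback.
    """

    ratio: tuple[int, int] = (1, 1)
    max_attempts: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        pos, neg = self.ratio
        if pos <= 0 or neg <= 0:
            raise ValueError("ratio terms must be positive")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


@dataclass
class ReferencePool:
    """CDR3β sequences removed during downsampling, with their peptide
    of origin.  They re-enter only as negative-pair TCRs."""

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["cdr3_beta", "peptide"])
    )

    def __post_init__(self) -> None:
        self.df = self.df[["cdr3_beta", "peptide"]].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "ReferencePool":
        return cls(df=records[["cdr3_beta", "peptide"]].copy())

    @classmethod
    def merged(cls, pools: Iterable["ReferencePool"]) -> "ReferencePool":
        frames = [p.df for p in pools]
        if not frames:
            return cls()
        return cls(df=pd.concat(frames, ignore_index=True))


def _tcr_binding_map(known_positives: Iterable[tuple[str, str]]) -> dict[str, set[str]]:
    binds: dict[str, set[str]] = {}
    for tcr, pep in known_positives:
        binds.setdefault(tcr, set()).add(pep)
    return binds


def generate_negatives(
    fold_records: pd.DataFrame,
    known_positives: set[tuple[str, str]],
    params: NegativeGenParams,
    pool: ReferencePool | None = None,
) -> pd.DataFrame:
    """Create non-binding pairs for one fold.

    Each negative pairs a fold TCR with a peptide from the fold's own
    peptide multiset such that (a) the peptide differs from every
    peptide that TCR binds anywhere in ``known_positives``, (b) the
    pair is not itself a known positive, and (c) the pair has not
    already been generated.  Pairing is a seeded shuffle of the fold's
    peptide column with rejection-resampling (up to ``max_attempts``
    rounds); positives still unmatched are completed by drawing TCRs
    from the reference ``pool`` for the leftover peptides.

    Raises
    ------
    NegativeGenerationError
        If the fold has fewer than two distinct peptides, or the
        requested count cannot be reached even with the pool.
    """
    n_pep = fold_records["peptide"].nunique()
    if n_pep < 2:
        raise NegativeGenerationError(
            f"fold has {n_pep} distinct peptide(s); rearrangement needs >= 2"
        )
    pos, neg = params.ratio
    n_slots = (len(fold_records) * neg) // pos
    rng = np.random.default_rng(params.seed)
    binds = _tcr_binding_map(known_positives)
    # A positive row may be absent from known_positives only by caller
    # error; guard anyway so constraint (a) is never vacuous.
    for tcr, pep in zip(fold_records["cdr3_beta"], fold_records["peptide"]):
        binds.setdefault(tcr, set()).add(pep)

    reps = int(np.ceil(n_slots / len(fold_records)))
    tcrs = list(fold_records["cdr3_beta"]) * reps
    peps = list(fold_records["peptide"]) * reps
    tcrs, peps = tcrs[:n_slots], peps[:n_slots]

    assigned: dict[int, str] = {}
    used_pairs: set[tuple[str, str]] = set()
    pending_slots = list(range(n_slots))
    pending_peps = list(peps)
    for _ in range(params.max_attempts):
        if not pending_slots:
            break
        order = rng.permutation(len(pending_peps))
        shuffled = [pending_peps[i] for i in order]
        next_slots: list[int] = []
        next_peps: list[str] = []
        for slot, pep in zip(pending_slots, shuffled):
            tcr = tcrs[slot]
            if pep not in binds[tcr] and (tcr, pep) not in used_pairs:
                assigned[slot] = pep
                used_pairs.add((tcr, pep))
            else:
                next_slots.append(slot)
                next_peps.append(pep)
        pending_slots, pending_peps = next_slots, next_peps

    if pending_slots:
        # End-game repair: a leftover peptide may be invalid for every
        # pending TCR while an already-assigned slot could legally take
        # it in exchange — swap instead of giving up on rearrangement.
        still: list[tuple[int, str]] = []
        for slot, pep in zip(pending_slots, pending_peps):
            tcr = tcrs[slot]
            done = False
            others = rng.permutation(sorted(assigned))
            for j in others:
                q, tcr_j = assigned[j], tcrs[j]
                if (
                    q not in binds[tcr]
                    and (tcr, q) not in used_pairs
                    and pep not in binds[tcr_j]
                    and (tcr_j, pep) not in used_pairs
                ):
                    used_pairs.discard((tcr_j, q))
                    assigned[j] = pep
                    used_pairs.add((tcr_j, pep))
                    assigned[slot] = q
                    used_pairs.add((tcr, q))
                    done = True
                    break
            if not done:
                still.append((slot, pep))
        pending_slots = [s for s, _ in still]
        pending_peps = [p for _, p in still]

    if pending_slots:
        pool_df = pool.df if pool is not None else pd.DataFrame(columns=["cdr3_beta"])
        pool_tcrs = list(pool_df["cdr3_beta"])
        unmatched = []
        for slot, pep in zip(pending_slots, pending_peps):
            candidates = [
                t for t in pool_tcrs
                if pep not in binds.get(t, ()) and (t, pep) not in used_pairs
            ]
            if not candidates:
                unmatched.append((slot, pep))
                continue
            tcr = candidates[int(rng.integers(len(candidates)))]
            tcrs[slot] = tcr
            assigned[slot] = pep
            used_pairs.add((tcr, pep))
        if unmatched:
            raise NegativeGenerationError(
                f"{len(unmatched)} negatives could not be generated even with the "
                f"reference pool (degenerate fold; first leftover peptide "
                f"{unmatched[0][1]!r})"
            )
        logger.info("generate_negatives: %d/%d negatives drawn from reference pool",
                    len(pending_slots) - len(unmatched), n_slots)

    out = pd.DataFrame(
        {
            "cdr3_alpha": "",
            "cdr3_beta": [tcrs[i] for i in range(n_slots)],
            "peptide": [assigned[i] for i in range(n_slots)],
            "mhc": "",
            "source": "shuffled_negative",
            "label": NEGATIVE,
        }
    )
    if "fold" in fold_records.columns and len(fold_records):
        out["fold"] = int(fold_records["fold"].iloc[0])
    return out


def assemble_fold_table(
    positives: pd.DataFrame, negatives: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Concatenate positives and their generated negatives into one
    seeded-shuffled, labeled fold table."""
    if negatives is None or len(negatives) == 0:
        table = positives.copy()
    else:
        table = pd.concat([positives, negatives], ignore_index=True)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(table))
    return table.iloc[order].reset_index(drop=True)


def generate_for_folds(
    dataset: Dataset,
    fold_of: Mapping | pd.Series,
    params: NegativeGenParams,
    pool: ReferencePool | None = None,
) -> pd.DataFrame:
    """Generate negatives fold by fold and return the full labeled table.

    ``fold_of`` maps the dataset's row index to fold indices (−1 =
    excluded).  Negatives are generated strictly within folds; the
    exclusion set is ``known_positives`` of the *whole* dataset, which
    is stronger than fold-local exclusion and strictly safer.
    """
    fold_of = pd.Series(fold_of)
    df = dataset.df.copy()
    df["fold"] = fold_of.reindex(df.index).astype(int)
    known = set(zip(df["cdr3_beta"], df["peptide"]))
    tables = []
    for f in sorted(df.loc[df["fold"] >= 0, "fold"].unique()):
        fold_pos = df[df["fold"] == f]
        fold_params = NegativeGenParams(
            ratio=params.ratio,
            max_attempts=params.max_attempts,
            seed=params.seed + int(f),
        )
        negs = generate_negatives(fold_pos, known, fold_params, pool=pool)
        tables.append(assemble_fold_table(fold_pos, negs, seed=fold_params.seed))
    if not tables:
        out = empty_frame()
        out["fold"] = pd.Series(dtype=int)
        return out
    return pd.concat(tables, ignore_index=True)
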