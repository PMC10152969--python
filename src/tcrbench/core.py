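"""Core containers and constants for TCR-pMHC binding data.

The canonical in-memory representation of binding data is a pandas
DataFrame with the unified column set :data:`SCHEMA_COLUMNS`.  Absent
fields (a missing chain, an unknown MHC allele) are empty strings, so
frames round-trip losslessly through TSV.  :class:`Dataset` wraps such
a frame together with a name and a construction-provenance record;
:class:`BindingRecord` is a lightweight row view for code that prefers
tuples over frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Unified column order of every table the pipeline reads or writes.
SCHEMA_COLUMNS = ["cdr3_alpha", "cdr3_beta", "peptide", "mhc", "source", "label"]

#: Label values: harmonized observations are positives; negatives are
#: produced only by :mod:`tcrbench.negatives`.
POSITIVE = 1
NEGATIVE = 0


class SchemaError(ValueError):
    """A resource table does not satisfy its declared schema map."""


class SplitError(ValueError):
    """A fold partition cannot be constructed or fails validation."""


class NegativeGenerationError(RuntimeError):
    """Negative-pair generation could not satisfy the requested ratio."""


class ConfigError(ValueError):
    """A run configuration is malformed."""


class BindingRecord(NamedTuple):
    """One TCR-pMHC observation. Empty string means absent."""

    cdr3_alpha: str
    cdr3_beta: str
    peptide: str
    mhc: str
    source: str
    label: int = POSITIVE


def records_to_frame(records: Iterable[BindingRecord]) -> pd.DataFrame:
    """Build a unified-schema frame from an iterable of records."""
    df = pd.DataFrame(list(records), columns=SCHEMA_COLUMNS)
    if df.empty:
        df = empty_frame()
    return _normalize_dtypes(df)


def frame_to_records(df: pd.DataFrame) -> list[BindingRecord]:
    return [BindingRecord(*row) for row in df[SCHEMA_COLUMNS].itertuples(index=False)]


def empty_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in SCHEMA_COLUMNS})
    df["label"] = df["label"].astype(int)
    return df


def _normalize_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("cdr3_alpha", "cdr3_beta", "peptide", "mhc", "source"):
        df[col] = df[col].fillna("").astype(str)
    df["label"] = df["label"].astype(int)
    return df


@dataclass
class Dataset:
    """An ordered, deduplicated collection of binding records.

    Parameters
    ----------
    df
        Frame with at least :data:`SCHEMA_COLUMNS`.  Row order is
        meaningful: downstream seeded sampling iterates in frame order,
        so two datasets with the same rows in different order are not
        interchangeable.
    name
        Dataset identity, e.g. ``"tpp"``, ``"base"``, ``"balanced"``.
    provenance
        Construction parameters (filters applied, seed, parent name).
    """

    df: pd.DataFrame
    name: str = "dataset"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SCHEMA_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset frame lacks columns: {missing}")
        self.df = _normalize_dtypes(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def peptides(self) -> pd.Series:
        return self.df["peptide"]

    def peptide_counts(self) -> pd.Series:
        """Per-peptide record counts, sorted count-descending then
        peptide-lexicographic (the deterministic tie-break used
        throughout)."""
        counts = self.df.groupby("peptide").size()
        return counts.sort_index().sort_values(ascending=False, kind="stable")

    def to_tsv(self, path: str | Path) -> None:
        extra = [c for c in self.df.columns if c not in SCHEMA_COLUMNS]
        self.df[SCHEMA_COLUMNS + extra].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "dataset",
                 provenance: dict | None = None) -> "Dataset":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if "label" in df.columns:
            df["label"] = df["label"].astype(int)
        else:
            df["label"] = POSITIVE
        if "fold" in df.columns:
            df["fold"] = df["fold"].astype(int)
        return cls(df=df, name=name, provenance=provenance or {})
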