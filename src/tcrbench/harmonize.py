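"""Harmonization of heterogeneous TCR-pMHC resource exports.

Public binding resources (VDJdb, IEDB, McPAS-TCR, ImmuneCODE, TBAdb,
10X exports) ship delimited tables with incompatible column names.  A
:class:`SchemaMap` declares, per resource, how its columns map onto the
unified schema; :func:`read_resource` applies it, :func:`qc_filter`
enforces the canonical amino-acid alphabet, and :func:`merge_dedup`
concatenates all resources into one deduplicated dataset (the "tpp"
dataset) from which every benchmark variant is derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
import yaml

from .core import (
    CANONICAL_AA,
    POSITIVE,
    SCHEMA_COLUMNS,
    Dataset,
    SchemaError,
    _normalize_dtypes,
)

logger = logging.getLogger(__name__)

#: Unified field names a SchemaMap may map onto.
MAPPABLE_FIELDS = ("cdr3_alpha", "cdr3_beta", "peptide", "mhc")

#: Deduplication key of the merged tpp dataset: the full observation
#: tuple, the most conservative reading of "duplicates were removed".
TPP_DEDUP_KEY = ["cdr3_alpha", "cdr3_beta", "peptide", "mhc"]


@dataclass
class SchemaMap:
    """Column-mapping description of one resource dialect.

    ``column_map`` maps resource column names to unified field names
    (values drawn from :data:`MAPPABLE_FIELDS`).  ``header_rows`` is the
    number of leading lines before the data; the last of them is the
    column-name header, so the default 1 means a plain headed table.
    """

    resource_id: str
    column_map: dict[str, str] = field(default_factory=dict)
    delimiter: str = "\t"
    header_rows: int = 1

    def __post_init__(self) -> None:
        if not self.resource_id:
            raise SchemaError("resource_id must be non-empty")
        if self.header_rows < 1:
            raise SchemaError("header_rows must be >= 1 (name-keyed column_map)")
        bad = [v for v in self.column_map.values() if v not in MAPPABLE_FIELDS]
        if bad:
            raise SchemaError(f"{self.resource_id}: unknown unified fields {bad}")
        mapped = set(self.column_map.values())
        if "peptide" not in mapped:
            raise SchemaError(f"{self.resource_id}: no column mapped to peptide")
        if not mapped & {"cdr3_alpha", "cdr3_beta"}:
            raise SchemaError(f"{self.resource_id}: no chain column mapped")


def load_schema_maps(path: str | Path) -> list[SchemaMap]:
    """Load SchemaMaps from a YAML config (a list of resource blocks)."""
    with open(path) as fh:
        blocks = yaml.safe_load(fh)
    if not isinstance(blocks, list):
        raise SchemaError("schema config must be a list of resource blocks")
    return [SchemaMap(**block) for block in blocks]


def example_schema_config_path() -> Path:
    """Path of the bundled example SchemaMap config covering the six
    common public resources (VDJdb, IEDB, McPAS-TCR, ImmuneCODE,
    TBAdb, 10X)."""
    return Path(__file__).parent / "data" / "resource_schemas.yaml"


def example_schema_maps() -> list[SchemaMap]:
    return load_schema_maps(example_schema_config_path())


def read_resource(path: str | Path, schema: SchemaMap) -> pd.DataFrame:
    """Read one resource table and unify it to the common schema.

    Rows lacking a peptide, or lacking both CDR3 chains, are dropped
    (only entries with a peptide and at least one of CDR3 TRA / TRB are
    kept); the drop count is logged.
    """
    try:
        df = pd.read_csv(
            path,
            sep=schema.delimiter,
            skiprows=schema.header_rows - 1,
            dtype=str,
            keep_default_na=False,
        )
    except OSError as exc:
        raise OSError(f"cannot read resource table {path}: {exc}") from exc
    missing = [c for c in schema.column_map if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema.resource_id}: mapped columns absent from {path}: {missing}"
        )
    out = pd.DataFrame(index=df.index)
    for src_col, dst_col in schema.column_map.items():
        out[dst_col] = df[src_col]
    for fld in MAPPABLE_FIELDS:
        if fld not in out.columns:
            out[fld] = ""
    out["source"] = schema.resource_id
    out["label"] = POSITIVE
    out = _normalize_dtypes(out[SCHEMA_COLUMNS])

    stripped = out[["cdr3_alpha", "cdr3_beta", "peptide"]].apply(
        lambda s: s.str.strip()
    )
    keep = (stripped["peptide"] != "") & (
        (stripped["cdr3_alpha"] != "") | (stripped["cdr3_beta"] != "")
    )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "%s: dropped %d/%d rows without peptide or without any CDR3 chain",
            schema.resource_id, n_drop, len(out),
        )
    return out[keep].reset_index(drop=True)


def _valid_seq(s: pd.Series, allow_empty: bool) -> pd.Series:
    pat = f"^[{''.join(sorted(CANONICAL_AA))}]+$"
    ok = s.str.fullmatch(pat).fillna(False)
    if allow_empty:
        ok |= s == ""
    return ok


def qc_filter(records: pd.DataFrame) -> pd.DataFrame:
    """Keep only records whose peptide and every present chain use the
    20 canonical amino-acid letters.

    Sequences are whitespace-stripped and uppercased first (resource
    exports vary in case); order is preserved.  Filtering never fails.
    """
    df = records.copy()
    for col in ("cdr3_alpha", "cdr3_beta", "peptide"):
        df[col] = df[col].str.strip().str.upper()
    df["mhc"] = df["mhc"].str.strip()
    keep = (
        _valid_seq(df["peptide"], allow_empty=False)
        & _valid_seq(df["cdr3_alpha"], allow_empty=True)
        & _valid_seq(df["cdr3_beta"], allow_empty=True)
        & ((df["cdr3_alpha"] != "") | (df["cdr3_beta"] != ""))
    )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("qc_filter: removed %d/%d records with non-canonical residues",
                    n_drop, len(df))
    return df[keep].reset_index(drop=True)


def merge_dedup(record_sets: Sequence[pd.DataFrame], name: str = "tpp") -> Dataset:
    """Concatenate quality-controlled resource frames and deduplicate.

    Resources are concatenated in the given order; duplicates under the
    key (cdr3_alpha, cdr3_beta, peptide, mhc) keep the first occurrence,
    so a shared entry is attributed to the earlier resource.
    """
    if not record_sets:
        raise ValueError("merge_dedup requires at least one record set")
    merged = pd.concat(list(record_sets), ignore_index=True)
    n_before = len(merged)
    merged = merged.drop_duplicates(subset=TPP_DEDUP_KEY, keep="first")
    merged = merged.reset_index(drop=True)
    logger.info("merge_dedup: %d records merged, %d after deduplication",
                n_before, len(merged))
    return Dataset(
        df=merged,
        name=name,
        provenance={
            "operation": "merge_dedup",
            "dedup_key": TPP_DEDUP_KEY,
            "n_input": n_before,
            "n_output": len(merged),
            "sources": [str(s) for s in merged["source"].unique()],
        },
    )


class ChainCounts(NamedTuple):
    """Chain availability of a dataset; fields sum to the dataset size."""

    paired: int
    alpha_only: int
    beta_only: int


def chain_availability_summary(dataset: Dataset) -> ChainCounts:
    """Count records with paired chains, only an α chain, or only a β chain."""
    has_a = dataset.df["cdr3_alpha"] != ""
    has_b = dataset.df["cdr3_beta"] != ""
    return ChainCounts(
        paired=int((has_a & has_b).sum()),
        alpha_only=int((has_a & ~has_b).sum()),
        beta_only=int((~has_a & has_b).sum()),
    )


def harmonize_resources(
    tables: Iterable[tuple[str | Path, SchemaMap]], name: str = "tpp"
) -> Dataset:
    """Full harmonization: read, QC, and merge a set of resource tables."""
    frames = [qc_filter(read_resource(path, schema)) for path, schema in tables]
    return merge_dedup(frames, name=name)
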