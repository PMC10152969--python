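"""Construction of the benchmark dataset variants from the merged data.

From the harmonized "tpp" dataset three variants are derived:

``base``
    CDR3β present with length 10–18, 9-mer peptide, HLA-A*02-presented,
    deduplicated on (CDR3β, peptide).  The common denominator that all
    compared predictors can consume.
``balanced``
    base with rare peptides (< ``min_examples_per_peptide`` positives)
    removed and frequent peptides downsampled to ``downsample_cap``
    examples, so every peptide contributes 5–10 records by default.
``imbalanced``
    as balanced, except the single most frequent peptide keeps *all*
    its records — isolating the effect of peptide imbalance from the
    effect of dataset size.

Records removed by downsampling are not discarded: their CDR3β
sequences feed the reference pool used as fallback TCRs during
negative generation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import Dataset
from .negatives import ReferencePool

logger = logging.getLogger(__name__)

#: Dedup key of the base dataset (stricter than the tpp key: one
#: observation per receptor-peptide pair regardless of allele detail).
BASE_DEDUP_KEY = ["cdr3_beta", "peptide"]


@dataclass
class BuildParams:
    """Filtering and downsampling parameters of the dataset builders."""

    min_examples_per_peptide: int = 5
    downsample_cap: int = 10
    peptide_length: int = 9
    cdr3b_length_range: tuple[int, int] = (10, 18)
    mhc_prefix: str = "HLA-A*02"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_examples_per_peptide > self.downsample_cap:
            raise ValueError("min_examples_per_peptide must be <= downsample_cap")
        lo, hi = self.cdr3b_length_range
        if lo <= 0 or hi < lo or self.peptide_length <= 0:
            raise ValueError("length bounds must be positive and ordered")


_MHC_STARRED_RE = re.compile(r"^HLA-([A-Z0-9]+)\*([0-9]+)(.*)$")
# Without the separator only a letters-only gene is unambiguous
# ("HLA-A2", "HLA-A02:01"); digit-bearing genes require the star.
_MHC_LEGACY_RE = re.compile(r"^HLA-([A-Z]+)([0-9]+)(.*)$")


def normalize_mhc_allele(allele: str) -> str:
    """Normalize an MHC class I allele string for prefix matching.

    Resources encode alleles at different resolutions and in legacy
    styles ("HLA-A2", "HLA-A*02", "HLA-A*02:01").  Uppercase, insert
    the ``*`` separator where omitted, and zero-pad a bare single-digit
    group ("HLA-A2" → "HLA-A*02").  Unparseable strings are returned
    stripped/uppercased, unmodified otherwise.
    """
    s = allele.strip().upper()
    m = _MHC_STARRED_RE.match(s) or _MHC_LEGACY_RE.match(s)
    if not m:
        return s
    gene, group, rest = m.groups()
    if len(group) == 1:
        group = "0" + group
    return f"HLA-{gene}*{group}{rest}"


def build_base(tpp: Dataset, params: BuildParams | None = None) -> Dataset:
    """Apply the base-dataset criteria and deduplicate on (CDR3β, peptide).

    Criteria: 9-mer peptide; present CDR3β of length 10–18; MHC allele
    in the HLA-A*02 group (records without any MHC annotation cannot be
    verified and are excluded).  First occurrence wins deduplication.
    """
    params = params or BuildParams()
    df = tpp.df
    lo, hi = params.cdr3b_length_range
    beta_len = df["cdr3_beta"].str.len()
    mhc_norm = df["mhc"].map(normalize_mhc_allele)
    crit_pep = df["peptide"].str.len() == params.peptide_length
    crit_beta = (df["cdr3_beta"] != "") & beta_len.between(lo, hi)
    crit_mhc = mhc_norm.str.startswith(params.mhc_prefix)
    kept = df[crit_pep & crit_beta & crit_mhc]
    n_filtered = len(kept)
    kept = kept.drop_duplicates(subset=BASE_DEDUP_KEY, keep="first")
    logger.info(
        "build_base: %d -> %d after criteria (no-mhc excluded: %d) -> %d after dedup",
        len(df), n_filtered, int((df["mhc"].str.strip() == "").sum()), len(kept),
    )
    return Dataset(
        df=kept.reset_index(drop=True),
        name="base",
        provenance={
            "parent": tpp.name,
            "criteria": {
                "peptide_length": params.peptide_length,
                "cdr3b_length_range": list(params.cdr3b_length_range),
                "mhc_prefix": params.mhc_prefix,
            },
            "dedup_key": BASE_DEDUP_KEY,
            "n_input": len(df),
            "n_output": len(kept),
        },
    )


class PeptideSummary(NamedTuple):
    """Peptide-frequency summary of a dataset.

    ``table`` has columns peptide, count, rank (1-based; count
    descending, peptide lexicographic on ties).  ``top_share`` is the
    percentage of records carried by the ``top_n`` most frequent
    peptides, rounded to two decimals.
    """

    table: pd.DataFrame
    n_unique_peptides: int
    n_records: int
    top_n: int
    top_count: int
    top_share: float


def peptide_summary(dataset: Dataset, top_n: int = 20) -> PeptideSummary:
    """Count records per peptide and the share of the top-N peptides."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if len(dataset) == 0:
        raise ValueError("peptide_summary requires a non-empty dataset")
    counts = dataset.peptide_counts()
    table = counts.rename("count").reset_index()
    table["rank"] = np.arange(1, len(table) + 1)
    top_count = int(table["count"].iloc[:top_n].sum())
    share = round(100.0 * top_count / len(dataset), 2)
    return PeptideSummary(
        table=table,
        n_unique_peptides=len(table),
        n_records=len(dataset),
        top_n=top_n,
        top_count=top_count,
        top_share=share,
    )


def _filter_and_downsample(
    base: Dataset, params: BuildParams, exempt: str | None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shared core of the balanced/imbalanced builders.

    Returns (kept, removed-by-downsampling).  Peptides below the
    minimum are removed entirely (and do NOT enter the pool — they were
    filtered, not downsampled); peptides above the cap are reduced to
    exactly the cap, uniformly without replacement under one
    dataset-level seed.  ``exempt`` names a peptide exempt from both
    rules.
    """
    counts = base.peptide_counts()
    kept_parts: list[pd.DataFrame] = []
    pool_parts: list[pd.DataFrame] = []
    # Each peptide draws from its own rng keyed by (seed, frequency
    # rank), so the picks for a given peptide do not depend on which
    # other peptides were downsampled — the imbalanced build then
    # matches the balanced build exactly on non-exempt peptides.
    for rank, (pep, n) in enumerate(counts.items()):
        grp = base.df[base.df["peptide"] == pep]
        if pep == exempt:
            kept_parts.append(grp)
            continue
        if n < params.min_examples_per_peptide:
            continue
        if n > params.downsample_cap:
            rng = np.random.default_rng(
                np.random.SeedSequence(params.seed, spawn_key=(rank,))
            )
            pick = rng.choice(n, size=params.downsample_cap, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[pick] = True
            kept_parts.append(grp[mask])
            pool_parts.append(grp[~mask])
        else:
            kept_parts.append(grp)
    kept = (
        pd.concat(kept_parts).sort_index().reset_index(drop=True)
        if kept_parts else base.df.iloc[0:0].copy()
    )
    removed = (
        pd.concat(pool_parts).sort_index().reset_index(drop=True)
        if pool_parts else base.df.iloc[0:0].copy()
    )
    return kept, removed


def build_balanced(
    base: Dataset, params: BuildParams | None = None
) -> tuple[Dataset, ReferencePool]:
    """Build the balanced variant: every peptide contributes between
    ``min_examples_per_peptide`` and ``downsample_cap`` records.

    Returns the dataset and the reference pool of downsampled-away
    records (fallback TCRs for negative generation).
    """
    params = params or BuildParams()
    kept, removed = _filter_and_downsample(base, params, exempt=None)
    ds = Dataset(
        df=kept,
        name="balanced",
        provenance={
            "parent": base.name,
            "min_examples_per_peptide": params.min_examples_per_peptide,
            "downsample_cap": params.downsample_cap,
            "seed": params.seed,
            "n_input": len(base),
            "n_output": len(kept),
        },
    )
    return ds, ReferencePool.from_records(removed)


def build_imbalanced(
    base: Dataset, params: BuildParams | None = None
) -> tuple[Dataset, ReferencePool]:
    """Build the imbalanced variant: the most frequent peptide (mfp)
    keeps all its records; every other peptide is treated as in the
    balanced build.  Ties on the maximal count break lexicographically.
    """
    params = params or BuildParams()
    if len(base) == 0:
        raise ValueError("build_imbalanced requires a non-empty base dataset")
    mfp = str(base.peptide_counts().index[0])
    kept, removed = _filter_and_downsample(base, params, exempt=mfp)
    ds = Dataset(
        df=kept,
        name="imbalanced",
        provenance={
            "parent": base.name,
            "mfp": mfp,
            "min_examples_per_peptide": params.min_examples_per_peptide,
            "downsample_cap": params.downsample_cap,
            "seed": params.seed,
            "n_input": len(base),
            "n_output": len(kept),
        },
    )
    return ds, ReferencePool.from_records(removed)
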