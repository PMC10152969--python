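"""Synthetic TCR-pMHC tables with controlled statistical structure.

Real repertoire-binding collections are dominated by a handful of
heavily screened peptides; here peptide frequencies follow a truncated
Zipf law with a tunable exponent (0 = uniform).  CDR3β sequences are
random strings over the 20 canonical amino acids, length-uniform in
the base dataset's admissible range, optionally framed by the
conserved leading cysteine / trailing phenylalanine.  An optional
per-peptide binding motif — a short subsequence spliced into a
positive record's CDR3β with probability ``motif_strength`` — plants a
learnable, peptide-conditional signal whose ground truth is returned
alongside the table.  Only positive pairs are generated; negatives
always flow through :mod:`tcrbench.negatives`, exactly as for real
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import POSITIVE, SCHEMA_COLUMNS, Dataset

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SynthParams:
    """Generator parameters.

    zipf_exponent s ≥ 0 sets the peptide rank-frequency law
    p(rank r) ∝ r^−s (s = 0 uniform).  motif_strength is the
    probability that a positive record's CDR3β contains its peptide's
    motif.  frame adds the conventional C...F flanks.
    """

    n_peptides: int = 20
    n_records: int = 1000
    zipf_exponent: float = 1.0
    peptide_length: int = 9
    cdr3b_length_range: tuple[int, int] = (10, 18)
    motif_length: int = 3
    motif_strength: float = 0.5
    frame: bool = True
    mhc: str = "HLA-A*02:01"
    source: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides < 1 or self.n_records < self.n_peptides:
            raise ValueError("need n_records >= n_peptides >= 1")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must lie in [0, 1]")
        lo, hi = self.cdr3b_length_range
        interior = lo - 2 if self.frame else lo
        if self.motif_length > interior:
            raise ValueError(
                f"motif of length {self.motif_length} does not fit the shortest "
                f"CDR3β ({'framed ' if self.frame else ''}length {lo})"
            )


@dataclass
class GroundTruth:
    """Planted signal of a synthetic table: peptide → motif, and a
    per-record flag of whether the motif was actually spliced in."""

    motifs: dict[str, str]
    motif_present: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))


def zipf_weights(n: int, exponent: float) -> np.ndarray:
    """Truncated-Zipf rank probabilities p(r) ∝ r^−s, r = 1..n."""
    w = np.arange(1, n + 1, dtype=float) ** -exponent
    return w / w.sum()


def _random_seqs(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n distinct random sequences of the given length."""
    seqs: set[str] = set()
    while len(seqs) < n:
        block = rng.choice(AA, size=(n - len(seqs), length))
        seqs.update("".join(row) for row in block)
    return sorted(seqs)[:n]


def generate_positive_table(params: SynthParams) -> tuple[Dataset, GroundTruth]:
    """Generate a positive-only synthetic binding table.

    Deterministic under ``params.seed``; byte-identical tables for
    identical parameters.
    """
    rng = np.random.default_rng(params.seed)
    peptides = _random_seqs(rng, params.n_peptides, params.peptide_length)
    rng.shuffle(peptides)  # decouple rank from lexicographic order
    motifs = dict(zip(peptides, _random_seqs(rng, params.n_peptides,
                                             params.motif_length)))
    weights = zipf_weights(params.n_peptides, params.zipf_exponent)
    pep_idx = rng.choice(params.n_peptides, size=params.n_records, p=weights)

    lo, hi = params.cdr3b_length_range
    lengths = rng.integers(lo, hi + 1, size=params.n_records)
    plant = rng.random(params.n_records) < params.motif_strength

    cdr3s: list[str] = []
    for i in range(params.n_records):
        L = int(lengths[i])
        chars = rng.choice(AA, size=L)
        if params.frame:
            chars[0], chars[-1] = "C", "F"
        if plant[i]:
            motif = motifs[peptides[pep_idx[i]]]
            start_lo = 1 if params.frame else 0
            start_hi = L - params.motif_length - (1 if params.frame else 0)
            pos = int(rng.integers(start_lo, start_hi + 1))
            chars[pos:pos + params.motif_length] = list(motif)
        cdr3s.append("".join(chars))

    df = pd.DataFrame({
        "cdr3_alpha": "",
        "cdr3_beta": cdr3s,
        "peptide": [peptides[j] for j in pep_idx],
        "mhc": params.mhc,
        "source": params.source,
        "label": POSITIVE,
    })[SCHEMA_COLUMNS]
    ds = Dataset(df=df, name="synthetic", provenance={
        "generator": "tcrbench.synthetic",
        "n_peptides": params.n_peptides,
        "n_records": params.n_records,
        "zipf_exponent": params.zipf_exponent,
        "motif_strength": params.motif_strength,
        "motif_length": params.motif_length,
        "seed": params.seed,
    })
    truth = GroundTruth(motifs=motifs,
                        motif_present=pd.Series(plant, index=df.index))
    return ds, truth


def summarize_imbalance(dataset: Dataset, top_n: int = 20) -> tuple[float, float]:
    """(top-N peptide share in percent, balance statistic) of a dataset."""
    from .dataset_builder import peptide_summary
    from .evaluation import dataset_balance

    summ = peptide_summary(dataset, top_n=top_n)
    rep = dataset_balance(dataset)
    return summ.top_share, rep.balance
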