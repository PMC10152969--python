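import pandas as pd
import pytest

from tcrbench.core import Dataset, records_to_frame, BindingRecord


def rec(cdr3_beta="CASSLAPGATNEKLFF", peptide="NLVPMVATV", cdr3_alpha="",
        mhc="HLA-A*02:01", source="res1", label=1) -> BindingRecord:
    """Binding record with sensible defaults for terse test tables."""
    return BindingRecord(cdr3_alpha=cdr3_alpha, cdr3_beta=cdr3_beta,
                         peptide=peptide, mhc=mhc, source=source, label=label)


@pytest.fixture
def make_dataset():
    def _make(records, name="test", provenance=None) -> Dataset:
        return Dataset(df=records_to_frame(records), name=name,
                       provenance=provenance or {})
    return _make


@pytest.fixture
def counts_dataset(make_dataset):
    """Dataset with an exact per-peptide count profile.

    Peptides are synthesized as distinct 9-mers; CDR3β strings are
    distinct 12-mers so no dedup key collides.
    """
    def _make(counts: dict[str, int] | list[int], **rec_kwargs) -> Dataset:
        if isinstance(counts, list):
            aa = "ACDEFGHIKLMNPQRSTVWY"
            counts = {
                aa[(i // 8000) % 20] + aa[(i // 400) % 20]
                + aa[(i // 20) % 20] + aa[i % 20] + "PPPPP": n
                for i, n in enumerate(counts)
            }
        records = []
        i = 0
        for pep, n in counts.items():
            assert len(pep) == 9
            for _ in range(n):
                beta = f"CASS{i:08d}".replace("0", "G").replace("1", "A") \
                    .replace("2", "S").replace("3", "T").replace("4", "V") \
                    .replace("5", "L").replace("6", "I").replace("7", "P") \
                    .replace("8", "E").replace("9", "K")
                records.append(rec(cdr3_beta=beta, peptide=pep, **rec_kwargs))
                i += 1
        return Dataset(df=records_to_frame(records), name="counts")
    return _make
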