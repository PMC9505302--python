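import numpy as np
import pandas as pd
import pytest

from repgvhd.tables import COLUMNS, ClonotypeTable


def make_table(counts, sample_id="s", seed=0, **meta) -> ClonotypeTable:
    """Build a table with given counts and distinct synthetic clonotypes."""
    counts = np.asarray(counts, dtype=np.int64)
    n = len(counts)
    # unique CDR3s: "TGT" + base-4 encoding of the clone index
    def enc(i):
        s = ""
        for _ in range(8):
            s += "ACGT"[i % 4]
            i //= 4
        return "TGT" + s
    nts = [enc(i) for i in range(n)]
    df = pd.DataFrame({
        "count": counts,
        "freq": 0.0,
        "cdr3nt": nts,
        "cdr3aa": [s[:6] for s in nts],
        "v": [f"TRBV{i % 7 + 1}" for i in range(n)],
        "d": ".",
        "j": [f"TRBJ1-{i % 5 + 1}" for i in range(n)],
    })[COLUMNS]
    return ClonotypeTable(sample_id=sample_id, data=df, **meta)


@pytest.fixture
def uniform100():
    return make_table([10] * 100)


@pytest.fixture
def table_50_30_20():
    return make_table([50, 30, 20])


@pytest.fixture
def single_clone():
    return make_table([1234])


def write_vdjtools(path, counts, freqs=None):
    """Write a minimal VDJtools-style TSV for IO tests."""
    n = len(counts)
    total = sum(counts) or 1
    freqs = [c / total for c in counts] if freqs is None else freqs
    df = pd.DataFrame({
        "count": counts,
        "freq": freqs,
        "cdr3nt": [f"TGTGC{'ACGT'[i % 4]}" + "AAA" * (i % 3 + 1) for i in range(n)],
        "cdr3aa": [f"CA{'FWYS'[i % 4]}" for i in range(n)],
        "v": [f"TRBV{i + 1}" for i in range(n)],
        "d": ".",
        "j": [f"TRBJ1-{i % 5 + 1}" for i in range(n)],
    })
    df.to_csv(path, sep="\t", index=False)
    return path
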