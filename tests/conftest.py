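import numpy as np
import pandas as pd
import pytest

from rrntraits import OtuTable, RrnLookup


def make_table(counts, otu_ids=None, sample_ids=None, meta=None):
    counts = np.asarray(counts)
    otu_ids = otu_ids or [f"otu{i}" for i in range(1, counts.shape[0] + 1)]
    sample_ids = sample_ids or [f"s{j}" for j in range(1, counts.shape[1] + 1)]
    df = pd.DataFrame(counts, index=otu_ids, columns=sample_ids)
    meta_df = None
    if meta is not None:
        meta_df = pd.DataFrame(meta).set_index("sample_id")
    return OtuTable(df, meta_df)


@pytest.fixture
def tiny_table():
    return make_table([[5, 0], [1, 2], [0, 3]])


@pytest.fixture
def simple_lookup():
    return RrnLookup({
        "sphingomonas": 2.0,
        "acidovorax": 3.0,
        "flavobacterium": 5.0,
        "azospirillum": 9.0,
        "phenylobacterium": 1.0,
    })


def write_tsv(path, text):
    path.write_text(text, encoding="utf-8")
    return path
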