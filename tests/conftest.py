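import numpy as np
import pandas as pd
import pytest

import clonemark as cm
from clonemark.io import COLUMNS


@pytest.fixture(scope="session")
def toy_ref():
    return cm.build_toy_reference(1)


@pytest.fixture(scope="session")
def annotator(toy_ref):
    return cm.Annotator(toy_ref)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def table_row(**kw):
    """One rearrangement-table row with sensible defaults."""
    row = {
        "sequence_id": "r1", "case_id": "caseA", "platform": "DNAamp",
        "tube": "TRG", "locus": "TRG", "junction_class": "Vg-Jg",
        "five_gene": "TRGV1-1", "five_del": 2, "np_total": 5, "three_del": 1,
        "three_gene": "TRGJ1", "junction": "TGTGCCAGC", "junction_aa": "CAS",
        "productivity": "productive", "damaged": False, "duplicate_count": 1,
    }
    row.update(kw)
    return row


def make_table(rows):
    df = pd.DataFrame(rows, columns=COLUMNS)
    for c in ("five_del", "np_total", "three_del"):
        df[c] = df[c].astype("Int64")
    if len(df):
        df["damaged"] = df["damaged"].astype(bool)
    return df
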