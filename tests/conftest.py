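import numpy as np
import pandas as pd
import pytest

from tcrtissue.types import CloneTable, SampleMeta


def make_meta(
    sample_id="S1",
    donor_id="D1",
    age=45,
    lineage="CD8",
    subset="TEM",
    tissue="Bld",
    replicate=1,
) -> SampleMeta:
    return SampleMeta(
        sample_id=sample_id,
        donor_id=donor_id,
        age=age,
        lineage=lineage,
        subset=subset,
        tissue=tissue,
        replicate=replicate,
    )


def make_table(clones, meta=None) -> CloneTable:
    """Build a CloneTable from (v, j, cdr3, copies) tuples."""
    meta = meta or make_meta()
    df = pd.DataFrame(clones, columns=["v_call", "j_call", "cdr3_aa", "copies"])
    return CloneTable.from_counts(meta, df)


@pytest.fixture
def meta():
    return make_meta()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
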