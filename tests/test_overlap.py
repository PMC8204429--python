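"""Cosine overlap: replicate averaging, per-donor matrices, compiled
group summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_meta, make_table
from tcrtissue.overlap import (
    CROSS_SUBSET_BETWEEN_SITES,
    CROSS_SUBSET_WITHIN_SITE,
    SAME_SUBSET_BETWEEN_SITES,
    classify_pair,
    compile_group_overlap,
    cosine,
    overlap_matrix,
    pairwise_cosine_frame,
    sample_pair_cosine,
)


def test_cosine_identity_and_orthogonality():
    a = {"c1": 0.6, "c2": 0.4}
    assert cosine(a, a) == pytest.approx(1.0)
    assert cosine({"c1": 1.0}, {"c2": 1.0}) == pytest.approx(0.0)


def test_cosine_hand_example():
    assert cosine({"c1": 1.0}, {"c1": 0.5, "c2": 0.5}) == pytest.approx(
        0.5 / np.sqrt(0.5)
    )
    assert cosine({"c1": 1.0}, {"c1": 0.5, "c2": 0.5}) == pytest.approx(0.7071, abs=1e-4)


def test_cosine_zero_vector_errors():
    with pytest.raises(ValueError, match="zero vector"):
        cosine({"c1": 0.0}, {"c1": 1.0})


@settings(deadline=None, derandomize=True)
@given(
    values=st.lists(
        st.floats(min_value=0.01, max_value=10.0), min_size=1, max_size=8
    ),
    scale=st.floats(min_value=0.1, max_value=50.0),
)
def test_cosine_symmetric_and_scale_invariant(values, scale):
    a = {f"c{i}": v for i, v in enumerate(values)}
    b = {f"c{i}": v for i, v in enumerate(reversed(values))}
    assert cosine(a, b) == pytest.approx(cosine(b, a), abs=1e-12)
    scaled = {k: v * scale for k, v in a.items()}
    assert cosine(scaled, b) == pytest.approx(cosine(a, b), abs=1e-9)


def _rep_tables(clone_sets, subset="TEM", tissue="Bld", donor="D1", lineage="CD8"):
    """clone_sets: one list of (cdr3, copies) per replicate."""
    return [
        make_table(
            [("TRBV19", "TRBJ1-1", cdr3, c) for cdr3, c in clones],
            make_meta(
                f"{donor}_{lineage}_{subset}_{tissue}_r{r}", donor_id=donor,
                lineage=lineage, subset=subset, tissue=tissue, replicate=r,
            ),
        )
        for r, clones in enumerate(clone_sets, start=1)
    ]


def test_sample_pair_cosine_identical_replicates():
    reps = _rep_tables([[("CAAAF", 5), ("CAACF", 5)]] * 2)
    out = sample_pair_cosine(reps, reps, apply_cutoff=False)
    assert out.cosine_mean == pytest.approx(1.0)
    assert out.n_replicate_pairs == 4


def test_sample_pair_cosine_disjoint_samples():
    a = _rep_tables([[("CAAAF", 5)], [("CAAAF", 5)]])
    b = _rep_tables([[("CGGGF", 5)], [("CGGGF", 5)]], tissue="Spl")
    assert sample_pair_cosine(a, b, apply_cutoff=False).cosine_mean == 0.0


def test_sample_pair_cosine_crossed_replicates_mean_half():
    # A1=B1={c1}, A2=B2={c2}: pairs (1,0,0,1) -> mean 0.5
    a = _rep_tables([[("CAAAF", 5)], [("CGGGF", 5)]])
    b = _rep_tables([[("CAAAF", 5)], [("CGGGF", 5)]], tissue="Spl")
    out = sample_pair_cosine(a, b, apply_cutoff=False)
    assert out.cosine_mean == pytest.approx(0.5)
    assert out.n_replicate_pairs == 4


def test_sample_pair_cosine_missing_replicate_falls_back():
    a = _rep_tables([[("CAAAF", 5)]])
    b = _rep_tables([[("CAAAF", 5)], [("CAAAF", 5)]], tissue="Spl")
    out = sample_pair_cosine(a, b, apply_cutoff=False)
    assert out.n_replicate_pairs == 2
    assert out.cosine_mean == pytest.approx(1.0)


def _donor_tables():
    tables = []
    layout = {
        ("TEM", "Bld"): [("CAAAF", 6), ("CAACF", 4)],
        ("TEM", "Spl"): [("CAAAF", 5), ("CAADF", 5)],
        ("TRM", "Spl"): [("CGGGF", 10)],
    }
    for (subset, tissue), clones in layout.items():
        tables += _rep_tables([clones, clones], subset=subset, tissue=tissue)
    return tables


def test_overlap_matrix_symmetry_and_diagonal():
    mat, order = overlap_matrix(_donor_tables(), apply_cutoff=False)
    assert mat.shape == (3, 3)
    assert np.allclose(mat, mat.T, atol=1e-12)
    assert np.allclose(np.diag(mat), 1.0)
    assert sorted(order) == sorted(mat.index)


def test_overlap_matrix_invariant_to_input_order():
    tables = _donor_tables()
    mat1, _ = overlap_matrix(tables, apply_cutoff=False)
    mat2, _ = overlap_matrix(tables[::-1], apply_cutoff=False)
    pd.testing.assert_frame_equal(mat1, mat2)


def test_overlap_matrix_two_samples_off_diagonal():
    tables = _donor_tables()[:4]  # TEM_Bld + TEM_Spl, 2 replicates each
    mat, _ = overlap_matrix(tables, apply_cutoff=False)
    expected = sample_pair_cosine(tables[:2], tables[2:], apply_cutoff=False).cosine_mean
    assert mat.iloc[0, 1] == pytest.approx(expected)


def test_overlap_matrix_rejects_mixed_donors():
    tables = _donor_tables()[:2] + _rep_tables(
        [[("CAAAF", 5)], [("CAAAF", 5)]], donor="D2"
    )
    with pytest.raises(ValueError, match="one donor"):
        overlap_matrix(tables)


def test_classify_pair_designs():
    tem_bld = make_meta("a", subset="TEM", tissue="Bld")
    tem_spl = make_meta("b", subset="TEM", tissue="Spl")
    trm_spl = make_meta("c", subset="TRM", tissue="Spl")
    trm_bld = make_meta("d", subset="TRM", tissue="Bld")
    assert classify_pair(tem_bld, tem_spl) == SAME_SUBSET_BETWEEN_SITES
    assert classify_pair(tem_spl, trm_spl) == CROSS_SUBSET_WITHIN_SITE
    assert classify_pair(tem_bld, trm_spl) == CROSS_SUBSET_BETWEEN_SITES
    assert classify_pair(trm_bld, trm_bld) is None


def test_compile_group_overlap_two_donor_sem():
    pairs = pd.DataFrame(
        {
            "donor_id": ["D1", "D2"],
            "lineage": "CD8",
            "design": SAME_SUBSET_BETWEEN_SITES,
            "group": "TEM",
            "cosine_mean": [0.4, 0.6],
            "n_replicate_pairs": 4,
        }
    )
    out = compile_group_overlap(pairs).iloc[0]
    assert out["mean"] == pytest.approx(0.5)
    assert out["sem"] == pytest.approx(0.1)
    assert out["n"] == 2 and bool(out["sem_defined"])


def test_compile_group_overlap_single_pair_flags_sem():
    pairs = pd.DataFrame(
        {
            "donor_id": ["D1"], "lineage": "CD8", "design": SAME_SUBSET_BETWEEN_SITES,
            "group": "TEM", "cosine_mean": [0.4], "n_replicate_pairs": 4,
        }
    )
    out = compile_group_overlap(pairs).iloc[0]
    assert out["mean"] == pytest.approx(0.4)
    assert out["sem"] == 0.0 and not bool(out["sem_defined"])


def test_between_subject_normalization_preserves_grand_mean():
    pairs = pd.DataFrame(
        {
            "donor_id": ["D1", "D1", "D2", "D2"],
            "lineage": "CD8",
            "design": SAME_SUBSET_BETWEEN_SITES,
            "group": "TEM",
            "cosine_mean": [0.2, 0.3, 0.6, 0.7],
            "n_replicate_pairs": 4,
        }
    )
    raw = compile_group_overlap(pairs, normalize_between_subjects=False).iloc[0]
    norm = compile_group_overlap(pairs, normalize_between_subjects=True).iloc[0]
    assert norm["mean"] == pytest.approx(raw["mean"])  # grand mean restored
    assert norm["sem"] < raw["sem"]  # donor-level variation removed


def test_pairwise_cosine_frame_classification():
    frame = pairwise_cosine_frame(_donor_tables(), apply_cutoff=False)
    designs = dict(
        zip(zip(frame["subset_a"] + "_" + frame["tissue_a"],
                frame["subset_b"] + "_" + frame["tissue_b"]), frame["design"])
    )
    assert designs[("TEM_Bld", "TEM_Spl")] == SAME_SUBSET_BETWEEN_SITES
    assert designs[("TEM_Spl", "TRM_Spl")] == CROSS_SUBSET_WITHIN_SITE
    assert designs[("TEM_Bld", "TRM_Spl")] == CROSS_SUBSET_BETWEEN_SITES
    assert len(frame) == 3
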