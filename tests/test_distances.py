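"""CDR3 edit/Hamming distances, symmetrized KL divergence of TRBV usage,
clone sampling and the stratum hierarchy."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_meta, make_table
from tcrtissue.distances import (
    DistanceSample,
    classify_stratum,
    distance_hierarchy,
    draw_distance_sample,
    embedding_input,
    hamming,
    kl_divergence_sym,
    levenshtein,
    pairwise_distance_matrix,
    pooled_distance_matrix,
    remove_overlapping_clones,
)


def dp_levenshtein(a: str, b: str) -> int:
    """Independent quadratic dynamic-programming oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[len(b)]


def test_levenshtein_basics():
    assert levenshtein("CASSLG", "CASSLG") == 0
    assert levenshtein("CASSL", "CASS") == 1
    assert levenshtein("kitten", "sitting") == 3
    assert levenshtein("", "CASS") == 4
    assert levenshtein("", "") == 0


def test_levenshtein_matches_dp_oracle_short_alphabet():
    """Agreement with an independent DP oracle on all pairs from a pool of
    short strings over a reduced 4-letter alphabet (lengths 0..8)."""
    rng = np.random.default_rng(14)
    alphabet = "ACDE"
    pool = [""]
    pool += [
        "".join(rng.choice(list(alphabet), size=length))
        for length in range(1, 9)
        for _ in range(14)
    ]
    for a, b in itertools.combinations(pool, 2):
        assert levenshtein(a, b) == dp_levenshtein(a, b)


@settings(deadline=None, derandomize=True)
@given(st.lists(st.text(alphabet="ACDEFGHIKL", min_size=0, max_size=12), min_size=3, max_size=3))
def test_levenshtein_metric_axioms(strings):
    a, b, c = strings
    assert levenshtein(a, b) == levenshtein(b, a)
    assert (levenshtein(a, b) == 0) == (a == b)
    assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)


def test_hamming_basics_and_skip_policy():
    assert hamming("CASS", "CASS") == 0
    assert hamming("CASS", "CAST") == 1
    assert hamming("CAS", "CASS") is None


def test_kl_identical_vectors_zero():
    counts = {"TRBV1": 5, "TRBV2": 3}
    assert kl_divergence_sym(counts, counts) == pytest.approx(0.0, abs=1e-15)


def test_kl_hand_example():
    # {A:3,B:0} vs {A:0,B:3} with pseudocount 1 -> 1.2 * ln 4
    d = kl_divergence_sym({"A": 3}, {"B": 3})
    assert d == pytest.approx(1.2 * np.log(4), rel=1e-12)
    assert d == pytest.approx(1.6636, abs=1e-4)


@settings(deadline=None, derandomize=True)
@given(
    ci=st.lists(st.integers(min_value=0, max_value=40), min_size=2, max_size=10),
    cj=st.lists(st.integers(min_value=0, max_value=40), min_size=2, max_size=10),
)
def test_kl_symmetry_and_nonnegativity(ci, cj):
    genes = [f"TRBV{i}" for i in range(max(len(ci), len(cj)))]
    a = dict(zip(genes, ci))
    b = dict(zip(genes, cj))
    d_ab = kl_divergence_sym(a, b, support=genes)
    d_ba = kl_divergence_sym(b, a, support=genes)
    assert d_ab == pytest.approx(d_ba, abs=1e-12)
    assert d_ab >= 0.0
    # permuting gene labels in both samples leaves the divergence unchanged
    perm = genes[::-1]
    a_p = dict(zip(perm, ci))
    b_p = dict(zip(perm, cj))
    assert kl_divergence_sym(a_p, b_p, support=genes) == pytest.approx(d_ab, abs=1e-12)


def _tables_with(cdr3s_by_sample):
    tables = []
    for sid, cdr3s in cdr3s_by_sample.items():
        tables.append(
            make_table(
                [("TRBV19", "TRBJ1-1", c, 5) for c in cdr3s],
                make_meta(sid, tissue="Bld" if sid.endswith("A") else "Spl"),
            )
        )
    return tables


def test_remove_overlapping_clones_removes_from_all():
    a, b = _tables_with({"SA": ["CAAAF", "CBBBF"], "SB": ["CAAAF"]})
    out_a, out_b = remove_overlapping_clones([a, b])
    assert out_a.df["cdr3_aa"].tolist() == ["CBBBF"]
    assert out_b.n_clones == 0


def test_remove_overlapping_clones_disjoint_identity():
    a, b = _tables_with({"SA": ["CAAAF"], "SB": ["CBBBF"]})
    out_a, out_b = remove_overlapping_clones([a, b])
    assert out_a.n_clones == 1 and out_b.n_clones == 1


def test_remove_overlapping_clones_identical_samples_emptied():
    a, b = _tables_with({"SA": ["CAAAF", "CBBBF"], "SB": ["CAAAF", "CBBBF"]})
    out_a, out_b = remove_overlapping_clones([a, b])
    assert out_a.n_clones == 0 and out_b.n_clones == 0


def _big_table(n, meta=None, seed=0):
    rng = np.random.default_rng(seed)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    rows = [
        (f"TRBV{i % 20}", "TRBJ1-1", "C" + "".join(rng.choice(aa, 10)) + "F", 5)
        for i in range(n)
    ]
    return make_table(rows, meta or make_meta())


def test_draw_distance_sample_deterministic_and_order_invariant():
    table = _big_table(300)
    s1 = draw_distance_sample(table, n=100, seed=7)
    s2 = draw_distance_sample(table, n=100, seed=7)
    pd.testing.assert_frame_equal(s1.clones, s2.clones)
    shuffled = table.with_df(table.df.sample(frac=1.0, random_state=1))
    s3 = draw_distance_sample(shuffled, n=100, seed=7)
    pd.testing.assert_frame_equal(s1.clones, s3.clones)
    assert not s1.undersampled
    assert draw_distance_sample(table, n=100, seed=8).clones["cdr3_aa"].tolist() != s1.clones["cdr3_aa"].tolist()


def test_draw_distance_sample_undersampled_takes_all():
    table = _big_table(120)
    s = draw_distance_sample(table, n=500, seed=0)
    assert s.undersampled and len(s.clones) == 120


def test_pairwise_distance_matrix_counts_cross_pairs():
    a, b = _tables_with({"SA": ["CAAAF", "CBBBF"], "SB": ["CCCCF", "CDDDF"]})
    sa = draw_distance_sample(a, n=2, seed=0)
    sb = draw_distance_sample(b, n=2, seed=0)
    long = pairwise_distance_matrix([sa, sb])
    assert len(long) == 4
    assert (long["distance"] > 0).all()


def test_pooled_matrix_symmetric_zero_diagonal_labels_aligned():
    a, b = _tables_with({"SA": ["CAAAF", "CBBBF"], "SB": ["CCCCF"]})
    samples = [draw_distance_sample(t, n=5, seed=0) for t in (a, b)]
    mat, labels = pooled_distance_matrix(samples)
    assert mat.shape == (3, 3) and len(labels) == 3
    assert np.allclose(mat, mat.T)
    assert np.allclose(np.diag(mat), 0.0)
    assert labels["sample_id"].tolist() == ["SA", "SA", "SB"]


def test_classify_stratum_finest_difference():
    base = dict(donor_id="D1", age=45, lineage="CD8", subset="TEM", tissue="Bld")
    a = make_meta("a", replicate=1, **base)
    assert classify_stratum(a, make_meta("b", replicate=2, **base)) == "replicate"
    assert classify_stratum(a, make_meta("c", **{**base, "subset": "TRM"})) == "subset"
    assert classify_stratum(a, make_meta("d", **{**base, "tissue": "Spl", "subset": "TRM"})) == "tissue"
    assert classify_stratum(a, make_meta("e", **{**base, "lineage": "CD4", "tissue": "Spl"})) == "lineage"
    assert classify_stratum(a, make_meta("f", **{**base, "donor_id": "D2"})) == "donor"


def _mini_cohort_samples():
    samples = []
    i = 0
    for donor in ("D1", "D2"):
        for tissue in ("Bld", "Spl"):
            for subset in ("TEM", "TRM"):
                for rep in (1, 2):
                    table = _big_table(
                        30,
                        make_meta(
                            f"{donor}{tissue}{subset}{rep}", donor_id=donor,
                            subset=subset, tissue=tissue, replicate=rep,
                        ),
                        seed=i,
                    )
                    samples.append(draw_distance_sample(table, n=20, seed=i))
                    i += 1
    return samples


def test_hierarchy_partitions_all_pairs():
    samples = _mini_cohort_samples()
    summary, pairs = distance_hierarchy(samples, metric="levenshtein")
    n = len(samples)
    assert summary["n_pairs"].sum() == n * (n - 1) // 2
    assert len(pairs) == n * (n - 1) // 2
    assert set(summary["stratum"]) <= {"replicate", "subset", "tissue", "lineage", "donor"}


def test_hierarchy_kl_metric_runs_and_partitions():
    samples = _mini_cohort_samples()
    summary, pairs = distance_hierarchy(samples, metric="kl")
    assert summary["n_pairs"].sum() == len(pairs)
    assert (pairs["mean_distance"] >= 0).all()


def test_hierarchy_identical_cdr3s_all_zero():
    samples = []
    for i, sid in enumerate(("A1", "A2")):
        table = make_table(
            [("TRBV19", "TRBJ1-1", "CASSF", 5)],
            make_meta(sid, replicate=i + 1),
        )
        samples.append(draw_distance_sample(table, n=1, seed=0))
    summary, _ = distance_hierarchy(samples, metric="levenshtein")
    assert summary["mean"].to_numpy() == pytest.approx([0.0])
    assert summary["stratum"].tolist() == ["replicate"]


def test_embedding_input_shape_and_determinism():
    tables = [
        _big_table(40, make_meta("SA"), seed=1),
        _big_table(40, make_meta("SB", tissue="Spl"), seed=2),
    ]
    mat1, labels1 = embedding_input(tables, n=25, seed=3)
    mat2, labels2 = embedding_input(tables, n=25, seed=3)
    assert np.array_equal(mat1, mat2)
    pd.testing.assert_frame_equal(labels1, labels2)
    assert mat1.shape[0] == len(labels1)
    assert {"tissue", "subset"} <= set(labels1.columns)
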