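"""Reading, probe intersection, merge normalization and pairwise subsets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from expr2img.containers import ExpressionMatrix
from expr2img.errors import FormatError, LabelingError
from expr2img.ingest import (
    TASKS,
    intersect_probes,
    make_pair_subset,
    merge_and_normalize,
    read_expression,
)


def _mat(values, probes, samples, labels=None, dataset="D"):
    return ExpressionMatrix(
        values=np.asarray(values, dtype=float),
        probe_ids=probes,
        sample_ids=samples,
        labels=labels,
        dataset_ids=[dataset] * len(samples),
    )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def test_tsv_round_trip_preserves_order(tmp_path):
    m = _mat([[1, 2], [3, 4], [5, 6]], ["p2", "p1", "p3"], ["s1", "s2"], ["AD", "NC"])
    m.write_tsv(tmp_path / "m.tsv", tmp_path / "m_labels.csv")
    back = read_expression(tmp_path / "m.tsv", labels_path=tmp_path / "m_labels.csv")
    assert back.probe_ids == ["p2", "p1", "p3"]  # file order, verbatim
    assert back.sample_ids == ["s1", "s2"]
    assert back.labels == ["AD", "NC"]
    np.testing.assert_array_equal(back.values, m.values)


def test_duplicate_probe_id_is_named_in_error(tmp_path):
    (tmp_path / "dup.tsv").write_text("probe_id\ts1\np7\t1.0\np7\t2.0\n")
    with pytest.raises(FormatError, match="p7"):
        read_expression(tmp_path / "dup.tsv")


def test_missing_label_raises(tmp_path):
    m = _mat([[1, 2]], ["p1"], ["s1", "s2"], ["AD", "NC"])
    m.write_tsv(tmp_path / "m.tsv")
    (tmp_path / "labels.csv").write_text("sample_id,label\ns1,AD\n")
    with pytest.raises(LabelingError, match="s2"):
        read_expression(tmp_path / "m.tsv", labels_path=tmp_path / "labels.csv")


GEO_FIXTURE = """!Series_title\t"synthetic fixture"
!Sample_geo_accession\t"GSM1"\t"GSM2"\t"GSM3"
!Sample_characteristics_ch1\t"status: AD"\t"status: CTL"\t"status: MCI"
!series_matrix_table_begin
"ID_REF"\t"GSM1"\t"GSM2"\t"GSM3"
"pA"\t1.5\t2.5\t3.5
"pB"\t4.0\t5.0\t6.0
!series_matrix_table_end
"""


def test_geo_series_matrix_parses_table_block_only(tmp_path):
    path = tmp_path / "gse.txt"
    path.write_text(GEO_FIXTURE)
    m = read_expression(path, format="geo_series_matrix")
    # hand-parsed expectation of the fixture above
    assert m.probe_ids == ["pA", "pB"]
    assert m.sample_ids == ["GSM1", "GSM2", "GSM3"]
    np.testing.assert_array_equal(m.values, [[1.5, 2.5, 3.5], [4.0, 5.0, 6.0]])
    assert m.labels == ["AD", "NC", "MCI"]  # CTL mapped to NC


# ---------------------------------------------------------------------------
# intersection
# ---------------------------------------------------------------------------

def test_intersection_restricts_to_shared_probes():
    a = _mat([[1, 1], [2, 2], [3, 3]], ["a", "b", "c"], ["s1", "s2"])
    b = _mat([[4], [5], [6]], ["b", "c", "d"], ["t1"])
    ia, ib = intersect_probes([a, b])
    assert ia.probe_ids == ib.probe_ids == ["b", "c"]
    np.testing.assert_array_equal(ia.values, [[2, 2], [3, 3]])
    np.testing.assert_array_equal(ib.values, [[4], [5]])


def test_intersection_three_way_count(rng):
    # 20 probes each, engineered to share exactly 5
    shared = [f"s{i}" for i in range(5)]
    mats = []
    for d in range(3):
        own = [f"d{d}_{i}" for i in range(15)]
        probes = shared + own
        rng.shuffle(probes)
        mats.append(_mat(rng.normal(size=(20, 2)), probes, [f"x{d}a", f"x{d}b"]))
    outs = intersect_probes(mats)
    # brute-force oracle
    expect = sorted(set(mats[0].probe_ids) & set(mats[1].probe_ids) & set(mats[2].probe_ids))
    assert all(o.probe_ids == expect for o in outs)
    assert all(o.n_genes == 5 for o in outs)


def test_intersection_canonical_order_is_input_order_independent():
    a = _mat([[1], [2], [3]], ["c", "a", "b"], ["s1"])
    b = _mat([[4], [5], [6]], ["b", "c", "a"], ["t1"])
    o1 = intersect_probes([a, b])
    o2 = intersect_probes([b, a])
    assert o1[0].probe_ids == o2[0].probe_ids == ["a", "b", "c"]
    np.testing.assert_array_equal(o1[0].values, o2[1].values)


def test_empty_intersection_errors():
    a = _mat([[1]], ["a"], ["s1"])
    b = _mat([[2]], ["b"], ["t1"])
    with pytest.raises(FormatError):
        intersect_probes([a, b])


# ---------------------------------------------------------------------------
# merge + normalize
# ---------------------------------------------------------------------------

def test_zscore_then_minmax_single_gene():
    m = _mat([[2, 4, 6]], ["g"], ["s1", "s2", "s3"], ["AD", "NC", "AD"])
    out = merge_and_normalize([m])
    np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])


def test_constant_gene_maps_to_zero():
    m = _mat([[5, 5, 5], [1, 2, 3]], ["g1", "g2"], ["a", "b", "c"], ["AD"] * 3)
    out = merge_and_normalize([m])
    np.testing.assert_array_equal(out.values[0], [0, 0, 0])


def test_dataset_offset_removed_in_merge():
    """Two one-gene datasets offset by 100 normalize to the same pattern."""
    a = _mat([[0.0, 1.0]], ["g"], ["a1", "a2"], ["AD", "NC"], dataset="A")
    b = _mat([[100.0, 101.0]], ["g"], ["b1", "b2"], ["AD", "NC"], dataset="B")
    out = merge_and_normalize([a, b])
    # hand computation: each dataset z-scores to [-1, +1], combined min-max
    # maps -1 -> 0 and +1 -> 1, so the offset disappears entirely
    np.testing.assert_allclose(out.values, [[0.0, 1.0, 0.0, 1.0]])
    assert out.dataset_ids == ["A", "A", "B", "B"]


def test_merge_output_in_unit_interval_and_idempotent(small_cohort):
    _, merged = small_cohort
    assert merged.values.min() >= 0.0 and merged.values.max() <= 1.0
    from expr2img.ingest import minmax_rows

    np.testing.assert_allclose(minmax_rows(merged.values), merged.values, atol=1e-12)


@settings(max_examples=25, derandomize=True)
@given(
    values=arrays(
        np.float64,
        st.tuples(st.integers(2, 6), st.integers(2, 8)),
        elements=st.floats(-1e6, 1e6, allow_nan=False),
    )
)
def test_normalized_range_property(values):
    m = ExpressionMatrix(
        values=values,
        probe_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
    )
    out = merge_and_normalize([m])
    assert np.isfinite(out.values).all()
    assert out.values.min() >= 0.0 and out.values.max() <= 1.0


# ---------------------------------------------------------------------------
# pairwise tasks
# ---------------------------------------------------------------------------

@pytest.fixture
def three_class_matrix(rng):
    labels = ["AD"] * 10 + ["MCI"] * 10 + ["NC"] * 10
    return _mat(rng.normal(size=(4, 30)), [f"g{i}" for i in range(4)],
                [f"s{j}" for j in range(30)], labels)


def test_pair_subset_filters_and_binarizes(three_class_matrix):
    sub = make_pair_subset(three_class_matrix, "AD_vs_NC")
    assert sub.n_samples == 20
    assert sub.binary_labels.sum() == 10
    assert sub.labels == ["AD"] * 10 + ["NC"] * 10  # order preserved


def test_union_class_task(three_class_matrix):
    sub = make_pair_subset(three_class_matrix, "AD+MCI_vs_NC")
    assert sub.n_samples == 30
    assert sub.binary_labels.sum() == 20


def test_absent_class_errors(three_class_matrix):
    two = three_class_matrix.subset_samples(np.arange(20))  # drops NC
    with pytest.raises(LabelingError, match="NC"):
        make_pair_subset(two, "AD_vs_NC")


def test_task_registry_is_consistent():
    for task in TASKS.values():
        assert not task.positive_classes & task.negative_classes
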