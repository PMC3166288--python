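"""Overlap criterion, per-record classification, and the benchmark metrics."""

import math

import pytest

from nolscan.evaluation import (
    EvaluationRecord,
    classify,
    compute_metrics,
    length_filter,
    load_benchmark,
    overlap_fraction,
)
from nolscan.params import Parameters
from nolscan.segment_caller import NoLSInterval


def iv(s, e):
    return NoLSInterval(s, e)


def rec(experimental, predicted, acc="P1", group="mammals"):
    return EvaluationRecord(
        organism="test", group=group, protein_accession=acc,
        protein_name="test", experimental_nols=tuple(experimental),
        predicted_nols=tuple(predicted))


@pytest.mark.parametrize("a,b,expected", [
    (iv(129, 143), iv(120, 143), 15 / 15),   # prediction contains signal
    (iv(31, 64), iv(27, 49), 19 / 23),       # partial overlap
    (iv(1, 47), iv(22, 60), 26 / 39),        # partial overlap
    (iv(1, 10), iv(20, 30), 0.0),            # disjoint
    (iv(5, 8), iv(1, 100), 1.0),             # containment
])
def test_overlap_fraction_worked_examples(a, b, expected):
    assert overlap_fraction(a, b) == pytest.approx(expected)
    assert overlap_fraction(b, a) == pytest.approx(expected)  # symmetric


def test_classify_one_detected_one_missed_no_fp():
    c = classify(rec([iv(10, 41), iv(131, 154)], [iv(133, 155)]))
    assert c.detected == (False, True)
    assert c.n_tp == 1 and c.n_fp == 0
    assert not c.has_false_positive


def test_classify_detected_plus_false_positive():
    c = classify(rec([iv(220, 262)], [iv(230, 255), iv(276, 306)]))
    assert c.n_detected == 1
    assert c.is_tp == (True, False)
    assert c.has_false_positive


def test_classify_empty_prediction_list():
    c = classify(rec([iv(1, 30), iv(50, 80)], []))
    assert c.n_detected == 0 and c.n_missed == 2 and c.n_fp == 0


def test_classification_counts_partition():
    c = classify(rec([iv(1, 30), iv(50, 80)], [iv(5, 28), iv(200, 230)]))
    assert c.n_detected + c.n_missed == 2
    assert c.n_tp + c.n_fp == 2


@pytest.mark.parametrize("interval,keep", [
    (iv(129, 143), True),    # length 15
    (iv(51, 100), True),     # inclusive length exactly 50 is retained
    (iv(1, 60), False),
])
def test_length_filter_inclusive_50(interval, keep):
    assert length_filter(interval) is keep


def test_length_filter_strict_variant_drops_exact_50():
    strict = Parameters(strict_length_filter=True)
    assert length_filter(iv(51, 100), strict) is False
    assert length_filter(iv(51, 99), strict) is True


def test_benchmark_fixture_shape(benchmark_records):
    assert len({r.protein_accession for r in benchmark_records}) == 27
    assert sum(len(r.experimental_nols) for r in benchmark_records) == 31
    assert sum(len(r.predicted_nols) for r in benchmark_records) == 28
    esag8 = next(r for r in benchmark_records if r.protein_name == "ESAG8")
    assert esag8.predicted_nols == ()


def test_single_perfect_record_gives_unit_metrics():
    table = compute_metrics([rec([iv(10, 30)], [iv(10, 30)])])
    row = table.overall
    assert row["sensitivity"] == row["ppv"] == row["specificity"] == 1.0


def test_metrics_undefined_ppv_reported_as_na(benchmark_records):
    table = compute_metrics(benchmark_records)
    assert math.isnan(table.frame.loc["trypanosomes", "ppv"])


def test_metrics_invariant_to_record_order(benchmark_records):
    fwd = compute_metrics(benchmark_records).frame
    rev = compute_metrics(list(reversed(benchmark_records))).frame
    assert fwd.equals(rev.loc[fwd.index])


def test_per_organism_rows(benchmark_records):
    table = compute_metrics(benchmark_records, by="organism").rounded()
    hs = table.loc["Homo sapiens"]
    assert (hs["distinct_protein_count"], hs["nols_count"]) == (5, 6)
    assert (hs["sensitivity"], hs["ppv"], hs["specificity"]) == (0.83, 1.0, 1.0)
    mm = table.loc["Mus musculus"]
    assert (mm["sensitivity"], mm["ppv"], mm["specificity"]) == (1.0, 0.75, 0.67)


def test_metrics_export_tsv(benchmark_records, tmp_path):
    out = tmp_path / "metrics.tsv"
    compute_metrics(benchmark_records).to_tsv(out)
    text = out.read_text()
    assert text.startswith("group\t")
    assert "N/A" in text  # undefined PPV cell
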