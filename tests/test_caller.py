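"""Filter cascade, replicate restriction, control exclusion, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import naive_call
from ppredit.offtarget_caller import (
    CallerParams,
    DatasetSet,
    SiteCounts,
    aggregate_efficiency,
    call_offtargets,
    orient,
    passes_filters,
    quantify_peaks,
    read_site_counts,
    write_site_counts,
)


def _site(ref="C", rna=(0, 900, 5, 95), dataset="d1", contig="c", pos=100, dna=None):
    return SiteCounts(dataset, contig, pos, ref, rna, dna)


# -- orientation -------------------------------------------------------------


def test_orient_forward_arithmetic():
    ori = orient(_site("C", (0, 900, 5, 95)))
    assert ori.strand == "+"
    assert ori.edited_reads == 95 and ori.unedited_reads == 900
    assert ori.transition_purity == pytest.approx(0.995)
    assert ori.edit_frac == pytest.approx(95 / 995)


def test_orient_reverse_mirror():
    ori = orient(_site("G", (40, 0, 60, 0)))
    assert ori.strand == "-"
    assert ori.transition_purity == 1.0
    assert ori.edit_frac == pytest.approx(0.40)


def test_orient_non_candidate_reference():
    assert orient(_site("A")) is None
    assert orient(_site("T")) is None


# -- per-dataset criteria ----------------------------------------------------


def test_coverage_boundary():
    # 29 reads, otherwise perfect: criterion (i) fails
    low = passes_filters(_site("C", (0, 26, 0, 3)), CallerParams())
    assert not low.coverage_ok and not low.passed
    assert low.first_failure == "coverage"
    ok = passes_filters(_site("C", (0, 27, 0, 3)), CallerParams())
    assert ok.passed


def test_transition_purity_is_strict():
    # exactly 99% C+T is NOT a clear transition signal ("> 99%")
    at = passes_filters(_site("C", (1, 94, 0, 5)), CallerParams())
    assert not at.transition_ok
    above = passes_filters(_site("C", (0, 95, 0, 5)), CallerParams())
    assert above.transition_ok


def test_edit_signal_boundary():
    params = CallerParams()
    low = passes_filters(_site("C", (0, 991, 0, 9)), params)  # 0.9%
    assert not low.signal_ok and low.first_failure == "edit_signal"
    at = passes_filters(_site("C", (0, 990, 0, 10)), params)  # exactly 1%
    assert at.signal_ok and at.passed


def test_dna_purity_strict_and_assumed():
    dna_at = passes_filters(
        _site("C", dna=(0, 98, 2, 0)), CallerParams()
    )  # exactly 98% -> fail
    assert not dna_at.dna_ok
    dna_above = passes_filters(_site("C", dna=(0, 99, 1, 0)), CallerParams())
    assert dna_above.dna_ok
    assumed = passes_filters(_site("C"), CallerParams())
    assert assumed.dna_ok and assumed.dna_assumed_pure


# -- aggregation & Sanger ----------------------------------------------------


def test_aggregate_is_read_sum():
    assert aggregate_efficiency([(10, 90), (30, 70)]) == pytest.approx(0.20)
    assert aggregate_efficiency([(38, 62)]) == pytest.approx(0.38)
    # equals the coverage-weighted mean of per-dataset fractions
    assert aggregate_efficiency([(1, 9), (99, 891)]) == pytest.approx(0.10)


def test_aggregate_requires_reads():
    with pytest.raises(ValueError):
        aggregate_efficiency([(0, 0)])


@pytest.mark.parametrize(
    "t,c,expected", [(0.0, 2.5, 0.0), (1.3, 0.0, 1.0), (3.0, 1.0, 0.75)]
)
def test_quantify_peaks(t, c, expected):
    assert quantify_peaks(t, c) == pytest.approx(expected)


def test_quantify_peaks_undefined():
    with pytest.raises(ValueError):
        quantify_peaks(0.0, 0.0)


# -- replicate restriction & control exclusion -------------------------------


def _passing(dataset, pos=100, frac=0.1, cov=1000):
    edited = int(cov * frac)
    return _site("C", (0, cov - edited, 0, edited), dataset, pos=pos)


def test_two_of_three_datasets_called():
    sets = DatasetSet("p", ("d1", "d2", "d3"), ("w1",))
    counts = [_passing("d1"), _passing("d2")]
    calls, _ = call_offtargets(sets, counts)
    assert len(calls) == 1
    assert calls[0].supporting_dataset_ids == ("d1", "d2")


def test_single_dataset_not_called():
    sets = DatasetSet("p", ("d1", "d2", "d3"), ())
    calls, stats = call_offtargets(sets, [_passing("d1")])
    assert calls == []
    assert stats.failed_replicate_rule == 1


def test_control_editing_excludes_site():
    sets = DatasetSet("p", ("d1", "d2"), ("w1",))
    counts = [_passing("d1"), _passing("d2"), _passing("w1", frac=0.02)]
    calls, stats = call_offtargets(sets, counts)
    assert calls == []
    assert stats.failed_control_rule == 1


def test_silent_control_does_not_exclude():
    sets = DatasetSet("p", ("d1", "d2"), ("w1",))
    counts = [
        _passing("d1"),
        _passing("d2"),
        _site("C", (0, 995, 0, 5), "w1"),  # 0.5% in control: below veto
    ]
    calls, _ = call_offtargets(sets, counts)
    assert len(calls) == 1
    assert calls[0].aggregate_efficiency == pytest.approx(0.1)


def test_overlapping_treatment_control_rejected():
    with pytest.raises(ValueError):
        DatasetSet("p", ("d1", "d2"), ("d2",))


# -- oracle equivalence & properties ----------------------------------------

_counts4 = st.tuples(
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=60),
    st.integers(min_value=0, max_value=60),
)


@st.composite
def count_tables(draw):
    rows = draw(
        st.lists(
            st.tuples(
                st.sampled_from(["d1", "d2", "d3", "w1"]),
                st.integers(min_value=1, max_value=4),  # position
                st.sampled_from("ACGT"),
                _counts4,
            ),
            min_size=1,
            max_size=25,
        )
    )
    seen = set()
    records = []
    for dataset, pos, ref, rna in rows:
        if (dataset, pos) in seen or sum(rna) == 0:
            continue
        seen.add((dataset, pos))
        records.append(SiteCounts(dataset, "c", pos, ref, rna))
    return records


@settings(max_examples=150, deadline=None)
@given(count_tables())
def test_caller_matches_naive_oracle(records):
    sets = DatasetSet("p", ("d1", "d2", "d3"), ("w1",))
    params = CallerParams(min_coverage=20)
    calls, _ = call_offtargets(sets, records, params)
    got = {
        (c.contig, c.position, c.strand): c.aggregate_efficiency for c in calls
    }
    expected = naive_call(sets, records, params)
    assert set(got) == set(expected)
    for key in got:
        assert got[key] == pytest.approx(expected[key])


@settings(max_examples=60, deadline=None)
@given(count_tables())
def test_tightening_thresholds_never_adds_calls(records):
    sets = DatasetSet("p", ("d1", "d2", "d3"), ("w1",))
    base = CallerParams(min_coverage=20)
    n_base = len(call_offtargets(sets, records, base)[0])
    for tighter in (
        CallerParams(min_coverage=40),
        CallerParams(min_coverage=20, min_transition_purity=0.999),
        CallerParams(min_coverage=20, min_dna_purity=0.999),
        CallerParams(min_coverage=20, min_edit_frac=0.05),
        CallerParams(min_coverage=20, min_replicates=3),
    ):
        assert len(call_offtargets(sets, records, tighter)[0]) <= n_base


def _mirror(site: SiteCounts) -> SiteCounts:
    """Reverse-complement the evidence: A<->T, C<->G, ref complemented."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    a, c, g, t = site.rna_counts
    dna = None
    if site.dna_counts is not None:
        da, dc, dg, dt = site.dna_counts
        dna = (dt, dg, dc, da)
    return SiteCounts(
        site.dataset_id, site.contig, site.position,
        comp[site.dna_ref], (t, g, c, a), dna,
    )


@settings(max_examples=60, deadline=None)
@given(count_tables())
def test_orientation_symmetry(records):
    sets = DatasetSet("p", ("d1", "d2", "d3"), ("w1",))
    params = CallerParams(min_coverage=20)
    calls, _ = call_offtargets(sets, records, params)
    mirrored, _ = call_offtargets(sets, [_mirror(r) for r in records], params)
    flip = {"+": "-", "-": "+"}
    assert {(c.contig, c.position, flip[c.strand]) for c in calls} == {
        (c.contig, c.position, c.strand) for c in mirrored
    }
    assert sorted(c.aggregate_efficiency for c in calls) == pytest.approx(
        sorted(c.aggregate_efficiency for c in mirrored)
    )


def test_binomial_efficiency_recovery(rng):
    """Planted efficiency recovered within 3 binomial SE in >=99% of sims."""
    e, cov, n_sims = 0.3, 1000, 300
    se = np.sqrt(e * (1 - e) / (2 * cov))  # two supporting datasets
    hits = 0
    for _ in range(n_sims):
        evidence = [(int(rng.binomial(cov, e)), 0) for _ in range(2)]
        evidence = [(ed, cov - ed) for ed, _ in evidence]
        if abs(aggregate_efficiency(evidence) - e) <= 3 * se:
            hits += 1
    assert hits / n_sims >= 0.99


# -- tabular I/O -------------------------------------------------------------


def test_native_roundtrip(tmp_path):
    records = [
        _site("C", (0, 900, 5, 95), "d1"),
        _site("G", (40, 0, 60, 0), "d2", pos=200, dna=(1, 0, 99, 0)),
    ]
    path = tmp_path / "counts.tsv"
    write_site_counts(records, path)
    back = read_site_counts(path)
    assert back == [
        SiteCounts("d1", "c", 100, "C", (0, 900, 5, 95), (0, 0, 0, 0)),
        SiteCounts("d2", "c", 200, "G", (40, 0, 60, 0), (1, 0, 99, 0)),
    ]


def test_jacusa_style_column_mapping(tmp_path):
    path = tmp_path / "jacusa.tsv"
    path.write_text(
        "#chrom\tposition\trefbase\tbases11\tsample\n"
        "c\t100\tC\t0,900,5,95\td1\n"
    )
    records = read_site_counts(
        path,
        column_map={
            "contig": "#chrom",
            "pos": "position",
            "ref": "refbase",
            "rna_bases": "bases11",
            "dataset": "sample",
        },
    )
    assert records == [SiteCounts("d1", "c", 100, "C", (0, 900, 5, 95))]


def test_zero_coverage_rows_dropped(tmp_path):
    path = tmp_path / "counts.tsv"
    path.write_text(
        "contig\tpos\tref\tA\tC\tG\tT\tdataset\n"
        "c\t1\tC\t0\t0\t0\t0\td1\n"
        "c\t2\tC\t0\t30\t0\t5\td1\n"
    )
    records = read_site_counts(path)
    assert len(records) == 1 and records[0].position == 2


def test_missing_column_raises(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("contig\tpos\tA\tC\tG\tT\n" "c\t1\t0\t1\t0\t0\n")
    with pytest.raises(ValueError, match="ref"):
        read_site_counts(path)


def test_empty_table(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("contig\tpos\tref\tA\tC\tG\tT\tdataset\n")
    assert read_site_counts(path) == []
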