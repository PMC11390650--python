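"""Event model: table IO, PSI computation, classification, expression filter."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from orthosplice.events import (
    Condition,
    DialectError,
    EventTableParseError,
    EventType,
    InclusionClass,
    ReplicateCounts,
    SpliceEvent,
    classify_psi,
    compute_psi,
    filter_expressed,
    read_event_table,
    write_event_table,
    RMATS_JC_COLUMNS,
)


def _rc(inc, skp, li=2.0, ls=1.0, cond=Condition.basal, eid="e1"):
    return ReplicateCounts(eid, cond, tuple(inc), tuple(skp),
                           inclusion_eff_len=li, skipping_eff_len=ls)


def _rmats_row(**overrides):
    row = {
        "ID": "ev1", "GeneID": "G1", "geneSymbol": "Gene1", "chr": "chr1",
        "strand": "+", "exonStart_0base": "100", "exonEnd": "200",
        "upstreamES": "10", "upstreamEE": "50", "downstreamES": "300",
        "downstreamEE": "400", "IJC_SAMPLE_1": "30,28,31",
        "SJC_SAMPLE_1": "10,12,9", "IJC_SAMPLE_2": "5,6,7",
        "SJC_SAMPLE_2": "20,21,22", "IncFormLen": "2", "SkipFormLen": "1",
        "PValue": "NA", "FDR": "NA", "IncLevel1": "NA", "IncLevel2": "NA",
        "IncLevelDifference": "NA",
    }
    row.update(overrides)
    return "\t".join(row[c] for c in RMATS_JC_COLUMNS)


class TestEventInvariants:
    def test_boundary_order_enforced(self):
        with pytest.raises(ValueError, match="boundary order"):
            SpliceEvent("e", "s", "g", "G", EventType.SE, "chr1", "+",
                        target_start=100, target_end=200,
                        upstream_end=150, downstream_start=300)

    def test_empty_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chromosome"):
            SpliceEvent("e", "s", "g", "G", EventType.SE, "", "+",
                        100, 200, 50, 300)

    def test_unequal_replicate_vectors_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            _rc([1, 2], [1])


class TestReadEventTable:
    def test_rmats_row_maps_fields(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("\t".join(RMATS_JC_COLUMNS) + "\n" + _rmats_row() + "\n")
        events, counts = read_event_table(path, dialect="rmats_jc")
        assert len(events) == 1
        ev = events[0]
        assert (ev.target_start, ev.target_end) == (100, 200)
        assert (ev.upstream_end, ev.downstream_start) == (50, 300)
        basal = [c for c in counts if c.condition is Condition.basal][0]
        assert basal.inclusion_counts == (30, 28, 31)
        assert basal.skipping_counts == (10, 12, 9)
        assert basal.n_replicates == 3

    def test_empty_table(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("\t".join(RMATS_JC_COLUMNS) + "\n")
        events, counts = read_event_table(path)
        assert events == [] and counts == []

    def test_invariant_violation_reports_line(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("\t".join(RMATS_JC_COLUMNS) + "\n"
                        + _rmats_row(upstreamEE="150") + "\n")
        with pytest.raises(EventTableParseError, match="line 2"):
            read_event_table(path)

    def test_non_integer_count_reports_line(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("\t".join(RMATS_JC_COLUMNS) + "\n"
                        + _rmats_row(IJC_SAMPLE_1="3,x,1") + "\n")
        with pytest.raises(EventTableParseError, match="line 2"):
            read_event_table(path)

    def test_wrong_header_is_dialect_error(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("foo\tbar\n1\t2\n")
        with pytest.raises(DialectError):
            read_event_table(path)


class TestComputePsi:
    @pytest.mark.parametrize("inc, skp, li, ls, expected", [
        (20, 10, 2.0, 1.0, 50.0),   # length normalisation halves inclusion
        (0, 7, 2.0, 1.0, 0.0),
        (7, 0, 2.0, 1.0, 100.0),
        (30, 10, 1.0, 1.0, 75.0),
    ])
    def test_single_replicate_values(self, inc, skp, li, ls, expected):
        est = compute_psi(_rc([inc], [skp], li, ls))
        assert est.psi_per_replicate[0] == pytest.approx(expected)
        assert est.mean_psi == pytest.approx(expected)

    def test_undefined_replicate_excluded_from_mean(self):
        est = compute_psi(_rc([30, 0], [10, 0], 1.0, 1.0))
        assert est.psi_per_replicate == (75.0, None)
        assert est.mean_psi == pytest.approx(75.0)

    def test_all_zero_is_unquantifiable(self):
        est = compute_psi(_rc([0, 0], [0, 0]))
        assert est.mean_psi is None and not est.quantifiable

    @given(i1=st.integers(0, 500), i2=st.integers(0, 500), s=st.integers(1, 500))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_inclusion(self, i1, i2, s):
        lo, hi = sorted([i1, i2])
        p_lo = compute_psi(_rc([lo], [s])).mean_psi
        p_hi = compute_psi(_rc([hi], [s])).mean_psi
        assert p_lo <= p_hi

    @given(i=st.integers(0, 500), s=st.integers(0, 500),
           scale=st.floats(0.1, 50, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_of_effective_lengths(self, i, s, scale):
        if i == 0 and s == 0:
            return
        base = compute_psi(_rc([i], [s], 2.0, 1.0)).mean_psi
        scaled = compute_psi(_rc([i], [s], 2.0 * scale, 1.0 * scale)).mean_psi
        assert scaled == pytest.approx(base, abs=1e-9)


class TestClassifyPsi:
    @pytest.mark.parametrize("psi, expected", [
        (0.0, InclusionClass.PS),
        (20.0, InclusionClass.PS),     # closed outer bin
        (20.01, InclusionClass.AS),
        (50.0, InclusionClass.AS),
        (79.99, InclusionClass.AS),
        (80.0, InclusionClass.PI),     # closed outer bin
        (80.01, InclusionClass.PI),
        (90.0, InclusionClass.PI),
        (100.0, InclusionClass.PI),
    ])
    def test_boundaries(self, psi, expected):
        assert classify_psi(psi) is expected

    def test_undefined_psi_rejected(self):
        with pytest.raises(ValueError):
            classify_psi(float("nan"))

    def test_classification_total_on_expressed_events(self):
        # any event passing the expression filter has a defined mean PSI
        rc = _rc([6, 6], [0, 0])
        assert filter_expressed([rc], min_count=5) == {"e1"}
        assert classify_psi(compute_psi(rc).mean_psi) is InclusionClass.PI


class TestFilterExpressed:
    def test_all_samples_kept(self):
        assert filter_expressed([_rc([6, 6], [0, 0])], 5, "all_samples") == {"e1"}

    def test_all_samples_strict_inequality(self):
        assert filter_expressed([_rc([6, 5], [0, 0])], 5, "all_samples") == set()

    def test_mean_over_samples(self):
        assert filter_expressed([_rc([20, 0], [0, 0])], 5, "mean_over_samples") == {"e1"}

    def test_both_conditions_considered(self):
        basal = _rc([10, 10], [0, 0], cond=Condition.basal)
        stim = _rc([1, 1], [2, 2], cond=Condition.stimulated)
        assert filter_expressed([basal, stim], 5, "all_samples") == set()

    def test_empty_input(self):
        assert filter_expressed([], 5) == set()


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path):
        events = [SpliceEvent(f"e{i}", "sp", f"g{i}", f"G{i}", EventType.SE,
                              "chr1", "+", 100 + i, 200 + i, 50, 300 + i)
                  for i in range(5)]
        counts = []
        for e in events:
            counts.append(_rc([3, 4], [5, 6], eid=e.event_id, cond=Condition.basal))
            counts.append(_rc([9, 8], [7, 6], eid=e.event_id, cond=Condition.stimulated))
        path = tmp_path / "t.tsv"
        write_event_table(events, counts, [compute_psi(c) for c in counts], path)
        events2, counts2 = read_event_table(path, dialect="internal_tsv")
        assert events2 == events
        assert counts2 == counts

    def test_empty_inputs_header_only(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_event_table([], [], None, path)
        assert len(path.read_text().splitlines()) == 1
        assert read_event_table(path, dialect="internal_tsv") == ([], [])

    def test_simulated_bundle_round_trips(self, small_bundle, tmp_path):
        events = small_bundle.events_source
        counts = (small_bundle.counts[("source", "basal")]
                  + small_bundle.counts[("source", "stimulated")])
        path = tmp_path / "sim.tsv"
        write_event_table(events, counts, None, path)
        events2, counts2 = read_event_table(path, dialect="internal_tsv")
        assert events2 == events
        assert sorted(counts2, key=lambda c: (c.event_id, c.condition.value)) == \
            sorted(counts, key=lambda c: (c.event_id, c.condition.value))
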