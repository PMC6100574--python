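"""InDel event extraction, diagnostic classification, filtering, mapping."""

import numpy as np
import pytest

from indeldiag.align import Alignment, import_alignment
from indeldiag.indelscan import (
    STATUS_DIAGNOSTIC,
    STATUS_POLYMORPHIC,
    STATUS_SHARED,
    STATUS_TERMINAL,
    DiagnosticCall,
    InDelEvent,
    call_indels,
    classify_diagnostic,
    event_to_genome,
    filter_markers,
    merge_marker_regions,
)
from indeldiag.seqio import ConfigError


def scan_oracle(rows: dict[str, str]):
    """Brute-force column scan: maximal runs of identical gap patterns with
    at least one gap.  Independent of the vectorized implementation."""
    ids = list(rows)
    ncols = len(next(iter(rows.values())))
    events = []
    cur_pat, cur_start = None, None
    for c in range(ncols):
        pat = tuple(rows[i][c] == "-" for i in ids)
        key = pat if any(pat) else None
        if key != cur_pat:
            if cur_pat is not None:
                events.append((cur_start + 1, c, dict(zip(ids, cur_pat))))
            cur_pat = key
            cur_start = c
    if cur_pat is not None:
        events.append((cur_start + 1, ncols, dict(zip(ids, cur_pat))))
    return events


def as_tuples(events: list[InDelEvent]):
    return [(e.col_start, e.col_end, e.gapped) for e in events]


class TestCallIndels:
    def test_gapless_alignment_empty(self):
        assert call_indels(import_alignment({"A": "ACGT", "B": "ACGT"})) == []

    def test_single_event(self):
        events = call_indels(import_alignment({"A": "AC---GT", "B": "ACTTTGT"}))
        assert as_tuples(events) == [(3, 5, {"A": True, "B": False})]
        assert events[0].length == 3
        assert not events[0].terminal

    def test_two_events_different_patterns(self):
        events = call_indels(import_alignment({"A": "A--T-G", "B": "ACCTCG"}))
        assert [(e.col_start, e.col_end) for e in events] == [(2, 3), (5, 5)]

    def test_terminal_runs_flagged(self):
        events = call_indels(import_alignment({"A": "--ACGT", "B": "CCAC-T"}))
        assert [(e.col_start, e.terminal) for e in events] == [(1, True), (5, False)]

    def test_agrees_with_bruteforce_oracle_on_random_alignments(self, rng):
        for _ in range(300):
            n_rows = int(rng.integers(2, 5))
            ncols = int(rng.integers(1, 30))
            rows = {
                f"r{i}": "".join(rng.choice(list("AC-"), size=ncols))
                for i in range(n_rows)
            }
            # avoid rows that are entirely gaps (no underlying sequence)
            rows = {k: (v if set(v) != {"-"} else "A" + v[1:]) for k, v in rows.items()}
            aln = Alignment(rows)
            got = [(e.col_start, e.col_end, e.gapped) for e in call_indels(aln)]
            assert got == scan_oracle(rows)

    def test_events_tile_gapped_columns_exactly(self, rng):
        rows = {
            f"r{i}": "".join(rng.choice(list("ACG-"), size=200)) for i in range(3)
        }
        rows = {k: (v if set(v) != {"-"} else "A" + v[1:]) for k, v in rows.items()}
        aln = Alignment(rows)
        events = call_indels(aln)
        covered = set()
        for e in events:
            cols = set(range(e.col_start, e.col_end + 1))
            assert not cols & covered, "events overlap"
            covered |= cols
        gappy = {
            c + 1
            for c in range(aln.col_count)
            if any(r[c] == "-" for r in rows.values())
        }
        assert covered == gappy

    def test_row_base_count_conserved(self, small_truth):
        from indeldiag.align import align_star

        aln = align_star(small_truth.group_set)
        events = call_indels(aln)
        for rec in small_truth.group_set.records():
            row = aln.rows[rec.id]
            in_event = np.zeros(aln.col_count, dtype=bool)
            for e in events:
                in_event[e.col_start - 1 : e.col_end] = True
            bases_in_events = sum(
                1 for c in range(aln.col_count) if in_event[c] and row[c] != "-"
            )
            bases_outside = sum(
                1 for c in range(aln.col_count) if not in_event[c] and row[c] != "-"
            )
            assert bases_in_events + bases_outside == rec.length


class TestClassify:
    def test_one_record_per_group_always_diagnostic(self):
        aln = import_alignment({"A": "AC--GT", "B": "ACTTGT"})
        calls = classify_diagnostic(call_indels(aln), {"A": "G1", "B": "G2"})
        assert calls[0].status == STATUS_DIAGNOSTIC
        assert calls[0].group_alleles == {"G1": "absent", "G2": "present"}

    def test_uniform_groups_diagnostic(self):
        rows = {
            "cw1": "AC--GT", "cw2": "AC--GT",
            "ca1": "ACTTGT", "ca2": "ACTTGT", "ca3": "ACTTGT",
        }
        groups = {r: ("Cw" if r.startswith("cw") else "Ca") for r in rows}
        calls = classify_diagnostic(call_indels(import_alignment(rows)), groups)
        assert [c.status for c in calls] == [STATUS_DIAGNOSTIC]

    def test_within_group_disagreement_polymorphic(self):
        rows = {"ca1": "AC--GT", "ca2": "ACTTGT", "ca3": "ACTTGT"}
        calls = classify_diagnostic(
            call_indels(import_alignment(rows)), {r: "Ca" for r in rows}
        )
        assert [c.status for c in calls] == [STATUS_POLYMORPHIC]

    def test_cross_group_subset_polymorphic(self):
        rows = {
            "cw1": "AC--GT", "cw2": "ACTTGT",
            "ca1": "AC--GT", "ca2": "ACTTGT",
        }
        groups = {r: ("Cw" if r.startswith("cw") else "Ca") for r in rows}
        calls = classify_diagnostic(call_indels(import_alignment(rows)), groups)
        assert [c.status for c in calls] == [STATUS_POLYMORPHIC]

    def test_terminal_status_wins(self):
        calls = classify_diagnostic(
            call_indels(import_alignment({"A": "--ACGT", "B": "CCACGT"})),
            {"A": "G1", "B": "G2"},
        )
        assert [c.status for c in calls] == [STATUS_TERMINAL]

    def test_unmapped_row_is_config_error(self):
        events = call_indels(import_alignment({"A": "AC--GT", "B": "ACTTGT"}))
        with pytest.raises(ConfigError, match="without a group"):
            classify_diagnostic(events, {"A": "G1"})


def _call(length, status, gapped=None, terminal=False) -> DiagnosticCall:
    ev = InDelEvent(
        col_start=1000,
        col_end=1000 + length - 1,
        gapped=gapped or {"A": True, "B": False},
        terminal=terminal,
    )
    return DiagnosticCall(event=ev, status=status, group_alleles={})


class TestFilter:
    def test_strict_length_boundary(self):
        kept = filter_markers([_call(100, STATUS_DIAGNOSTIC)])
        assert kept == []
        kept = filter_markers([_call(101, STATUS_DIAGNOSTIC)])
        assert len(kept) == 1

    def test_347bp_diagnostic_retained(self):
        assert len(filter_markers([_call(347, STATUS_DIAGNOSTIC)])) == 1

    def test_non_diagnostic_excluded(self):
        assert filter_markers([_call(500, STATUS_SHARED)]) == []
        assert filter_markers([_call(500, STATUS_POLYMORPHIC)]) == []

    def test_terminal_excluded(self):
        calls = [_call(500, STATUS_TERMINAL, terminal=True)]
        assert filter_markers(calls) == []
        assert len(filter_markers(calls, exclude_terminal=False,
                                  require_diagnostic=False)) == 1


class TestEventToGenome:
    @pytest.fixture
    def aln(self):
        return import_alignment({"A": "AC---GT", "B": "ACTTTGT"})

    def test_base_row_span(self, aln):
        ev = call_indels(aln)[0]
        assert event_to_genome(ev, "B", aln) == ("span", 3, 5)

    def test_gapped_row_insertion_point(self, aln):
        ev = call_indels(aln)[0]
        assert event_to_genome(ev, "A", aln) == ("insertion", 2, 3)

    def test_event_at_alignment_start(self):
        aln = import_alignment({"A": "--CGT", "B": "TTCGT"})
        ev = call_indels(aln)[0]
        assert event_to_genome(ev, "A", aln) == ("insertion", 0, 1)

    def test_missing_record_key_error(self, aln):
        ev = call_indels(aln)[0]
        with pytest.raises(KeyError):
            event_to_genome(ev, "Z", aln)


class TestMergeRegions:
    def test_nearby_seeds_merge_and_absorb_small_events(self):
        # two >100 bp diagnostic events 120 columns apart, one small event between
        gap = "-"
        rows = {
            "A": "X" * 500 + gap * 150 + "X" * 50 + gap * 3 + "X" * 67 + gap * 120 + "X" * 500,
            "B": "X" * 500 + "X" * 150 + "X" * 50 + "X" * 3 + "X" * 67 + "X" * 120 + "X" * 500,
        }
        rows = {k: v.replace("X", "A") for k, v in rows.items()}
        aln = Alignment(rows)
        calls = classify_diagnostic(call_indels(aln), {"A": "G1", "B": "G2"})
        regions = merge_marker_regions(calls)
        assert len(regions) == 1
        assert len(regions[0].events) == 3

    def test_bed_export_is_zero_based_half_open(self, tmp_path):
        from indeldiag.indelscan import write_markers_bed

        rows = {
            "A": "ACGTACGTAC" + "-" * 120 + "ACGTACGTAC",
            "B": "ACGTACGTAC" + "G" * 120 + "ACGTACGTAC",
        }
        aln = Alignment(rows)
        calls = classify_diagnostic(call_indels(aln), {"A": "G1", "B": "G2"})
        regions = merge_marker_regions(calls)
        path = tmp_path / "markers.bed"
        write_markers_bed(regions, aln, "B", path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("#") and "0-based" in lines[0]
        chrom, start, end, name = lines[1].split("\t")
        # 1-based inclusive span 11..130 becomes 0-based half-open 10..130
        assert (chrom, int(start), int(end)) == ("B", 10, 130)

    def test_distant_seeds_stay_separate(self):
        rows = {
            "A": "A" * 500 + "-" * 150 + "A" * 800 + "-" * 120 + "A" * 500,
            "B": "A" * 2070,
        }
        calls = classify_diagnostic(call_indels(Alignment(rows)), {"A": "G1", "B": "G2"})
        regions = merge_marker_regions(calls)
        assert len(regions) == 2
        assert [r.marker_id for r in regions] == ["marker1", "marker2"]
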