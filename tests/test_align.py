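"""Pairwise and star alignment: invariants, oracle agreement, planted indels."""

import numpy as np
import pytest

from indeldiag.align import (
    Alignment,
    AlignmentError,
    align_pair,
    align_pair_seqs,
    align_star,
    find_anchors,
    gotoh_align,
    import_alignment,
    left_shift_gaps,
)
from indeldiag.seqio import FormatError, GenomeRecord, SpeciesGroupSet, write_alignment_fasta

from conftest import mutate, random_seq

MATCH, MISMATCH, OPEN, EXTEND = 1, -2, 5, 1


def oracle_score(x: str, y: str) -> int:
    """Independent exhaustive Gotoh DP, score only.

    Same model as the implementation: +1/−2 per aligned pair, a gap of
    length L costs OPEN + L*EXTEND.  Written as a plain three-matrix sweep
    with no shortcuts, bands or anchors.
    """
    n, m = len(x), len(y)
    NEG = float("-inf")
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = -(OPEN + EXTEND * i)
    for j in range(1, m + 1):
        Y[0, j] = -(OPEN + EXTEND * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if x[i - 1] == y[j - 1] else MISMATCH
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(
                M[i - 1, j] - OPEN - EXTEND,
                X[i - 1, j] - EXTEND,
                Y[i - 1, j] - OPEN - EXTEND,
            )
            Y[i, j] = max(
                M[i, j - 1] - OPEN - EXTEND,
                Y[i, j - 1] - EXTEND,
                X[i, j - 1] - OPEN - EXTEND,
            )
    return int(max(M[n, m], X[n, m], Y[n, m]))


def score_rows(gx: str, gy: str) -> int:
    """Score a gapped row pair under the alignment model."""
    total = 0
    in_gap_x = in_gap_y = False
    for a, b in zip(gx, gy):
        if a == "-" and b == "-":
            raise AssertionError("all-gap column")
        if a == "-":
            total -= (OPEN + EXTEND) if not in_gap_x else EXTEND
            in_gap_x, in_gap_y = True, False
        elif b == "-":
            total -= (OPEN + EXTEND) if not in_gap_y else EXTEND
            in_gap_y, in_gap_x = True, False
        else:
            total += MATCH if a == b else MISMATCH
            in_gap_x = in_gap_y = False
    return total


class TestImport:
    def test_minimal_gapped_alignment(self):
        aln = import_alignment({"A": "ACG-T", "B": "ACGGT"})
        assert aln.col_count == 5
        assert aln.degapped("A") == "ACGT"

    def test_unequal_rows_rejected(self):
        with pytest.raises(FormatError, match="unequal"):
            import_alignment({"A": "ACGT", "B": "AC"})

    def test_row_genome_mismatch_rejected(self):
        gs = SpeciesGroupSet(
            groups={"G": [GenomeRecord(id="A", species_group="G", seq="ACGA")]}
        )
        with pytest.raises(FormatError, match="reproduce"):
            import_alignment({"A": "ACG-T"}, gs)

    def test_export_import_round_trip(self, tmp_path):
        rows = {"A": "ACG--TTA", "B": "ACGGGTTA", "C": "ACG--T-A"}
        path = tmp_path / "msa.fasta"
        write_alignment_fasta(rows, path)
        back = import_alignment(str(path))
        assert back.rows == rows


class TestPairwise:
    def test_self_alignment_gapless(self):
        a = GenomeRecord(id="a", species_group="G", seq="ACGTACGTAA")
        b = GenomeRecord(id="b", species_group="G", seq="ACGTACGTAA")
        aln = align_pair(a, b)
        assert aln.rows["a"] == aln.rows["b"] == "ACGTACGTAA"

    def test_simple_deletion(self):
        gx, gy = align_pair_seqs("AAATTTCCC", "AAACCC")
        assert gx == "AAATTTCCC"
        assert gy.count("-") == 3
        # one contiguous gap run
        assert "-" * 3 in gy and gy.replace("---", "") == "AAACCC"

    def test_round_trip_and_no_allgap_columns(self, rng):
        x = random_seq(rng, 300)
        y = mutate(rng, x, 0.02, 0.01)
        gx, gy = align_pair_seqs(x, y)
        assert gx.replace("-", "") == x
        assert gy.replace("-", "") == y
        assert not any(a == b == "-" for a, b in zip(gx, gy))

    def test_matches_exhaustive_oracle_on_small_pairs(self, rng):
        """The aligner is exact below the anchoring threshold: its score
        equals an independent exhaustive DP on random related pairs."""
        for _ in range(40):
            n = int(rng.integers(5, 120))
            x = random_seq(rng, n)
            y = mutate(rng, x, 0.1, 0.05)
            gx, gy = align_pair_seqs(x, y)
            assert score_rows(gx, gy) == oracle_score(x, y)

    def test_left_shift_preserves_content_and_score(self, rng):
        for _ in range(20):
            x = random_seq(rng, 80)
            y = mutate(rng, x, 0.05, 0.08)
            _, gx, gy = gotoh_align(x, y)
            sx, sy = left_shift_gaps(gx, gy)
            assert sx.replace("-", "") == x and sy.replace("-", "") == y
            assert score_rows(sx, sy) == score_rows(gx, gy)

    def test_planted_large_insertion_recovered(self, rng):
        """A 347 bp insertion planted in a 50 kb pair appears as exactly one
        gap run of length 347."""
        base = random_seq(rng, 50_000)
        ins = random_seq(rng, 347)
        other = base[:25_000] + ins + base[25_000:]
        gx, gy = align_pair_seqs(base, other)
        import re

        gap_runs = [len(m.group()) for m in re.finditer(r"-+", gx)]
        assert gap_runs == [347]
        assert "-" not in gy

    def test_uncollinear_large_pair_rejected(self, rng):
        # no shared unique anchors and too large for exhaustive DP
        x = random_seq(rng, 9000)
        y = random_seq(np.random.default_rng(999), 9000)
        with pytest.raises(AlignmentError, match="collinearity"):
            align_pair_seqs(x, y)

    def test_anchors_are_collinear_and_nonoverlapping(self, rng):
        x = random_seq(rng, 5000)
        y = mutate(rng, x, 0.01, 0.01)
        anchors = find_anchors(x, y)
        assert anchors
        for a, b in zip(anchors, anchors[1:]):
            assert b.pos_a >= a.pos_a + a.length
            assert b.pos_b >= a.pos_b + a.length


class TestStar:
    def _gs(self, seqs: dict[str, tuple[str, str]]) -> SpeciesGroupSet:
        groups: dict[str, list[GenomeRecord]] = {}
        for rid, (g, s) in seqs.items():
            groups.setdefault(g, []).append(
                GenomeRecord(id=rid, species_group=g, seq=s)
            )
        return SpeciesGroupSet(groups=groups)

    def test_identical_records_gapless(self, rng):
        s = random_seq(rng, 500)
        gs = self._gs({"a": ("G1", s), "b": ("G1", s), "c": ("G2", s)})
        aln = align_star(gs)
        assert all(row == s for row in aln.rows.values())

    def test_planted_deletion_single_row_gap(self, rng):
        base = random_seq(rng, 3000)
        deleted = base[:1500] + base[1600:]  # 100 bp deletion
        gs = self._gs(
            {"a": ("G1", base), "b": ("G1", base), "c": ("G2", deleted)}
        )
        aln = align_star(gs)
        assert "-" not in aln.rows["a"]
        assert "-" not in aln.rows["b"]
        import re

        runs = [len(m.group()) for m in re.finditer(r"-+", aln.rows["c"])]
        assert runs == [100]

    def test_projection_round_trip(self, small_truth):
        aln = align_star(small_truth.group_set)
        for rec in small_truth.group_set.records():
            assert aln.degapped(rec.id) == rec.seq

    def test_reference_defaults_to_longest_of_first_group(self, small_truth):
        aln = align_star(small_truth.group_set)
        ref = max(
            small_truth.group_set.groups["Cw"], key=lambda r: (r.length, r.id)
        )
        assert "-" not in aln.rows[ref.id] or aln.degapped(ref.id) == ref.seq
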