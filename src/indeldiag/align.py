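"""Collinear alignment of closely related organelle genomes.

Two routes produce an :class:`Alignment`:

* :func:`import_alignment` — trust an externally computed aligned-FASTA
  (e.g. from Clustal Omega or MAFFT) after verifying its invariants.
* :func:`align_pair` / :func:`align_star` — a built-in anchor-and-fill
  aligner: unique shared k-mers are chained into the heaviest collinear
  chain, and the short inter-anchor segments are aligned by global affine
  dynamic programming (match +1, mismatch −2, gap open −5, gap extend −1;
  a gap of length L costs open + L·extend).

The built-in aligner assumes the genomes are collinear (no inversions or
rearrangements) — adequate for conspecific / congeneric plastomes.  Gap
placement is deterministic: DP ties resolve to a fixed traceback order and
indels are subsequently left-shifted within repeats, so event coordinates
do not depend on dict ordering or hashing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .seqio import GAP, FormatError, GenomeRecord, SpeciesGroupSet

MATCH = 1
MISMATCH = -2
GAP_OPEN = 5  # charged once per gap, in addition to per-column extension
GAP_EXTEND = 1
DEFAULT_K = 15
DEFAULT_BAND = 64

# anchor-free full-DP fallback is capped at this many cells
_MAX_FALLBACK_CELLS = 4_000_000

NEG_INF = float("-inf")


class AlignmentError(ValueError):
    """Raised when sequences cannot be aligned collinearly."""


class Alignment:
    """A gapped matrix over N records with column <-> genome coordinate maps.

    Rows are gapped strings of identical length; removing gaps from any row
    reproduces that record's sequence exactly.  Columns are addressed
    1-based inclusive on the external surface.
    """

    def __init__(self, rows: Mapping[str, str]):
        if not rows:
            raise FormatError("alignment has no rows")
        lengths = {len(r) for r in rows.values()}
        if len(lengths) != 1:
            raise FormatError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        self.rows: dict[str, str] = dict(rows)
        self.col_count: int = lengths.pop()
        self._matrix: np.ndarray | None = None
        self._col_to_pos: dict[str, np.ndarray] = {}

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def degapped(self, record_id: str) -> str:
        return self.rows[record_id].replace(GAP, "")

    def matrix(self) -> np.ndarray:
        """(N, col_count) uint8 byte matrix in row order of :attr:`ids`."""
        if self._matrix is None:
            self._matrix = np.frombuffer(
                "".join(self.rows.values()).encode(), dtype=np.uint8
            ).reshape(len(self.rows), self.col_count)
        return self._matrix

    def col_to_pos(self, record_id: str) -> np.ndarray:
        """Per column: 1-based genome position of the base there, or 0 at gaps."""
        if record_id not in self._col_to_pos:
            row = np.frombuffer(self.rows[record_id].encode(), dtype=np.uint8)
            isbase = row != ord(GAP)
            pos = np.cumsum(isbase)
            pos[~isbase] = 0
            self._col_to_pos[record_id] = pos.astype(np.int64)
        return self._col_to_pos[record_id]

    def last_pos_before(self, record_id: str) -> np.ndarray:
        """Per column: 1-based position of the last base at or before it (0 if none)."""
        row = np.frombuffer(self.rows[record_id].encode(), dtype=np.uint8)
        isbase = row != ord(GAP)
        return np.cumsum(isbase).astype(np.int64)

    def slice_cols(self, col_start: int, col_end: int) -> "Alignment":
        """Sub-alignment over 1-based inclusive column range."""
        return Alignment(
            {rid: row[col_start - 1 : col_end] for rid, row in self.rows.items()}
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({len(self.rows)} rows x {self.col_count} cols)"


def import_alignment(
    source: Mapping[str, str] | str,
    group_set: SpeciesGroupSet | None = None,
) -> Alignment:
    """Build an Alignment from aligned-FASTA rows, verifying invariants.

    If ``group_set`` is given, every row id must name a loaded genome and the
    degapped row must reproduce its sequence exactly.
    """
    if isinstance(source, Mapping):
        rows = dict(source)
    else:
        from .seqio import read_alignment_fasta

        rows = read_alignment_fasta(source)
    aln = Alignment(rows)
    if group_set is not None:
        for rid in aln.ids:
            try:
                rec = group_set.record(rid)
            except KeyError:
                raise FormatError(f"alignment row {rid!r} is not a loaded genome")
            if aln.degapped(rid) != rec.seq:
                raise FormatError(
                    f"alignment row {rid!r} does not reproduce the genome sequence"
                )
    return aln


# ---------------------------------------------------------------------------
# pairwise dynamic programming (Gotoh, affine gaps)
# ---------------------------------------------------------------------------

def gotoh_align(
    x: str,
    y: str,
    *,
    band: int | None = None,
) -> tuple[int, str, str]:
    """Optimal global alignment of two sequences; returns (score, gapped_x, gapped_y).

    Affine model: aligned pair scores +1/−2; a gap of length L scores
    −(GAP_OPEN + L·GAP_EXTEND).  With ``band`` set, cells with |i−j| beyond
    max(band, |len difference|+1) are pruned (heuristic for long segments).
    Ties in traceback prefer the aligned-pair state, then gap-in-y, then
    gap-in-x, which keeps the output deterministic.
    """
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        return (
            -(GAP_OPEN + GAP_EXTEND * (n + m)) if (n or m) else 0,
            x + GAP * m,
            GAP * n + y,
        )
    b = None
    if band is not None:
        b = max(band, abs(n - m) + 1)

    open_cost = GAP_OPEN + GAP_EXTEND
    # M: x[i] aligned to y[j]; X: gap in y (consumes x); Y: gap in x (consumes y)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(GAP_OPEN + GAP_EXTEND * i)
    for j in range(1, m + 1):
        Y[0][j] = -(GAP_OPEN + GAP_EXTEND * j)
    for i in range(1, n + 1):
        xi = x[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        lo, hi = 1, m
        if b is not None:
            lo = max(1, i - b)
            hi = min(m, i + b)
        for j in range(lo, hi + 1):
            s = MATCH if xi == y[j - 1] else MISMATCH
            d = Mp[j - 1]
            if Xp[j - 1] > d:
                d = Xp[j - 1]
            if Yp[j - 1] > d:
                d = Yp[j - 1]
            Mi[j] = d + s if d != NEG_INF else NEG_INF
            # gap in y, consuming x[i-1]
            best = Mp[j] - open_cost
            t = Xp[j] - GAP_EXTEND
            if t > best:
                best = t
            t = Yp[j] - open_cost
            if t > best:
                best = t
            Xi[j] = best
            # gap in x, consuming y[j-1]
            best = Mi[j - 1] - open_cost
            t = Yi[j - 1] - GAP_EXTEND
            if t > best:
                best = t
            t = Xi[j - 1] - open_cost
            if t > best:
                best = t
            Yi[j] = best

    # traceback; fixed preference at ties: M, then X, then Y
    i, j = n, m
    final = max(M[n][m], X[n][m], Y[n][m])
    if M[n][m] == final:
        state = "M"
    elif X[n][m] == final:
        state = "X"
    else:
        state = "Y"
    gx: list[str] = []
    gy: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = MATCH if x[i - 1] == y[j - 1] else MISMATCH
            target = M[i][j] - s
            if M[i - 1][j - 1] == target:
                nxt = "M"
            elif X[i - 1][j - 1] == target:
                nxt = "X"
            else:
                nxt = "Y"
            gx.append(x[i - 1])
            gy.append(y[j - 1])
            i -= 1
            j -= 1
            state = nxt
        elif state == "X":
            if i == 0:  # pragma: no cover - unreachable by construction
                state = "Y"
                continue
            val = X[i][j]
            if M[i - 1][j] - open_cost == val:
                nxt = "M"
            elif X[i - 1][j] - GAP_EXTEND == val:
                nxt = "X"
            else:
                nxt = "Y"
            gx.append(x[i - 1])
            gy.append(GAP)
            i -= 1
            state = nxt
        else:  # Y
            val = Y[i][j]
            if M[i][j - 1] - open_cost == val:
                nxt = "M"
            elif Y[i][j - 1] - GAP_EXTEND == val:
                nxt = "Y"
            else:
                nxt = "X"
            gx.append(GAP)
            gy.append(y[j - 1])
            j -= 1
            state = nxt
    score = max(M[n][m], X[n][m], Y[n][m])
    return int(score), "".join(reversed(gx)), "".join(reversed(gy))


def left_shift_gaps(gx: str, gy: str) -> tuple[str, str]:
    """Shift gap runs as far left as possible without changing the score.

    Canonicalizes indel placement inside repeats so event coordinates are
    stable across equivalent optimal alignments.
    """
    ax, ay = list(gx), list(gy)

    def shift(a: list[str], b: list[str]) -> bool:
        moved = False
        i = 0
        n = len(a)
        while i < n:
            if a[i] != GAP:
                i += 1
                continue
            s = i
            while i < n and a[i] == GAP:
                i += 1
            e = i - 1  # gap run [s, e] in a
            while s > 0 and a[s - 1] != GAP and b[s - 1] != GAP:
                c = a[s - 1]
                # score-neutral iff match status of c is unchanged by the move
                if (c == b[s - 1]) != (c == b[e]):
                    break
                a[s - 1], a[e] = GAP, c
                s -= 1
                e -= 1
                moved = True
            # strip columns where both rows became gapped (cannot happen here,
            # guarded by the b[s-1] != GAP condition)
        return moved

    for _ in range(64):  # fixpoint; tiny in practice
        if not (shift(ax, ay) | shift(ay, ax)):
            break
    return "".join(ax), "".join(ay)


# ---------------------------------------------------------------------------
# anchors
# ---------------------------------------------------------------------------

def _unique_kmer_index(s: str, k: int) -> dict[str, int]:
    idx: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(s) - k + 1):
        km = s[i : i + k]
        if km in dup:
            continue
        if km in idx:
            del idx[km]
            dup.add(km)
        else:
            idx[km] = i
    return idx


def _lis_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain strictly increasing in both coordinates.

    ``pairs`` is sorted by first coordinate (all distinct); patience LIS on
    the second coordinate with parent pointers.
    """
    import bisect

    tails: list[int] = []  # j values
    tails_idx: list[int] = []
    parent = [-1] * len(pairs)
    for idx, (_, j) in enumerate(pairs):
        p = bisect.bisect_left(tails, j)
        if p == len(tails):
            tails.append(j)
            tails_idx.append(idx)
        else:
            tails[p] = j
            tails_idx[p] = idx
        parent[idx] = tails_idx[p - 1] if p > 0 else -1
    if not tails_idx:
        return []
    chain = []
    cur = tails_idx[-1]
    while cur != -1:
        chain.append(pairs[cur])
        cur = parent[cur]
    chain.reverse()
    return chain


@dataclass(frozen=True)
class Anchor:
    """Exact-match block: x[pos_a : pos_a+length] == y[pos_b : pos_b+length]."""

    pos_a: int
    pos_b: int
    length: int


def find_anchors(x: str, y: str, k: int = DEFAULT_K) -> list[Anchor]:
    """Collinear chain of merged unique shared k-mer anchors (0-based)."""
    ix = _unique_kmer_index(x, k)
    iy = _unique_kmer_index(y, k)
    pairs = sorted((i, iy[km]) for km, i in ix.items() if km in iy)
    chain = _lis_chain(pairs)
    if not chain:
        return []
    # merge consecutive k-mers into maximal blocks
    blocks: list[list[int]] = []
    for i, j in chain:
        if blocks and i == blocks[-1][0] + blocks[-1][2] - k + 1 and j == blocks[-1][1] + blocks[-1][2] - k + 1:
            blocks[-1][2] += 1
        else:
            blocks.append([i, j, k])
    # enforce non-overlap between successive blocks (trim from the left)
    anchors: list[Anchor] = []
    for i, j, ln in blocks:
        if anchors:
            prev = anchors[-1]
            d = max(prev.pos_a + prev.length - i, prev.pos_b + prev.length - j, 0)
            i += d
            j += d
            ln -= d
        if ln >= k:
            anchors.append(Anchor(i, j, ln))
    return anchors


def _seg_align(sx: str, sy: str, band: int) -> tuple[str, str]:
    """Align an inter-anchor segment; cheap shortcuts for the common cases."""
    if not sx and not sy:
        return "", ""
    if not sx:
        return GAP * len(sy), sy
    if not sy:
        return sx, GAP * len(sx)
    if sx == sy:
        return sx, sy
    if len(sx) == len(sy):
        ham = sum(a != b for a, b in zip(sx, sy))
        # direct pairing is optimal when too few mismatches to pay two gaps
        if 3 * ham < 2 * GAP_OPEN + 2 * GAP_EXTEND * len(sx):
            return sx, sy
    use_band = band if len(sx) * len(sy) > 250_000 else None
    _, gx, gy = gotoh_align(sx, sy, band=use_band)
    return gx, gy


def align_pair(
    a: GenomeRecord | str,
    b: GenomeRecord | str,
    *,
    k: int = DEFAULT_K,
    band: int = DEFAULT_BAND,
) -> Alignment:
    """Global alignment of two genomes by anchor chaining + banded DP fill.

    Small pairs (≤ ~2 kb of DP) bypass anchoring and are solved exactly, so
    the result matches an exhaustive Needleman–Wunsch/Gotoh oracle there.
    Raises :class:`AlignmentError` when no anchors exist and the pair is too
    large for exhaustive DP ("insufficient collinearity").
    """
    ida, x = (a.id, a.seq) if isinstance(a, GenomeRecord) else ("seq_a", a.upper())
    idb, y = (b.id, b.seq) if isinstance(b, GenomeRecord) else ("seq_b", b.upper())
    if not x or not y:
        raise AlignmentError("cannot align empty sequences")
    if ida == idb:
        raise FormatError("cannot align a record with itself under one id")
    gx, gy = align_pair_seqs(x, y, k=k, band=band)
    return Alignment({ida: gx, idb: gy})


def align_pair_seqs(
    x: str, y: str, *, k: int = DEFAULT_K, band: int = DEFAULT_BAND
) -> tuple[str, str]:
    """String-level core of :func:`align_pair`; returns the two gapped rows."""
    if len(x) * len(y) <= _MAX_FALLBACK_CELLS:
        _, gx, gy = gotoh_align(x, y)
        return left_shift_gaps(gx, gy)
    anchors = find_anchors(x, y, k=k)
    if not anchors:
        raise AlignmentError(
            "insufficient collinearity: no shared unique anchors and the pair "
            "is too large for exhaustive DP"
        )
    gx_parts: list[str] = []
    gy_parts: list[str] = []
    pa = pb = 0
    for anc in anchors:
        sx, sy = x[pa : anc.pos_a], y[pb : anc.pos_b]
        seg = _seg_align(sx, sy, band)
        gx_parts.append(seg[0])
        gy_parts.append(seg[1])
        block = x[anc.pos_a : anc.pos_a + anc.length]
        gx_parts.append(block)
        gy_parts.append(block)
        pa = anc.pos_a + anc.length
        pb = anc.pos_b + anc.length
    seg = _seg_align(x[pa:], y[pb:], band)
    gx_parts.append(seg[0])
    gy_parts.append(seg[1])
    gx, gy = "".join(gx_parts), "".join(gy_parts)
    return left_shift_gaps(gx, gy)


# ---------------------------------------------------------------------------
# star alignment
# ---------------------------------------------------------------------------

def _pairwise_profile(
    gr: str, go: str, ref_len: int
) -> tuple[dict[int, str], list[str]]:
    """Decompose a (reference, other) pairwise alignment.

    Returns ``(insertions, aligned)`` where ``insertions[j]`` is the string
    of other-record bases inserted at junction j (between reference positions
    j and j+1; j = 0 .. ref_len), and ``aligned[p]`` is the other-record
    character aligned to reference base p+1 ('-' for a deletion).
    """
    ins: dict[int, str] = {}
    aligned = [GAP] * ref_len
    rpos = 0
    buf: list[str] = []
    for cr, co in zip(gr, go):
        if cr == GAP:
            if co != GAP:
                buf.append(co)
        else:
            if buf:
                ins[rpos] = ins.get(rpos, "") + "".join(buf)
                buf = []
            aligned[rpos] = co
            rpos += 1
    if buf:
        ins[ref_len] = ins.get(ref_len, "") + "".join(buf)
    return ins, aligned


def align_star(
    group_set: SpeciesGroupSet,
    reference_id: str | None = None,
    *,
    k: int = DEFAULT_K,
    band: int = DEFAULT_BAND,
) -> Alignment:
    """Multiple alignment by pairwise-to-reference projection.

    Every non-reference record is aligned to the reference with
    :func:`align_pair`; insertions relative to the reference are merged into
    a common column space (insertions at the same junction are left-
    justified against each other).  The reference defaults to the longest
    record of the first group.
    """
    records = list(group_set.records())
    if len(records) < 2:
        raise FormatError("star alignment requires at least two records")
    if reference_id is None:
        first_group = group_set.group_labels[0]
        reference_id = max(
            group_set.groups[first_group], key=lambda r: (r.length, r.id)
        ).id
    ref = group_set.record(reference_id)
    others = [r for r in records if r.id != reference_id]

    profiles: dict[str, tuple[dict[int, str], list[str]]] = {}
    for rec in others:
        gx, gy = align_pair_seqs(ref.seq, rec.seq, k=k, band=band)
        profiles[rec.id] = _pairwise_profile(gx, gy, ref.length)

    width = [0] * (ref.length + 1)
    for ins, _ in profiles.values():
        for j, s in ins.items():
            if len(s) > width[j]:
                width[j] = len(s)

    rows: dict[str, list[str]] = {reference_id: []}
    for rid in profiles:
        rows[rid] = []
    ref_row = rows[reference_id]
    for j in range(ref.length + 1):
        w = width[j]
        if w:
            ref_row.append(GAP * w)
            for rid, (ins, _) in profiles.items():
                s = ins.get(j, "")
                rows[rid].append(s + GAP * (w - len(s)))
        if j < ref.length:
            ref_row.append(ref.seq[j])
            for rid, (_, aligned) in profiles.items():
                rows[rid].append(aligned[j])
    # preserve the record order of the group set
    ordered = {r.id: "".join(rows[r.id]) for r in records}
    return Alignment(ordered)
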