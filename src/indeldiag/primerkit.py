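"""Flanking primer design for diagnostic InDel markers.

Candidates are enumerated from alignment windows flanking the marker region
in which every genome carries the identical unambiguous base — a primer in
such a window binds every record perfectly, so the amplicon length (not the
amplification itself) is what separates the species.  Candidates are
filtered by length, melting temperature, GC content, homopolymer and a
lightweight 3'-self-complementarity screen; each primer must bind exactly
once per genome; and a pair is reported only when its per-group product
sizes are separable on a gel (min inter-group gap ≥ max(10 bp, 5% of the
smaller product)), comparing group size *ranges* because allelic
within-group variants (e.g. 249/250 bp) are legitimate.

Melting temperatures use nearest-neighbor thermodynamics (SantaLucia
unified parameters via Biopython) at 50 mM monovalent salt and 0.5 µM
total oligo, with the Wallace 2(A+T)+4(G+C) rule available as a fallback
mode for quick manual arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import MeltingTemp as mt

from .align import Alignment
from .indelscan import MarkerRegion
from .ispcr import DEFAULT_MAX_PRODUCT, amplify, find_sites
from .seqio import GAP, SpeciesGroupSet, revcomp


@dataclass
class PrimerConstraints:
    """Design windows; defaults bracket typical plastome genotyping primers
    (17–27 nt, Tm 48–65 °C around a 55 °C annealing protocol, GC 30–70%)."""

    len_min: int = 17
    len_max: int = 27
    tm_min: float = 48.0
    tm_max: float = 65.0
    gc_min: float = 30.0
    gc_max: float = 70.0
    max_homopolymer: int = 5
    max_product_size: int = DEFAULT_MAX_PRODUCT
    flank_search: int = 300  # how far from the marker to look for windows
    min_separation_bp: int = 10
    min_separation_frac: float = 0.05

    def __post_init__(self) -> None:
        for lo, hi in (
            (self.len_min, self.len_max),
            (self.tm_min, self.tm_max),
            (self.gc_min, self.gc_max),
        ):
            if lo > hi:
                raise ValueError(f"constraint range inverted: {lo} > {hi}")


@dataclass
class PrimerPair:
    marker_id: str
    forward: str  # 5'->3', top strand
    reverse: str  # 5'->3', bottom strand
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    product_sizes: dict[str, list[int]] = field(default_factory=dict)  # record -> sizes
    forward_col: int = 0  # 1-based alignment column of the forward window start

    def group_sizes(self, group_map: dict[str, str]) -> dict[str, set[int]]:
        out: dict[str, set[int]] = {}
        for rid, sizes in self.product_sizes.items():
            out.setdefault(group_map[rid], set()).update(sizes)
        return out


def gc_content(seq: str) -> float:
    """GC percentage; ambiguity codes count toward length but not G+C."""
    s = seq.upper()
    if not s:
        raise ValueError("empty sequence")
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def melting_temp(
    seq: str,
    *,
    mode: str = "nn",
    na_mM: float = 50.0,
    oligo_uM: float = 0.5,
) -> float:
    """Primer melting temperature in °C.

    ``mode="nn"``: nearest-neighbor thermodynamics, SantaLucia unified
    parameters, with the SantaLucia (1998) entropic salt correction at
    ``na_mM`` monovalent cation and ``oligo_uM`` total oligonucleotide
    (split equally between the two strands).  ``mode="wallace"``: the
    2(A+T) + 4(G+C) rule.
    """
    s = seq.upper()
    if not 8 <= len(s) <= 40:
        raise ValueError("melting_temp expects 8-40 nt")
    if mode == "wallace":
        return float(mt.Tm_Wallace(s))
    if mode != "nn":
        raise ValueError(f"unknown Tm mode {mode!r}")
    half_nM = oligo_uM * 1000.0 / 2.0
    return float(
        mt.Tm_NN(s, Na=na_mM, dnac1=half_nM, dnac2=half_nM, saltcorr=5)
    )


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def has_self_complementary_tail(seq: str, run: int = 6) -> bool:
    """True when the 3'-terminal ``run`` bases are self-reverse-complementary
    (a primer-dimer-prone palindromic 3' end)."""
    tail = seq[-run:]
    return len(tail) == run and tail == revcomp(tail)


def count_exact_sites(primer: str, genome, *, max_mismatch: int = 0) -> int:
    """Number of binding sites on both strands (3'-terminal 3 nt exact)."""
    return len(find_sites(primer, genome, max_mismatch=max_mismatch))


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def conserved_mask(alignment: Alignment) -> np.ndarray:
    """Boolean per column: every row carries the identical A/C/G/T base."""
    mat = alignment.matrix()
    same = (mat == mat[0]).all(axis=0)
    unambiguous = np.isin(mat[0], np.frombuffer(b"ACGT", dtype=np.uint8))
    return same & unambiguous


def _candidate_windows(
    mask: np.ndarray,
    consensus: str,
    lo: int,
    hi: int,
    constraints: PrimerConstraints,
    *,
    nearest: str,
) -> list[tuple[int, int]]:
    """(start, length) 0-based candidate windows inside conserved runs of
    mask[lo:hi], ordered nearest-first to the marker edge."""
    cands: list[tuple[int, int]] = []
    region = mask[lo:hi]
    if not region.any():
        return []
    # maximal conserved runs
    idx = np.flatnonzero(region)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([0], breaks + 1))
    run_ends = np.concatenate((breaks, [len(idx) - 1]))
    for rs, re_ in zip(run_starts, run_ends):
        s0, e0 = int(idx[rs]) + lo, int(idx[re_]) + lo  # inclusive columns
        run_len = e0 - s0 + 1
        if run_len < constraints.len_min:
            continue
        for start in range(s0, e0 - constraints.len_min + 2):
            max_len = min(constraints.len_max, e0 - start + 1)
            for length in range(constraints.len_min, max_len + 1):
                cands.append((start, length))
    if nearest == "right":  # left flank: prefer windows ending near the marker
        cands.sort(key=lambda c: (-(c[0] + c[1]), c[0], c[1]))
    else:  # right flank: prefer windows starting near the marker
        cands.sort(key=lambda c: (c[0], c[1]))
    return cands


def _passes(seq: str, constraints: PrimerConstraints) -> tuple[bool, float, float]:
    gc = gc_content(seq)
    if not constraints.gc_min <= gc <= constraints.gc_max:
        return False, 0.0, gc
    if max_homopolymer_run(seq) > constraints.max_homopolymer:
        return False, 0.0, gc
    if has_self_complementary_tail(seq):
        return False, 0.0, gc
    tm = melting_temp(seq)
    if not constraints.tm_min <= tm <= constraints.tm_max:
        return False, tm, gc
    return True, tm, gc


def separability_gap(group_sizes: dict[str, set[int]]) -> int | None:
    """Smallest between-group band distance, or None with <2 groups."""
    labels = list(group_sizes)
    if len(labels) < 2 or any(not v for v in group_sizes.values()):
        return None
    gap = None
    for i, ga in enumerate(labels):
        for gb in labels[i + 1 :]:
            d = min(abs(a - b) for a in group_sizes[ga] for b in group_sizes[gb])
            gap = d if gap is None else min(gap, d)
    return gap


def design_pairs(
    marker: MarkerRegion,
    alignment: Alignment,
    group_set: SpeciesGroupSet,
    constraints: PrimerConstraints | None = None,
    *,
    max_pairs: int = 5,
    max_candidates_per_side: int = 600,
) -> list[PrimerPair]:
    """Design ranked primer pairs flanking a marker region.

    Returns an empty list for an undesignable marker (no conserved flank
    long enough, or no pair satisfying specificity and separability).
    Ranking: |Tm_f − Tm_r|, then |mean Tm − 60|, then leftmost forward
    window, then lexicographic sequences — total and deterministic.
    """
    constraints = constraints or PrimerConstraints()
    mask = conserved_mask(alignment)
    mat = alignment.matrix()
    consensus = mat[0].tobytes().decode()

    left_lo = max(0, marker.col_start - 1 - constraints.flank_search)
    left_hi = marker.col_start - 1  # exclusive of the marker itself
    right_lo = marker.col_end
    right_hi = min(alignment.col_count, marker.col_end + constraints.flank_search)

    fwd_wins = _candidate_windows(
        mask, consensus, left_lo, left_hi, constraints, nearest="right"
    )[:max_candidates_per_side]
    rev_wins = _candidate_windows(
        mask, consensus, right_lo, right_hi, constraints, nearest="left"
    )[:max_candidates_per_side]
    if not fwd_wins or not rev_wins:
        return []

    records = list(group_set.records())
    group_map = group_set.group_map()

    def window_seq(start: int, length: int) -> str:
        return consensus[start : start + length]

    def specific(seq: str) -> bool:
        return all(count_exact_sites(seq, rec) == 1 for rec in records)

    fwd_cands: list[tuple[str, float, float, int]] = []
    for start, length in fwd_wins:
        seq = window_seq(start, length)
        ok, tm, gc = _passes(seq, constraints)
        if ok and specific(seq):
            fwd_cands.append((seq, tm, gc, start))
        if len(fwd_cands) >= 12:
            break
    rev_cands: list[tuple[str, float, float, int]] = []
    for start, length in rev_wins:
        seq = revcomp(window_seq(start, length))
        ok, tm, gc = _passes(seq, constraints)
        if ok and specific(seq):
            rev_cands.append((seq, tm, gc, start))
        if len(rev_cands) >= 12:
            break

    pairs: list[PrimerPair] = []
    for fseq, ftm, fgc, fcol in fwd_cands:
        for rseq, rtm, rgc, _ in rev_cands:
            sizes: dict[str, list[int]] = {}
            ok = True
            for rec in records:
                amps = amplify(
                    (fseq, rseq), rec, max_product_size=constraints.max_product_size
                )
                if len(amps) != 1:
                    ok = False
                    break
                sizes[rec.id] = [a.size for a in amps]
            if not ok:
                continue
            pair = PrimerPair(
                marker_id=marker.marker_id,
                forward=fseq,
                reverse=rseq,
                tm_forward=round(ftm, 2),
                tm_reverse=round(rtm, 2),
                gc_forward=round(fgc, 2),
                gc_reverse=round(rgc, 2),
                product_sizes=sizes,
                forward_col=fcol + 1,
            )
            gsizes = pair.group_sizes(group_map)
            gap = separability_gap(gsizes)
            if gap is None:
                continue
            smallest = min(min(v) for v in gsizes.values())
            if gap < max(
                constraints.min_separation_bp,
                constraints.min_separation_frac * smallest,
            ):
                continue
            pairs.append(pair)
        if len(pairs) >= max_pairs * 4:
            break

    pairs.sort(
        key=lambda p: (
            abs(p.tm_forward - p.tm_reverse),
            abs((p.tm_forward + p.tm_reverse) / 2 - 60.0),
            p.forward_col,
            p.forward,
            p.reverse,
        )
    )
    return pairs[:max_pairs]
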