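"""In-silico PCR: primer binding sites, amplicons, and gel band patterns.

A primer binds the template where its footprint matches within
``max_mismatch`` substitutions AND its 3'-terminal ``three_prime_exact_len``
bases match exactly (polymerase extension requires a matched 3' end).
Ambiguity codes in the template never count as matches.  An amplicon is
every forward(+)/reverse(−) site combination whose product — including both
primer footprints, the standard PCR size convention — does not exceed
``max_product_size``.

Templates are linear by default; ``circular=True`` virtually extends the
template by ``max_product_size − 1`` bases so origin-spanning products are
found once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .seqio import GenomeRecord, revcomp

DEFAULT_MAX_PRODUCT = 2000
DEFAULT_THREE_PRIME_EXACT = 3

_ACGT = frozenset(b"ACGT")


@dataclass(frozen=True)
class BindingSite:
    record_id: str
    strand: str  # '+' or '-'
    start: int  # 1-based inclusive footprint span on the top strand
    end: int
    mismatches: int
    three_prime_exact: bool = True


@dataclass(frozen=True)
class Amplicon:
    record_id: str
    start: int  # 1-based inclusive, forward-site start .. reverse-site end
    end: int
    forward_site: BindingSite
    reverse_site: BindingSite

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class Band:
    size: int  # representative (smallest) size of the band
    sizes: tuple[int, ...]  # all co-migrating product sizes
    merged: bool = False

    @property
    def label(self) -> str:
        if not self.merged:
            return f"{self.size} bp"
        return f"{self.size} bp (unresolved doublet: {'/'.join(map(str, self.sizes))})"


@dataclass
class BandPattern:
    """Per-marker multiset of band sizes for one sample."""

    sample_id: str
    bands: dict[str, list[int]] = field(default_factory=dict)  # marker -> sizes


def _scan_exact(primer: str, template: str) -> list[int]:
    """0-based start positions of exact occurrences (overlaps allowed)."""
    hits = []
    i = template.find(primer)
    while i != -1:
        hits.append(i)
        i = template.find(primer, i + 1)
    return hits


def _scan_mismatch(
    primer: str, template: str, max_mismatch: int, three_prime_exact_len: int,
    three_prime_at_end: bool,
) -> list[tuple[int, int]]:
    """(0-based start, mismatches) for sites within the mismatch budget.

    ``three_prime_at_end`` selects which footprint end must be exact: the
    right end for a top-strand forward primer, the left end for the
    reverse-complemented footprint of a bottom-strand primer.
    """
    L = len(primer)
    n = len(template)
    if n < L:
        return []
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(t, L)
    # ambiguity codes never match: mask template positions outside ACGT
    valid = np.isin(t, np.frombuffer(b"ACGT", dtype=np.uint8))
    vwin = np.lib.stride_tricks.sliding_window_view(valid, L)
    eq = (win == p) & vwin
    mm = L - eq.sum(axis=1)
    if three_prime_exact_len > 0:
        k = min(three_prime_exact_len, L)
        exact3 = eq[:, -k:].all(axis=1) if three_prime_at_end else eq[:, :k].all(axis=1)
    else:
        exact3 = np.ones(len(mm), dtype=bool)
    ok = (mm <= max_mismatch) & exact3
    return [(int(i), int(mm[i])) for i in np.flatnonzero(ok)]


def find_sites(
    primer: str,
    genome: GenomeRecord | str,
    *,
    max_mismatch: int = 0,
    three_prime_exact_len: int = DEFAULT_THREE_PRIME_EXACT,
    circular: bool | None = None,
    max_product_size: int = DEFAULT_MAX_PRODUCT,
) -> list[BindingSite]:
    """All binding sites of ``primer`` on both strands of the template.

    Sites are ordered by (start, strand).  With a circular template the scan
    wraps across the origin; wrapped sites are reported at their modular
    start position.
    """
    primer = primer.upper()
    if not 8 <= len(primer) <= 40:
        raise ValueError("primer length must be 8-40 nt")
    if isinstance(genome, GenomeRecord):
        rid, template = genome.id, genome.seq
        if circular is None:
            circular = genome.circular
    else:
        rid, template = "template", genome.upper()
        circular = bool(circular)
    n = len(template)
    scan_template = template
    if circular and n > len(primer):
        scan_template = template + template[: max_product_size - 1]

    sites: list[BindingSite] = []
    for strand, probe in (("+", primer), ("-", revcomp(primer))):
        three_prime_at_end = strand == "+"
        if max_mismatch == 0:
            # ambiguity codes in the template make str.find miss nothing:
            # they can only produce byte-inequality, which is the wanted
            # "never a match" semantics
            hits = [(i, 0) for i in _scan_exact(probe, scan_template)]
        else:
            hits = _scan_mismatch(
                probe, scan_template, max_mismatch, three_prime_exact_len,
                three_prime_at_end,
            )
        for i, mm in hits:
            if i >= n:  # wrapped copy of a site already seen
                continue
            sites.append(
                BindingSite(
                    record_id=rid,
                    strand=strand,
                    start=i + 1,
                    end=i + len(primer),
                    mismatches=mm,
                )
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def amplify(
    pair,
    genome: GenomeRecord | str,
    *,
    max_mismatch: int = 0,
    max_product_size: int = DEFAULT_MAX_PRODUCT,
    three_prime_exact_len: int = DEFAULT_THREE_PRIME_EXACT,
    circular: bool | None = None,
) -> list[Amplicon]:
    """Predict all PCR products of a primer pair on a template.

    ``pair`` is a ``(forward, reverse)`` sequence pair (both written 5'→3')
    or any object with ``forward``/``reverse`` attributes.  Both primer
    orientations are considered, so swapping forward and reverse yields the
    same product sizes.  Products are sorted by (size, start).
    """
    if hasattr(pair, "forward"):
        fwd, rev = pair.forward, pair.reverse
    else:
        fwd, rev = pair
    kw = dict(
        max_mismatch=max_mismatch,
        three_prime_exact_len=three_prime_exact_len,
        circular=circular,
        max_product_size=max_product_size,
    )
    sites_f = find_sites(fwd, genome, **kw)
    sites_r = sites_f if rev == fwd else find_sites(rev, genome, **kw)
    if isinstance(genome, GenomeRecord):
        rid, n = genome.id, genome.length
        circ = genome.circular if circular is None else circular
    else:
        rid, n = "template", len(genome)
        circ = bool(circular)

    def plus_minus(a: Iterable[BindingSite], b: Iterable[BindingSite]) -> list[Amplicon]:
        out = []
        for fs in a:
            if fs.strand != "+":
                continue
            for rs in b:
                if rs.strand != "-":
                    continue
                end = rs.end
                if circ and end <= fs.start:
                    end += n  # origin-spanning product on the doubled template
                if fs.start < end and end - fs.start + 1 <= max_product_size:
                    out.append(
                        Amplicon(
                            record_id=rid,
                            start=fs.start,
                            end=end,
                            forward_site=fs,
                            reverse_site=rs,
                        )
                    )
        return out

    amps = plus_minus(sites_f, sites_r)
    if rev != fwd:
        amps += plus_minus(sites_r, sites_f)
    # a palindromic pair could enumerate the same product twice
    uniq = {(a.start, a.end): a for a in amps}
    return sorted(uniq.values(), key=lambda a: (a.size, a.start))


def band_tolerance(size: int) -> int:
    """Co-migration tolerance on agarose: max(2 bp, 1% of the size)."""
    return max(2, round(0.01 * size))


def simulate_gel(
    sizes: Sequence[int] | Sequence[Amplicon],
    *,
    tolerance=None,
) -> list[Band]:
    """Collapse product sizes into orderable gel bands (largest first).

    Products closer than the tolerance co-migrate and merge into one band
    flagged as an unresolved doublet (e.g. 249/250 bp alleles on 1.5%
    agarose).  ``tolerance`` may be an int or a ``size -> int`` callable.
    """
    vals = sorted(
        (a.size if isinstance(a, Amplicon) else int(a)) for a in sizes
    )
    if tolerance is None:
        tol = band_tolerance
    elif callable(tolerance):
        tol = tolerance
    else:
        tol = lambda _s, _t=int(tolerance): _t  # noqa: E731
    bands: list[Band] = []
    group: list[int] = []
    for v in vals:
        if group and v - group[-1] > tol(v):
            bands.append(Band(size=group[0], sizes=tuple(group), merged=len(set(group)) > 1))
            group = []
        group.append(v)
    if group:
        bands.append(Band(size=group[0], sizes=tuple(group), merged=len(set(group)) > 1))
    bands.sort(key=lambda b: -b.size)
    return bands
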