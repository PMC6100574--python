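"""InDel event extraction and species-diagnostic classification.

An *InDel event* is a maximal run of alignment columns sharing one identical
gap pattern, with at least one gapped row.  Events tile the gapped columns
of the alignment exactly: adjacent overlapping indels with different row
patterns split into separate events, which keeps the definition brute-force
checkable and the event count deterministic.

Classification compares each event's gap pattern against the species
grouping: an event is *diagnostic* when every group is internally uniform
(all members gapped, or all carrying bases) and at least two groups differ.
Within-group disagreement marks the event *polymorphic-within-group*
(allelic length variants); runs touching the alignment ends are flagged
*terminal* — those usually reflect linearization offsets of circular
genomes, not biology — and are excluded from marker candidacy by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .align import Alignment
from .seqio import GAP, ConfigError, SpeciesGroupSet

#: marker candidates must be STRICTLY longer than this many bp by default
DEFAULT_MIN_LEN = 100
#: diagnostic events closer than this are merged into one marker region
DEFAULT_FLANK_MIN = 150

STATUS_DIAGNOSTIC = "diagnostic"
STATUS_SHARED = "shared"
STATUS_POLYMORPHIC = "polymorphic-within-group"
STATUS_TERMINAL = "terminal"


@dataclass
class InDelEvent:
    """Maximal constant-gap-pattern alignment interval (columns 1-based)."""

    col_start: int
    col_end: int
    gapped: dict[str, bool]  # record id -> True if gapped over the interval
    terminal: bool = False

    @property
    def length(self) -> int:
        return self.col_end - self.col_start + 1

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("event length must be >= 1")
        if not any(self.gapped.values()):
            raise ValueError("an InDel event needs at least one gapped record")


@dataclass
class DiagnosticCall:
    event: InDelEvent
    status: str
    group_alleles: dict[str, str]  # group -> present | absent | mixed


@dataclass
class MarkerRegion:
    """One or more nearby diagnostic events bundled into a marker candidate."""

    col_start: int
    col_end: int
    events: list[InDelEvent] = field(default_factory=list)
    marker_id: str = ""
    name: str | None = None

    def net_length_difference(self, group_map: Mapping[str, str], group_a: str, group_b: str) -> int:
        """|sum of base columns carried by group_a − by group_b| over the region's events.

        For a two-group comparison this equals the expected amplicon size
        difference of any primer pair spanning the whole region.
        """
        diff = 0
        for ev in self.events:
            a_has = [not ev.gapped[r] for r, g in group_map.items() if g == group_a]
            b_has = [not ev.gapped[r] for r, g in group_map.items() if g == group_b]
            if all(a_has) and not any(b_has):
                diff += ev.length
            elif all(b_has) and not any(a_has):
                diff -= ev.length
        return abs(diff)


def call_indels(alignment: Alignment) -> list[InDelEvent]:
    """Extract all maximal constant-gap-pattern events, sorted by column.

    A gapless alignment yields an empty list.  Events never overlap and
    their union is exactly the set of columns containing at least one gap.
    """
    ids = alignment.ids
    if len(ids) > 63:
        raise ConfigError("more than 63 alignment rows are not supported")
    mat = alignment.matrix()
    gap = mat == ord(GAP)
    # integer code per column; 0 <=> gapless column
    weights = (1 << np.arange(len(ids), dtype=np.int64))[:, None]
    code = (gap * weights).sum(axis=0)
    if not code.any():
        return []
    boundaries = np.flatnonzero(np.diff(code)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [alignment.col_count]))  # exclusive
    events: list[InDelEvent] = []
    ncols = alignment.col_count
    for s, e in zip(starts, ends):
        c = code[s]
        if c == 0:
            continue
        gapped = {rid: bool(c >> i & 1) for i, rid in enumerate(ids)}
        events.append(
            InDelEvent(
                col_start=int(s) + 1,
                col_end=int(e),
                gapped=gapped,
                terminal=(s == 0 or e == ncols),
            )
        )
    return events


def classify_diagnostic(
    events: Iterable[InDelEvent],
    groups: SpeciesGroupSet | Mapping[str, str],
) -> list[DiagnosticCall]:
    """Classify events against the species grouping.

    ``groups`` is a :class:`SpeciesGroupSet` or a record-id -> group mapping
    covering every alignment row that appears in the events.
    """
    group_map = groups.group_map() if isinstance(groups, SpeciesGroupSet) else dict(groups)
    calls: list[DiagnosticCall] = []
    for ev in events:
        unmapped = [r for r in ev.gapped if r not in group_map]
        if unmapped:
            raise ConfigError(f"alignment rows without a group: {unmapped}")
        labels = sorted({group_map[r] for r in ev.gapped})
        alleles: dict[str, str] = {}
        for g in labels:
            states = {ev.gapped[r] for r in ev.gapped if group_map[r] == g}
            if len(states) > 1:
                alleles[g] = "mixed"
            else:
                alleles[g] = "absent" if states.pop() else "present"
        if ev.terminal:
            status = STATUS_TERMINAL
        elif "mixed" in alleles.values():
            status = STATUS_POLYMORPHIC
        elif len(set(alleles.values())) > 1:
            status = STATUS_DIAGNOSTIC
        else:
            status = STATUS_SHARED
        calls.append(DiagnosticCall(event=ev, status=status, group_alleles=alleles))
    return calls


def filter_markers(
    calls: Iterable[DiagnosticCall],
    *,
    min_len: int = DEFAULT_MIN_LEN,
    require_diagnostic: bool = True,
    exclude_terminal: bool = True,
) -> list[InDelEvent]:
    """Marker-candidate events: strictly longer than ``min_len`` bp,
    species-diagnostic, and away from the alignment ends."""
    out: list[InDelEvent] = []
    for call in calls:
        if call.event.length <= min_len:
            continue
        if require_diagnostic and call.status != STATUS_DIAGNOSTIC:
            continue
        if exclude_terminal and call.event.terminal:
            continue
        out.append(call.event)
    return out


def merge_marker_regions(
    calls: list[DiagnosticCall],
    *,
    min_len: int = DEFAULT_MIN_LEN,
    flank_min: int = DEFAULT_FLANK_MIN,
) -> list[MarkerRegion]:
    """Bundle filtered diagnostic events into marker regions.

    Diagnostic events passing the length filter seed the regions; seeds
    closer than ``flank_min`` columns merge (one amplicon can span several
    InDels), and any other called event within ``flank_min`` of a region is
    absorbed so its length contributes to expected product sizes.
    """
    seeds = filter_markers(calls, min_len=min_len)
    if not seeds:
        return []
    seeds.sort(key=lambda e: e.col_start)
    clusters: list[list[InDelEvent]] = [[seeds[0]]]
    for ev in seeds[1:]:
        if ev.col_start - clusters[-1][-1].col_end <= flank_min:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])
    regions: list[MarkerRegion] = []
    all_events = sorted((c.event for c in calls), key=lambda e: e.col_start)
    for i, cluster in enumerate(clusters, 1):
        span_start = cluster[0].col_start
        span_end = cluster[-1].col_end
        absorbed = [
            ev
            for ev in all_events
            if ev.col_start <= span_end + flank_min and ev.col_end >= span_start - flank_min
            and not ev.terminal
        ]
        regions.append(
            MarkerRegion(
                col_start=min(ev.col_start for ev in absorbed),
                col_end=max(ev.col_end for ev in absorbed),
                events=absorbed,
                marker_id=f"marker{i}",
            )
        )
    return regions


def event_to_genome(
    event: InDelEvent, record_id: str, alignment: Alignment
) -> tuple[str, int, int]:
    """Map an event to 1-based genome coordinates of one record.

    Returns ``("span", start, end)`` for a base-carrying row (the inclusive
    span of its bases inside the event) or ``("insertion", left, right)``
    for a gapped row, where the event falls between genome positions
    ``left`` and ``right`` (= left+1; ``left`` is 0 at the sequence start).
    """
    if record_id not in alignment.rows:
        raise KeyError(record_id)
    if event.gapped[record_id]:
        before = alignment.last_pos_before(record_id)
        left = int(before[event.col_start - 2]) if event.col_start > 1 else 0
        return ("insertion", left, left + 1)
    pos = alignment.col_to_pos(record_id)[event.col_start - 1 : event.col_end]
    pos = pos[pos > 0]
    return ("span", int(pos.min()), int(pos.max()))


def region_reference_span(
    region: MarkerRegion, record_id: str, alignment: Alignment
) -> tuple[int, int]:
    """Smallest 1-based genome span of ``record_id`` covering the region.

    For rows gapped across the whole region this is the two flanking
    positions (the insertion point widened to a 2 bp span).
    """
    pos = alignment.col_to_pos(record_id)[region.col_start - 1 : region.col_end]
    pos = pos[pos > 0]
    if pos.size:
        return int(pos.min()), int(pos.max())
    before = alignment.last_pos_before(record_id)
    left = int(before[region.col_start - 2]) if region.col_start > 1 else 0
    return max(left, 1), left + 1


def write_markers_bed(
    regions: Iterable[MarkerRegion],
    alignment: Alignment,
    reference_id: str,
    path,
) -> None:
    """BED export of marker regions on the reference genome.

    BED uses 0-based half-open coordinates, unlike every other surface of
    this package (1-based inclusive); the header comment says so.
    """
    with open(path, "w") as fh:
        fh.write("# BED: 0-based half-open coordinates on %s\n" % reference_id)
        for reg in regions:
            start, end = region_reference_span(reg, reference_id, alignment)
            name = (reg.name or reg.marker_id).replace(" ", "_")
            fh.write(f"{reference_id}\t{start - 1}\t{end}\t{name}\n")


def markers_table(
    regions: Iterable[MarkerRegion],
    alignment: Alignment,
    group_set: SpeciesGroupSet,
    reference_id: str,
) -> pd.DataFrame:
    """Tabular marker report (one row per region)."""
    group_map = group_set.group_map()
    labels = group_set.group_labels
    rows = []
    for reg in regions:
        start, end = region_reference_span(reg, reference_id, alignment)
        row: dict[str, object] = {
            "marker_id": reg.marker_id,
            "name": reg.name or "",
            "reference": reference_id,
            "ref_start": start,
            "ref_end": end,
            "n_events": len(reg.events),
        }
        if len(labels) == 2:
            row["net_size_difference_bp"] = reg.net_length_difference(
                group_map, labels[0], labels[1]
            )
        rows.append(row)
    return pd.DataFrame(rows)
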