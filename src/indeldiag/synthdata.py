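"""Synthetic genome sets with fully known planted InDel/SNP structure.

The generator emulates pairs of closely related organelle genomes the way
the discovery pipeline sees them: a common ancestor sequence, species-level
InDels (some clustered into large diagnostic regions, most small),
cross-group and within-group (allelic) variants, and background SNPs.  All
randomness flows from one seed through one generator, so identical specs
produce byte-identical FASTA output.

Planted events are applied right-to-left so ancestor coordinates stay valid
during construction, and SNPs are kept out of the primer-design flank
windows of diagnostic regions so that conserved flanks are guaranteed by
construction (real plastomes offer no such guarantee; see the methods note
for what that implies about the tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import (
    Feature,
    FeatureTable,
    GenomeRecord,
    SpeciesGroupSet,
    write_fasta,
    write_gff3,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SynthSpecError(ValueError):
    pass


@dataclass
class PlantedIndel:
    """One planted insertion or deletion in ancestor coordinates (1-based).

    ``kind="insertion"``: ``length`` bases inserted between ancestor
    positions ``pos`` and ``pos+1`` in every carrier.  ``kind="deletion"``:
    ancestor positions ``pos .. pos+length-1`` removed from every carrier.
    ``carriers`` is a group label (all members) or an explicit tuple of
    accession ids.  Events sharing a ``region`` label may sit close
    together (one amplicon spans them); everything else must keep its
    distance.
    """

    pos: int
    length: int
    kind: str  # insertion | deletion
    carriers: str | tuple[str, ...]
    region: str | None = None
    event_id: str = ""
    inserted_seq: str = ""  # filled by generate() for insertions

    def span(self) -> tuple[int, int]:
        if self.kind == "deletion":
            return (self.pos, self.pos + self.length - 1)
        return (self.pos, self.pos + 1)


@dataclass
class PlantedSnp:
    pos: int
    carriers: str | tuple[str, ...]
    alt: str = ""  # filled by generate()


@dataclass
class SynthSpec:
    seed: int
    base_length: int
    group_sizes: dict[str, int]  # group label -> number of accessions
    indels: list[PlantedIndel] = field(default_factory=list)
    snps: list[PlantedSnp] = field(default_factory=list)
    genes: list[Feature] = field(default_factory=list)
    flank: int = 200
    at_bias: float = 0.0  # 0 = uniform composition; >0 skews toward A/T

    def accession_ids(self) -> dict[str, list[str]]:
        return {
            g: [f"{g}{i}" for i in range(1, n + 1)]
            for g, n in self.group_sizes.items()
        }


@dataclass
class SynthTruth:
    spec: SynthSpec
    group_set: SpeciesGroupSet
    events: pd.DataFrame  # event_id, region, kind, length, pos, carriers
    features: FeatureTable  # planted genes in reference coordinates
    reference_id: str
    expected_marker_count: int
    expected_net_diffs: dict[str, int]  # region -> |net length difference|


def _carrier_ids(carriers: str | tuple[str, ...], ids: dict[str, list[str]]) -> set[str]:
    if isinstance(carriers, str):
        if carriers not in ids:
            raise SynthSpecError(f"unknown carrier group {carriers!r}")
        return set(ids[carriers])
    unknown = set(carriers) - {a for accs in ids.values() for a in accs}
    if unknown:
        raise SynthSpecError(f"unknown carrier accessions {sorted(unknown)}")
    return set(carriers)


def _validate(spec: SynthSpec) -> None:
    # No two planted events may overlap.  Labeled regions (diagnostic marker
    # candidates) additionally keep >= 2*flank clear of every other event and
    # of the sequence ends, so conserved primer flanks exist by construction.
    clusters: dict[object, list[tuple[int, int]]] = {}
    for i, ev in enumerate(spec.indels):
        if ev.kind not in ("insertion", "deletion"):
            raise SynthSpecError(f"unknown indel kind {ev.kind!r}")
        if ev.length < 1:
            raise SynthSpecError("indel length must be >= 1")
        key = ev.region if ev.region is not None else ("__solo__", i)
        clusters.setdefault(key, []).append(ev.span())
    spans = []
    for key, pieces in clusters.items():
        pieces.sort()
        for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
            if s2 <= e1:
                raise SynthSpecError(f"overlapping planted events near position {s2}")
        spans.append((pieces[0][0], pieces[-1][1], key))
    spans.sort()
    for (s1, e1, k1), (s2, e2, k2) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise SynthSpecError(
                f"overlapping planted events: {k1!r} and {k2!r}"
            )
        labeled = isinstance(k1, str) or isinstance(k2, str)
        if labeled and s2 - e1 < 2 * spec.flank:
            raise SynthSpecError(
                f"planted events {k1!r} and {k2!r} are closer than 2*flank"
            )
    for s, e, key in spans:
        if isinstance(key, str) and (
            s <= 2 * spec.flank or e >= spec.base_length - 2 * spec.flank
        ):
            raise SynthSpecError("diagnostic region too close to the sequence ends")
    indel_spans = [p for pieces in clusters.values() for p in pieces]
    for snp in spec.snps:
        if not 1 <= snp.pos <= spec.base_length:
            raise SynthSpecError(f"SNP position {snp.pos} outside the sequence")
        for s, e in indel_spans:
            if s - 10 <= snp.pos <= e + 10:
                raise SynthSpecError(f"SNP at {snp.pos} collides with a planted indel")


def _ancestor_to_acc(pos: int, events: Sequence[PlantedIndel]) -> int:
    """Map an ancestor position to accession coordinates (events = that
    accession's events; position must lie outside all deletion spans)."""
    shift = 0
    for ev in events:
        if ev.kind == "insertion" and ev.pos < pos:
            shift += ev.length
        elif ev.kind == "deletion" and ev.pos + ev.length - 1 < pos:
            shift -= ev.length
    return pos + shift


def generate(spec: SynthSpec) -> SynthTruth:
    """Materialize a :class:`SynthSpec` into genomes plus a truth table."""
    if len(spec.group_sizes) < 1 or any(n < 1 for n in spec.group_sizes.values()):
        raise SynthSpecError("each group needs at least one accession")
    _validate(spec)
    rng = np.random.default_rng(spec.seed)
    p_at = 0.25 + spec.at_bias / 2
    probs = np.array([p_at, 0.5 - p_at, 0.5 - p_at, p_at])
    ancestor_arr = rng.choice(_BASES, size=spec.base_length, p=probs / probs.sum())
    ancestor = ancestor_arr.tobytes().decode()

    ids = spec.accession_ids()
    # fill random payloads deterministically, in spec order
    for i, ev in enumerate(spec.indels):
        ev.event_id = ev.event_id or (
            f"{ev.region}.{i}" if ev.region else f"indel{i}"
        )
        if ev.kind == "insertion" and not ev.inserted_seq:
            ev.inserted_seq = rng.choice(_BASES, size=ev.length).tobytes().decode()
    for snp in spec.snps:
        ref = ancestor[snp.pos - 1]
        alts = [b for b in "ACGT" if b != ref]
        snp.alt = snp.alt or alts[int(rng.integers(len(alts)))]

    groups: dict[str, list[GenomeRecord]] = {g: [] for g in spec.group_sizes}
    acc_events: dict[str, list[PlantedIndel]] = {}
    for g, accs in ids.items():
        for acc in accs:
            mine = [
                ev for ev in spec.indels if acc in _carrier_ids(ev.carriers, ids)
            ]
            acc_events[acc] = mine
            seq = list(ancestor)
            for snp in spec.snps:
                if acc in _carrier_ids(snp.carriers, ids):
                    seq[snp.pos - 1] = snp.alt
            # right-to-left so earlier coordinates stay valid
            for ev in sorted(mine, key=lambda e: -e.pos):
                if ev.kind == "deletion":
                    del seq[ev.pos - 1 : ev.pos - 1 + ev.length]
                else:
                    seq[ev.pos : ev.pos] = list(ev.inserted_seq)
            groups[g].append(
                GenomeRecord(id=acc, species_group=g, seq="".join(seq), circular=True)
            )
    group_set = SpeciesGroupSet(groups=groups)

    rows = []
    for ev in spec.indels:
        carriers = sorted(_carrier_ids(ev.carriers, ids))
        rows.append(
            {
                "event_id": ev.event_id,
                "region": ev.region or "",
                "kind": ev.kind,
                "length": ev.length,
                "ancestor_pos": ev.pos,
                "carriers": ",".join(carriers),
            }
        )
    events = pd.DataFrame(rows)

    # expected per-region net length differences for a two-group design
    expected_net: dict[str, int] = {}
    labels = list(spec.group_sizes)
    if len(labels) == 2:
        ga, gb = labels
        for region in sorted({e.region for e in spec.indels if e.region}):
            net = 0
            for ev in spec.indels:
                if ev.region != region:
                    continue
                carriers = _carrier_ids(ev.carriers, ids)
                signed = ev.length if ev.kind == "insertion" else -ev.length
                if carriers == set(ids[ga]):
                    net += signed
                elif carriers == set(ids[gb]):
                    net -= signed
            expected_net[region] = abs(net)

    reference_id = max(group_set.groups[labels[0]], key=lambda r: (r.length, r.id)).id
    ref_events = acc_events[reference_id]
    features = FeatureTable(
        record_id=reference_id,
        features=[
            Feature(
                gene=f.gene,
                start=_ancestor_to_acc(f.start, ref_events),
                end=_ancestor_to_acc(f.end, ref_events),
                strand=f.strand,
            )
            for f in spec.genes
        ],
    )
    n_markers = len(
        {
            e.region
            for e in spec.indels
            if e.region and e.length > 100 and isinstance(e.carriers, str)
        }
    )
    return SynthTruth(
        spec=spec,
        group_set=group_set,
        events=events,
        features=features,
        reference_id=reference_id,
        expected_marker_count=n_markers,
        expected_net_diffs=expected_net,
    )


# ---------------------------------------------------------------------------
# paper-like canned study
# ---------------------------------------------------------------------------

def _sample_positions(
    rng: np.random.Generator,
    n: int,
    lo: int,
    hi: int,
    forbidden: list[tuple[int, int]],
    min_gap: int,
) -> list[int]:
    """Draw ``n`` positions in [lo, hi] avoiding forbidden spans, pairwise
    at least ``min_gap`` apart.  Deterministic for a given generator state."""
    chosen: list[int] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > 200 * n:
            raise SynthSpecError("could not place planted events; relax the spec")
        p = int(rng.integers(lo, hi + 1))
        if any(s - min_gap <= p <= e + min_gap for s, e in forbidden):
            continue
        if any(abs(p - q) < min_gap for q in chosen):
            continue
        chosen.append(p)
    return sorted(chosen)


def make_paper_like(
    seed: int,
    *,
    base_length: int = 150_000,
    n_small_indels: int = 222,
    n_cross_group_indels: int = 6,
    n_allelic_indels: int = 6,
    n_group_snps: int = 60,
    n_private_snps: int = 20,
) -> SynthTruth:
    """A canned two-species study shaped like a real plastome comparison.

    Two groups (2 Cw-like + 3 Ca-like accessions, ~150 kb) with three
    diagnostic marker regions whose net length differences are 170, 347 and
    93 bp — the first a cluster of eight insertions led by a 120 bp event,
    the second a single 347 bp insertion, the third a 110 bp deletion plus a
    17 bp insertion with a 1 bp allelic variant inside the region — plus
    ~234 small background InDels (species-level, cross-group and allelic)
    and background SNPs.  Every quantity is recoverable from the truth
    table, so end-to-end discovery, design and classification are checkable
    without any external data.
    """
    rng = np.random.default_rng(seed)
    indels: list[PlantedIndel] = []

    # region A: eight clustered Ca insertions, net +170 (one event > 100 bp)
    a_lengths = [120, 20, 12, 8, 5, 3, 1, 1]
    a_pos = 20_000
    for j, L in enumerate(a_lengths):
        indels.append(
            PlantedIndel(
                pos=a_pos + 12 * j, length=L, kind="insertion",
                carriers="Ca", region="regionA",
            )
        )
    # region B: one 347 bp Cw insertion
    indels.append(
        PlantedIndel(pos=60_000, length=347, kind="insertion",
                     carriers="Cw", region="regionB")
    )
    # region C: Ca deletion 110 + Ca insertion 17 (net 93) + 1 bp allelic
    indels.append(
        PlantedIndel(pos=100_000, length=110, kind="deletion",
                     carriers="Ca", region="regionC")
    )
    indels.append(
        PlantedIndel(pos=100_160, length=17, kind="insertion",
                     carriers="Ca", region="regionC")
    )
    indels.append(
        PlantedIndel(pos=100_220, length=1, kind="deletion",
                     carriers=("Ca3",), region="regionC")
    )

    region_zones = [(19_500, 20_800), (59_500, 60_500), (99_500, 100_800)]
    gene_zones = [
        ("trnQ", 18_300, 18_800), ("psbK", 21_400, 21_700),
        ("rps2", 58_400, 58_900), ("rpoC2", 61_200, 62_400),
        ("psaJ", 98_600, 98_900), ("rpl33", 101_500, 101_700),
        ("gX1", 40_000, 41_000), ("gX2", 120_000, 121_500),
    ]
    genes = [Feature(gene=g, start=s, end=e) for g, s, e in gene_zones]

    forbidden = [(s - 400, e + 400) for s, e in region_zones]
    n_bg = n_small_indels + n_cross_group_indels + n_allelic_indels
    bg_pos = _sample_positions(rng, n_bg, 1_500, base_length - 1_500, forbidden, 80)
    acc_ids = {"Cw": ["Cw1", "Cw2"], "Ca": ["Ca1", "Ca2", "Ca3"]}
    all_accs = acc_ids["Cw"] + acc_ids["Ca"]
    for i, p in enumerate(bg_pos):
        L = int(rng.integers(1, 31))
        kind = "insertion" if rng.random() < 0.5 else "deletion"
        if i < n_small_indels:
            carriers: str | tuple[str, ...] = "Cw" if i % 2 == 0 else "Ca"
        elif i < n_small_indels + n_cross_group_indels:
            carriers = ("Cw2", "Ca1")  # shared across the species boundary
        else:
            carriers = (all_accs[int(rng.integers(len(all_accs)))],)
        indels.append(PlantedIndel(pos=p, length=L, kind=kind, carriers=carriers))

    indel_forbidden = forbidden + [
        (ev.span()[0] - 60, ev.span()[1] + 60) for ev in indels
    ]
    snp_pos = _sample_positions(
        rng, n_group_snps + n_private_snps, 1_500, base_length - 1_500,
        indel_forbidden, 30,
    )
    snps: list[PlantedSnp] = []
    for i, p in enumerate(snp_pos):
        if i < n_group_snps:
            snps.append(PlantedSnp(pos=p, carriers="Cw" if i % 2 else "Ca"))
        else:
            snps.append(
                PlantedSnp(pos=p, carriers=(all_accs[int(rng.integers(len(all_accs)))],))
            )

    spec = SynthSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        base_length=base_length,
        group_sizes={"Cw": 2, "Ca": 3},
        indels=indels,
        snps=snps,
        genes=genes,
        flank=200,
    )
    return generate(spec)


# ---------------------------------------------------------------------------
# sample simulation for classification tests
# ---------------------------------------------------------------------------

def simulate_band_patterns(
    truth: SynthTruth,
    pairs,
    *,
    n_pure: int = 50,
    n_mixed: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Predicted band tables for simulated pure and mixed samples.

    Each pure sample is one accession's genome amplified with every designed
    pair; each mixed sample pools one accession from each of two groups (the
    adulteration scenario).  Returns (bands table, sample -> true label)
    where mixed samples are labelled ``"mixture"``.
    """
    from .ispcr import amplify

    rng = np.random.default_rng(seed)
    records = list(truth.group_set.records())
    labels = truth.group_set.group_labels
    rows = []
    expected: dict[str, str] = {}
    for i in range(n_pure):
        rec = records[int(rng.integers(len(records)))]
        sid = f"pure{i + 1}"
        expected[sid] = rec.species_group
        for pair in pairs:
            for amp in amplify(pair, rec):
                rows.append({"sample": sid, "marker": pair.marker_id, "size_bp": amp.size})
    for i in range(n_mixed):
        picks = [
            truth.group_set.groups[g][int(rng.integers(len(truth.group_set.groups[g])))]
            for g in labels[:2]
        ]
        sid = f"mixed{i + 1}"
        expected[sid] = "mixture"
        for pair in pairs:
            sizes = set()
            for rec in picks:
                sizes.update(a.size for a in amplify(pair, rec))
            for size in sorted(sizes):
                rows.append({"sample": sid, "marker": pair.marker_id, "size_bp": size})
    return pd.DataFrame(rows), expected


def write_fixture(truth: SynthTruth, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + groups TSV + truth TSV + GFF3 of planted genes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genomes.fasta",
        "groups": outdir / "groups.tsv",
        "truth": outdir / "truth.tsv",
        "gff3": outdir / "genes.gff3",
    }
    write_fasta(truth.group_set.records(), paths["fasta"])
    with open(paths["groups"], "w") as fh:
        for rec in truth.group_set.records():
            fh.write(f"{rec.id}\t{rec.species_group}\n")
    truth.events.to_csv(paths["truth"], sep="\t", index=False)
    write_gff3(truth.features, paths["gff3"])
    return paths
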