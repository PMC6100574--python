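"""Genome, alignment and annotation I/O.

Conventions used throughout the package:

* All coordinates reported on any external surface are **1-based inclusive**.
* Sequences are stored uppercase over the IUPAC nucleotide alphabet; ``U`` is
  mapped to ``T`` on input.  Ambiguity codes (``N``, ``R`` ...) are retained
  but never count as matches in exact-match contexts (primer sites, conserved
  windows).
* Chloroplast genomes are circular molecules, but deposited records are
  linearized; templates are treated as LINEAR by default with an opt-in
  circular mode in :mod:`indeldiag.ispcr`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO


class FormatError(ValueError):
    """Malformed input: bad alphabet, unequal alignment rows, duplicate ids ..."""


class ConfigError(ValueError):
    """Inconsistent configuration: unassigned records, missing groups ..."""


#: Characters accepted in a nucleotide sequence (after uppercasing; U -> T).
IUPAC_ALPHABET = frozenset("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)

GAP = "-"


def _clean_seq(raw: str, *, where: str = "sequence") -> str:
    seq = str(raw).upper().replace("U", "T")
    bad = set(seq) - IUPAC_ALPHABET
    if bad:
        raise FormatError(
            f"{where} contains non-nucleotide characters: {sorted(bad)!r}"
        )
    return seq


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string.

    Involution: ``revcomp(revcomp(s)) == s``.  Raises :class:`FormatError`
    on non-IUPAC characters.
    """
    s = str(seq)
    bad = set(s.upper()) - IUPAC_ALPHABET - {"U"}
    if bad:
        raise FormatError(f"cannot complement characters {sorted(bad)!r}")
    return s.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """One accession: sequence plus identity and grouping metadata."""

    id: str
    species_group: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.seq = _clean_seq(self.seq, where=f"record {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class SpeciesGroupSet:
    """Genome records partitioned into named species groups.

    Discovery requires at least two groups with at least one record each;
    a single group is still a valid container (e.g. for in-silico PCR only).
    """

    groups: dict[str, list[GenomeRecord]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, recs in self.groups.items():
            if not recs:
                raise ConfigError(f"group {label!r} has no records")
            for rec in recs:
                if rec.id in seen:
                    raise FormatError(f"duplicate record id {rec.id!r}")
                seen.add(rec.id)
                rec.species_group = label

    @property
    def group_labels(self) -> list[str]:
        return list(self.groups)

    def records(self) -> Iterator[GenomeRecord]:
        for recs in self.groups.values():
            yield from recs

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records()]

    def record(self, record_id: str) -> GenomeRecord:
        for rec in self.records():
            if rec.id == record_id:
                return rec
        raise KeyError(record_id)

    def group_of(self, record_id: str) -> str:
        return self.record(record_id).species_group

    def group_map(self) -> dict[str, str]:
        """record id -> group label."""
        return {r.id: r.species_group for r in self.records()}


@dataclass(frozen=True)
class Feature:
    gene: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"feature {self.gene!r}: invalid span {self.start}-{self.end}"
            )


@dataclass
class FeatureTable:
    """Gene features of one record, sorted by start (1-based inclusive)."""

    record_id: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.gene))

    def __len__(self) -> int:
        return len(self.features)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".gb", ".gbk", ".genbank"}:
        return "genbank"
    if suffix in {".fa", ".fasta", ".fna", ".ffn"}:
        return "fasta"
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "fasta" if line.startswith(">") else "genbank"
    raise FormatError(f"{path}: empty file")


def read_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA or GenBank file."""
    path = Path(path)
    fmt = _sniff_format(path)
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        out.append((rec.id, _clean_seq(str(rec.seq), where=f"record {rec.id!r}")))
    if not out:
        raise FormatError(f"{path}: no sequence records found")
    return out


def read_group_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV (record id, group label); '#' lines are comments."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: expected two columns, got {row!r}")
            assignments[row[0]] = row[1]
    return assignments


def load_genomes(
    paths: Iterable[str | Path],
    group_assignments: Mapping[str, str] | str | Path,
    *,
    circular: bool = False,
) -> SpeciesGroupSet:
    """Load genomes from FASTA/GenBank files into a grouped record set.

    ``group_assignments`` maps record id -> group label (a dict, or the path
    of a two-column TSV).  Every record must be assigned; duplicate ids are
    rejected.
    """
    if not isinstance(group_assignments, Mapping):
        group_assignments = read_group_tsv(group_assignments)
    groups: dict[str, list[GenomeRecord]] = {}
    seen: set[str] = set()
    for path in paths:
        for rid, seq in read_sequences(path):
            if rid in seen:
                raise FormatError(f"duplicate record id {rid!r}")
            seen.add(rid)
            try:
                label = group_assignments[rid]
            except KeyError:
                raise ConfigError(
                    f"record {rid!r} has no species-group assignment"
                ) from None
            groups.setdefault(label, []).append(
                GenomeRecord(id=rid, species_group=label, seq=seq, circular=circular)
            )
    if not groups:
        raise ConfigError("no records loaded")
    return SpeciesGroupSet(groups=groups)


def write_fasta(
    records: Iterable[GenomeRecord] | Mapping[str, str],
    path: str | Path,
    *,
    wrap: int = 70,
) -> None:
    if isinstance(records, Mapping):
        items = list(records.items())
    else:
        items = [(r.id, r.seq) for r in records]
    with open(path, "w") as fh:
        for rid, seq in items:
            fh.write(f">{rid}\n")
            if wrap:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")
            else:
                fh.write(seq + "\n")


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA (gap character '-') into id -> gapped row."""
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise FormatError(f"duplicate alignment row id {rec.id!r}")
        row = str(rec.seq).upper().replace("U", "T")
        bad = set(row) - IUPAC_ALPHABET - {GAP}
        if bad:
            raise FormatError(f"row {rec.id!r}: invalid characters {sorted(bad)!r}")
        rows[rec.id] = row
    if not rows:
        raise FormatError(f"{path}: no alignment rows found")
    return rows


def write_alignment_fasta(rows: Mapping[str, str], path: str | Path) -> None:
    write_fasta(rows, path, wrap=70)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _short_gene_name(name: str) -> str:
    # tRNA genes like trnQ-UUG are reported by their short label (trnQ)
    return name.split("-")[0]


def load_features(
    path: str | Path,
    *,
    record_id: str | None = None,
    feature_type: str = "gene",
) -> FeatureTable:
    """Read gene features from GenBank or GFF3 into a :class:`FeatureTable`."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _features_from_gff3(path, record_id=record_id, feature_type=feature_type)
    return _features_from_genbank(path, record_id=record_id, feature_type=feature_type)


def _features_from_genbank(
    path: Path, *, record_id: str | None, feature_type: str
) -> FeatureTable:
    feats: list[Feature] = []
    rid = record_id
    for rec in SeqIO.parse(str(path), "genbank"):
        if record_id is not None and rec.id != record_id:
            continue
        rid = rec.id
        for f in rec.features:
            if f.type != feature_type:
                continue
            name = f.qualifiers.get("gene", f.qualifiers.get("locus_tag", ["?"]))[0]
            feats.append(
                Feature(
                    gene=_short_gene_name(name),
                    start=int(f.location.start) + 1,
                    end=int(f.location.end),
                    strand="-" if f.location.strand == -1 else "+",
                )
            )
        break
    if rid is None:
        raise FormatError(f"{path}: record {record_id!r} not found")
    return FeatureTable(record_id=rid, features=feats)


def _features_from_gff3(
    path: Path, *, record_id: str | None, feature_type: str
) -> FeatureTable:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats: list[Feature] = []
    rid = record_id
    for f in db.features_of_type(feature_type):
        if record_id is not None and f.seqid != record_id:
            continue
        rid = f.seqid
        name = (
            f.attributes.get("Name", f.attributes.get("gene", f.attributes.get("ID", ["?"])))
        )[0]
        feats.append(
            Feature(
                gene=_short_gene_name(name),
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in "+-" else "+",
            )
        )
    if rid is None:
        raise FormatError(f"{path}: no {feature_type!r} features found")
    return FeatureTable(record_id=rid, features=feats)


def write_gff3(features: FeatureTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, f in enumerate(features.features, 1):
            attrs = f"ID=gene{i};Name={f.gene}"
            fh.write(
                "\t".join(
                    [
                        features.record_id,
                        "indeldiag",
                        "gene",
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
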