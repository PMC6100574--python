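"""Published Cynanchum marker panel and accession metadata.

The reference application of this package is the authentication of two
Korean/Chinese medicinal herbs, *Cynanchum wilfordii* (Cw) and
*C. auriculatum* (Ca), whose dried tubers are morphologically
indistinguishable and routinely adulterated in commerce.  Three InDel
markers in chloroplast intergenic spacers separate the species by amplicon
length alone.  This module carries the published primer sequences, expected
product sizes, accession metadata and the wet-lab PCR protocol as data, so
the panel can be evaluated (not re-designed) against genome records fetched
with ``scripts/fetch_accessions.py``.
"""

from __future__ import annotations

from .diagnose import MarkerPanel

#: NCBI accession -> (species group, printed genome length in bp; None where
#: the source table prints no length for the accession)
PUBLISHED_ACCESSIONS: dict[str, tuple[str, int | None]] = {
    "NC029459": ("Cw", 161_241),
    "KT220733": ("Cw", None),
    "NC029460": ("Ca", 160_840),
    "KT220734": ("Ca", None),
    "KU900231": ("Ca", 160_203),
}

#: marker -> (forward primer, reverse primer), both written 5'->3'
PUBLISHED_PRIMERS: dict[str, tuple[str, str]] = {
    "trnQ-psbK": ("AAACCCGTTGCCTTACC", "AGATTGGAGTTGACAAATAACG"),
    "rps2-rpoC2": ("GGTCTACCACTATAAACTAAAC", "GCGGTGATACTCATATACA"),
    "psaJ-rpl33": ("CACCGTTATTTCCTCCGTTGATA", "CCTTACCGAGCATTTGCGA"),
}

#: marker -> group -> expected amplicon sizes (bp).  psaJ-rpl33 includes the
#: 1 bp Ca allelic pair; the 360 bp Cw allele is sample-derived (seen in
#: field material, not in the deposited accessions) and is listed separately.
PUBLISHED_EXPECTED_SIZES: dict[str, dict[str, set[int]]] = {
    "trnQ-psbK": {"Cw": {249}, "Ca": {419}},
    "rps2-rpoC2": {"Cw": {629}, "Ca": {282}},
    "psaJ-rpl33": {"Cw": {342}, "Ca": {249, 250}},
}

#: alleles observed only in resequenced field samples
SAMPLE_DERIVED_ALLELES: dict[str, dict[str, set[int]]] = {
    "psaJ-rpl33": {"Cw": {360}},
}

#: thermocycling metadata (recorded for the lab report, not simulated)
PCR_PROTOCOL = {
    "initial_denaturation": "95 C, 5 min",
    "cycles": 40,
    "denaturation": "95 C, 30 s",
    "annealing": "55 C, 30 s",
    "extension": "72 C, 2 min",
    "final_extension": "72 C, 5 min",
    "gel": "1.5% agarose, 100 bp ladder",
}


def published_panel(*, tolerance: float = 0.0, include_sample_alleles: bool = True) -> MarkerPanel:
    """The published three-marker panel as a :class:`MarkerPanel`."""
    markers = {
        m: {g: set(s) for g, s in groups.items()}
        for m, groups in PUBLISHED_EXPECTED_SIZES.items()
    }
    if include_sample_alleles:
        for m, groups in SAMPLE_DERIVED_ALLELES.items():
            for g, sizes in groups.items():
                markers[m][g] |= sizes
    return MarkerPanel(markers=markers, tolerance=tolerance)


def genome_size_differences() -> dict[str, int]:
    """Pairwise Cw-vs-Ca differences of the printed genome lengths (bp)."""
    cw = [v for g, v in PUBLISHED_ACCESSIONS.values() if g == "Cw" and v]
    ca = [v for g, v in PUBLISHED_ACCESSIONS.values() if g == "Ca" and v]
    out = {}
    for a in cw:
        for b in ca:
            out[f"{a}-{b}"] = abs(a - b)
    return out
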