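"""Intergenic-spacer (IGS) nomenclature for marker regions.

Markers are named by their flanking annotated genes, e.g. a region lying
between ``trnQ`` and ``psbK`` is the "trnQ-psbK IGS".  A region that
intersects a gene is labelled ``within <gene>`` and demoted with a warning:
primers inside coding regions may be conserved, but intergenic spacers are
where length polymorphism accumulates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .seqio import FeatureTable


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class IgsName:
    upstream: str
    downstream: str

    @property
    def label(self) -> str:
        return f"{self.upstream}-{self.downstream} IGS"


def name_region(span: tuple[int, int], features: FeatureTable) -> str:
    """Label a 1-based inclusive span by its flanking genes.

    Returns ``"<geneA>-<geneB> IGS"`` when the span lies strictly between
    two genes, ``"within <gene>"`` when it intersects a gene, and
    ``"terminal region"`` when there is no gene on one side.  Naming does
    not depend on the input feature order (the table is kept sorted).
    """
    if not features.features:
        raise AnnotationError("no annotation")
    start, end = span
    if start > end:
        raise AnnotationError(f"invalid span {span}")
    for f in features.features:
        if start <= f.end and end >= f.start:
            warnings.warn(
                f"span {start}-{end} overlaps gene {f.gene}; "
                "intragenic markers are demoted",
                stacklevel=2,
            )
            return f"within {f.gene}"
    upstream = [f for f in features.features if f.end < start]
    downstream = [f for f in features.features if f.start > end]
    if upstream and downstream:
        return IgsName(upstream[-1].gene, downstream[0].gene).label
    return "terminal region"
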