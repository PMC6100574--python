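"""Sample classification from per-marker band patterns.

A marker panel records, per marker, each species group's expected amplicon
sizes (allelic within-group variants are sets, e.g. {249, 250}).  A sample's
observed bands are matched per marker within a tolerance; the sample call
is by concordance across markers:

* unanimous single group on at least ``min_markers`` markers -> that group;
* any marker showing both groups, or markers disagreeing -> mixture
  (adulteration), the double-band logic of mixed commercial products;
* fewer informative markers -> inconclusive.

Predicted (in-silico) band patterns use exact matching; gel-measured sizes
default to ±10% because manual sizing against a ladder is imprecise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .seqio import ConfigError

VERDICT_MIXTURE = "mixture"
VERDICT_INCONCLUSIVE = "inconclusive"

#: default tolerance (fraction of size) for gel-measured band sizes
OBSERVED_TOLERANCE = 0.10


@dataclass
class MarkerPanel:
    """marker -> group -> expected amplicon sizes, plus matching tolerance.

    ``tolerance`` is a fraction of band size (0 = exact).  Group size sets
    must stay disjoint after tolerance expansion, otherwise a band could
    support two species at once and the panel is rejected.
    """

    markers: dict[str, dict[str, set[int]]]
    tolerance: float = 0.0

    def __post_init__(self) -> None:
        self.markers = {
            m: {g: set(map(int, sizes)) for g, sizes in groups.items()}
            for m, groups in self.markers.items()
        }
        self.validate()

    def validate(self) -> None:
        for marker, groups in self.markers.items():
            labels = list(groups)
            for i, ga in enumerate(labels):
                for gb in labels[i + 1 :]:
                    for a in groups[ga]:
                        for b in groups[gb]:
                            if abs(a - b) <= self.tolerance * max(a, b) * 2:
                                raise ConfigError(
                                    f"marker {marker!r}: expected sizes {a} ({ga}) and "
                                    f"{b} ({gb}) overlap under tolerance "
                                    f"{self.tolerance:.0%}"
                                )

    @property
    def group_labels(self) -> list[str]:
        labels: list[str] = []
        for groups in self.markers.values():
            for g in groups:
                if g not in labels:
                    labels.append(g)
        return labels

    def to_json(self, path) -> None:
        payload = {
            "tolerance": self.tolerance,
            "markers": {
                m: {g: sorted(s) for g, s in groups.items()}
                for m, groups in self.markers.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "MarkerPanel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            markers={
                m: {g: set(v) for g, v in groups.items()}
                for m, groups in payload["markers"].items()
            },
            tolerance=float(payload.get("tolerance", 0.0)),
        )


@dataclass
class SampleCall:
    sample_id: str
    evidence: dict[str, dict[str, bool]]  # marker -> group -> present
    verdict: str
    supporting_markers: int = 0


def _matches(band: int, expected: int, tolerance: float) -> bool:
    return abs(band - expected) <= tolerance * expected


def match_bands(
    pattern: Mapping[str, list[int]],
    panel: MarkerPanel,
    *,
    tolerance: float | None = None,
) -> dict[str, dict[str, bool]]:
    """Per-marker, per-group presence evidence for one sample.

    A group is present at a marker iff some observed band matches some
    expected size within the tolerance.  Markers absent from the pattern
    contribute all-absent evidence.
    """
    tol = panel.tolerance if tolerance is None else tolerance
    unknown = set(pattern) - set(panel.markers)
    if unknown:
        raise ConfigError(f"bands reference markers not in the panel: {sorted(unknown)}")
    evidence: dict[str, dict[str, bool]] = {}
    for marker, groups in panel.markers.items():
        bands = [int(b) for b in pattern.get(marker, [])]
        evidence[marker] = {
            g: any(_matches(b, e, tol) for b in bands for e in expected)
            for g, expected in groups.items()
        }
    return evidence


def call_sample(
    evidence: Mapping[str, Mapping[str, bool]],
    *,
    sample_id: str = "",
    min_markers: int = 2,
) -> SampleCall:
    """Species / mixture verdict from per-marker evidence.

    The verdict does not depend on marker or band ordering.
    """
    informative = {
        m: {g for g, present in groups.items() if present}
        for m, groups in evidence.items()
        if any(groups.values())
    }
    n_informative = len(informative)
    if any(len(gs) > 1 for gs in informative.values()):
        verdict = VERDICT_MIXTURE
    else:
        seen = {next(iter(gs)) for gs in informative.values()}
        if len(seen) > 1:
            verdict = VERDICT_MIXTURE
        elif len(seen) == 1 and n_informative >= min_markers:
            verdict = seen.pop()
        else:
            verdict = VERDICT_INCONCLUSIVE
    return SampleCall(
        sample_id=sample_id,
        evidence={m: dict(g) for m, g in evidence.items()},
        verdict=verdict,
        supporting_markers=n_informative,
    )


def classify_samples(
    bands: pd.DataFrame,
    panel: MarkerPanel,
    *,
    tolerance: float | None = None,
    min_markers: int = 2,
) -> pd.DataFrame:
    """Classify a table of observed bands (columns: sample, marker, size_bp).

    Returns one row per sample: verdict, supporting marker count, and a
    per-group summary of which markers supported it.
    """
    required = {"sample", "marker", "size_bp"}
    missing = required - set(bands.columns)
    if missing:
        raise ConfigError(f"bands table lacks columns: {sorted(missing)}")
    rows = []
    for sample, sub in bands.groupby("sample", sort=True):
        pattern: dict[str, list[int]] = {}
        for marker, msub in sub.groupby("marker"):
            pattern[str(marker)] = [int(v) for v in msub["size_bp"]]
        ev = match_bands(pattern, panel, tolerance=tolerance)
        call = call_sample(ev, sample_id=str(sample), min_markers=min_markers)
        row = {
            "sample": call.sample_id,
            "verdict": call.verdict,
            "supporting_markers": call.supporting_markers,
        }
        for g in panel.group_labels:
            row[f"markers_{g}"] = sum(
                1 for groups in ev.values() if groups.get(g, False)
            )
        rows.append(row)
    return pd.DataFrame(rows)


def read_bands_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    return df
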