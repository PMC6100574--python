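"""Shared fixtures: small synthetic genome sets and one full paper-like study."""

from __future__ import annotations

import numpy as np
import pytest

from indeldiag.cli import run_discovery
from indeldiag.seqio import GenomeRecord, SpeciesGroupSet
from indeldiag.synthdata import PlantedIndel, SynthSpec, generate, make_paper_like


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float) -> str:
    """Random substitutions plus short indels — related-sequence generator
    for alignment oracle tests."""
    out = []
    bases = "ACGT"
    i = 0
    while i < len(seq):
        r = rng.random()
        if r < indel_rate / 2:  # deletion
            i += int(rng.integers(1, 4))
            continue
        if r < indel_rate:  # insertion
            out.append(random_seq(rng, int(rng.integers(1, 4))))
        c = seq[i]
        if rng.random() < sub_rate:
            c = bases[int(rng.integers(4))]
        out.append(c)
        i += 1
    return "".join(out)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def paper_like():
    """One paper-like synthetic study plus its full discovery output."""
    truth = make_paper_like(1)
    alignment, regions, pairs, panel = run_discovery(
        truth.group_set, features=truth.features
    )
    return truth, alignment, regions, pairs, panel


@pytest.fixture(scope="session")
def small_truth():
    """A compact 6 kb study: one 347 bp diagnostic insertion, one allelic
    1 bp deletion, one small shared indel — enough structure for every
    pipeline stage at unit-test speed."""
    spec = SynthSpec(
        seed=7,
        base_length=6000,
        group_sizes={"Cw": 2, "Ca": 3},
        indels=[
            PlantedIndel(pos=3000, length=347, kind="insertion",
                         carriers="Cw", region="regionX"),
            PlantedIndel(pos=1200, length=1, kind="deletion", carriers=("Ca2",)),
            PlantedIndel(pos=4600, length=12, kind="deletion", carriers="Ca"),
        ],
        flank=200,
    )
    return generate(spec)


@pytest.fixture
def two_group_records() -> SpeciesGroupSet:
    rng = np.random.default_rng(5)
    base = random_seq(rng, 400)
    a = base
    b = base[:200] + base[230:]  # 30 bp deletion in group B
    return SpeciesGroupSet(
        groups={
            "A": [GenomeRecord(id="A1", species_group="A", seq=a)],
            "B": [GenomeRecord(id="B1", species_group="B", seq=b)],
        }
    )
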