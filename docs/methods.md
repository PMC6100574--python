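# Methods

## Scope and model

`indeldiag` implements marker development for *length-polymorphic InDel
genotyping* between closely related, collinear genomes (the designed-for
case is chloroplast genomes of congeneric plants, ~150–165 kb, >99%
identical). The unit of analysis is the **InDel event**: a maximal run of
multiple-alignment columns sharing one identical gap pattern, with at least
one gapped row. This definition is deliberate:

* it is brute-force checkable by a per-column scan, so the scanner is
  testable against an independent oracle;
* events tile the gapped columns exactly (no overlaps, no gaps), so event
  counts and lengths are well defined;
* adjacent indels with different row patterns split into separate events,
  which matches how "InDel patterns" are counted in comparative plastome
  work.

An event is **diagnostic** when every species group is internally uniform
(all members gapped or all carrying bases) and at least two groups differ;
within-group disagreement marks it **polymorphic-within-group** (allelic
length variants are real and must not be mistaken for species signal);
runs touching the alignment ends are **terminal** and excluded — deposited
organelle genomes are circular molecules linearized at arbitrary origins,
so terminal overhangs are artifacts of linearization, not biology.

Marker candidates are diagnostic events **strictly longer than 100 bp**
(large enough to resolve on agarose as a band-size difference). Events
within 150 columns of a candidate merge into one *marker region*, because a
single amplicon typically spans a cluster of indels and every absorbed
event contributes to the product-size difference.

## Alignment

Two routes produce the alignment:

* **Import**: any externally computed aligned FASTA (Clustal Omega, MAFFT,
  ...) is accepted after verifying that each degapped row reproduces its
  genome exactly.
* **Built-in star alignment**: each non-reference genome is pairwise
  aligned to a reference (default: longest record of the first group) and
  the pairwise gaps are merged into one column space; insertions at the
  same junction are left-justified against each other. Pairwise alignment
  is anchor-and-fill: unique shared *k*-mers (k = 15) are chained by a
  longest-increasing-subsequence pass into the heaviest collinear chain,
  merged into maximal exact blocks, and the short inter-anchor segments are
  closed with global affine DP (Gotoh). Scoring: match +1, mismatch −2,
  and a gap of length L costs 5 + L (open 5, extend 1 per column). Pairs
  small enough for exhaustive DP (≤ ~4·10⁶ cells) skip anchoring entirely,
  so the aligner is provably optimal in the regime where an exhaustive
  oracle can check it. Anchor-free pairs above that size are rejected as
  insufficiently collinear rather than aligned badly; segments larger than
  ~250k cells use a diagonal band (|i−j| ≤ max(64, length difference + 1)).

Determinism matters more than cosmetic alignment choices here: DP ties
resolve in a fixed traceback order and gap runs are then shifted as far
left as score-neutrality allows, so equivalent optimal alignments always
collapse to the same event coordinates. Inversions and rearrangements are
out of scope; the aligner assumes collinearity and the star merge never
reorders blocks.

## Primer design

Candidate primers are enumerated only from alignment windows in which
*every* genome carries the identical unambiguous base, scanning up to
300 columns from each marker edge, nearest windows first. Defaults, chosen
as a design decision to bracket typical plastome genotyping primers
(including all six primers of the published Cynanchum panel, two of which
sit just below 50 °C under the nearest-neighbor model):

| parameter | default | note |
|---|---|---|
| length | 17–27 nt | published panel spans 17–23 |
| Tm | 48–65 °C | NN model; protocol anneals at 55 °C |
| GC | 30–70% | |
| homopolymer | ≤ 5 | |
| 3′ self-complementary run | < 6 nt | lightweight dimer screen |
| specificity | exactly 1 site/genome | both strands, 0 mismatches, 3′-3 nt exact |
| product size | ≤ 2000 bp | |
| band separability | ≥ max(10 bp, 5% of smaller product) | compared between group size *sets* |

Melting temperatures use nearest-neighbor thermodynamics (SantaLucia
unified parameters, via Biopython) at 50 mM monovalent salt and 0.5 µM
total oligo with the entropic salt correction; the Wallace 2(A+T)+4(G+C)
rule is available as a fallback mode. Pairs are ranked by |Tm_f − Tm_r|,
then |mean Tm − 60 °C|, then leftmost forward window, then lexicographic
sequence — a total order, so design is deterministic.

## In-silico PCR

A primer binds where its footprint matches within the mismatch budget
(default 0) *and* its 3′-terminal 3 nt match exactly; template ambiguity
codes never count as matches. Every forward(+)/reverse(−) site combination
within the size cap is reported, in both primer orientations, so swapping
primers or reverse-complementing the template cannot change the predicted
size multiset (both are tested invariants). Product sizes include both
primer footprints — the standard PCR convention, and the one that makes
published expected sizes reproducible. Templates are linear by default
(deposited records are linearized); circular mode virtually extends the
template by (max product size − 1) bases so origin-spanning products are
found once. Gel simulation merges products closer than max(2 bp, 1%) into
one band flagged as an unresolved doublet — a 249/250 bp allelic pair is
one band on 1.5% agarose.

## Classification

A marker panel stores per-group expected size sets; it is rejected if any
two groups' sets overlap after tolerance expansion. Evidence per marker:
a group is present iff some band matches some expected size within
tolerance (exact for predicted patterns; ±10% default for gel-measured
sizes, since manual sizing against a ladder is imprecise). Verdicts:
any marker with both groups present, or markers disagreeing, ⇒ *mixture*;
a unanimous group across ≥ 2 markers ⇒ that species; otherwise
*inconclusive*. Requiring two concordant markers guards against null
alleles at a single locus; the verdict is invariant to marker and band
ordering.

## Synthetic data

The generator builds genomes from a common ancestor (i.i.d. uniform
A/C/G/T; an AT-bias option exists but composition affects no tested
invariant) and applies planted events right-to-left so coordinates stay
valid. One seed drives one generator; identical specs give byte-identical
FASTA.

`make_paper_like(seed)` is the canned study used throughout the tests and
the acceptance script: 2 + 3 accessions of ~150 kb with three diagnostic
regions emulating the published Cynanchum markers —

* a cluster of eight insertions (120, 20, 12, 8, 5, 3, 1, 1 bp within
  ~100 bp) totalling a 170 bp net difference, flanked by `trnQ`/`psbK`
  genes;
* a single 347 bp insertion (`rps2`/`rpoC2`);
* a 110 bp deletion plus 17 bp insertion netting 93 bp, with a 1 bp
  within-group allelic variant inside the region (`psaJ`/`rpl33`) — this
  reproduces the {N, N+1} allelic product sets;

plus 222 small species-level indels, 6 cross-group and 6 allelic indels
(246 planted events in total), and 80 background SNPs. SNPs and background
indels are excluded from a 400 bp window around each diagnostic region, so
conserved primer flanks exist *by construction*.

What this establishes — and what it does not: passing tests demonstrate
that every stage is correct against its oracle and that the pipeline
recovers exactly what was planted under a realistic event census. Real
plastomes additionally have repeats (notably the inverted repeat),
non-uniform composition, and no guarantee of conserved flanks; on real
data a marker can legitimately be undesignable, which the design stage
reports as a result rather than an error. The exact genome-wide InDel
census of a real comparison is also aligner-parameter-dependent, so the
synthetic census (≈246 events) is reported as an order-of-magnitude
quantity, not asserted.

## Numerical and degenerate-input choices

* All external coordinates are 1-based inclusive; BED export converts to
  0-based half-open with an explicit header note.
* `U` maps to `T` on input; IUPAC ambiguity codes are retained but never
  match in exact-match contexts (conservative for primers).
* A gapless alignment yields an empty event list, not an error; a primer
  pair with no products yields an empty amplicon list.
* An insertion event maps, on a gapped row, to the insertion point between
  the two flanking genome positions (0 before position 1).
* Alignments are limited to 63 rows (gap patterns are packed into one
  64-bit code per column).
* The Wallace-rule mode, like the NN mode, accepts 8–40 nt (shorter
  oligos are not meaningful primers and are rejected).

## Problem sizes in the shipped checks

The replicated study used by the test suite and `scripts/acceptance.py`
runs 20 seeds at 150 kb × 5 genomes (~30 s of alignment-dominated compute),
then classifies 50 pure + 10 mixed simulated samples on the first
replicate's panel. Oracle-agreement checks use 1000 random small
alignments for the scanner and 200 random ≤ 200 bp pairs for the aligner —
sizes at which the exhaustive oracles are exact and fast.
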