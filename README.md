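# indeldiag

Species-diagnostic InDel markers from organelle genome alignments: discover
length-polymorphic insertion/deletion loci between closely related species,
design flanking PCR primers, predict amplicon sizes in silico, and classify
unknown samples — including adulterated mixtures — from their gel band
patterns.

## The problem

Closely related medicinal plants are often indistinguishable as dried
material. The motivating case is the authentication of *Cynanchum
wilfordii* (Cw) against its common adulterant *C. auriculatum* (Ca): their
tubers look alike, but their chloroplast genomes differ by hundreds of
small InDels, a handful of which are large (>100 bp), species-uniform, and
sit in intergenic spacers (IGS) where primers can flank them. A single PCR
per marker then separates the species by band size alone — e.g. the
*trnQ-psbK* IGS marker amplifies 249 bp from Cw and 419 bp from Ca, and a
sample showing **both** bands is a mixture.

`indeldiag` turns that workflow into a reproducible tool:

1. **Align** the genomes (import an external MSA, or use the built-in
   anchor-and-fill star aligner: unique shared *k*-mers chained into a
   collinear backbone, inter-anchor segments closed by global affine DP
   with match +1, mismatch −2, gap open −5, gap extend −1).
2. **Scan** the alignment for InDel events — maximal runs of columns with
   an identical gap pattern — and classify each as *diagnostic*
   (species-uniform, groups differ), *polymorphic-within-group* (allelic),
   or *terminal*.
3. **Filter** to events strictly longer than 100 bp, merge nearby events
   into marker regions, and **name** each region by its flanking genes
   (e.g. `trnQ-psbK IGS`).
4. **Design** primer pairs in fully conserved flanking windows
   (length 17–27 nt, nearest-neighbor Tm 48–65 °C, GC 30–70%, unique
   binding site per genome, between-group band gap ≥ max(10 bp, 5%)).
5. **Predict** per-genome products in silico (both strands, 3′-exact
   binding, product size includes both primer footprints) and simulate the
   gel (bands within max(2 bp, 1%) co-migrate).
6. **Classify** samples from band tables: unanimous markers call the
   species, any double-band or discordant marker calls a mixture.

## Worked example

Everything below runs offline on a simulated study whose ground truth is
known exactly (two Cw-like and three Ca-like ~150 kb genomes, three planted
diagnostic regions with net length differences 170, 347 and 93 bp, ~234
background InDels and SNPs):

```sh
indel-diag simulate --seed 7 --out demo/fixture
indel-diag discover \
    --genomes demo/fixture/genomes.fasta \
    --groups demo/fixture/groups.tsv \
    --annotation demo/fixture/genes.gff3 \
    --out demo/out
```

`demo/out/markers.tsv` (header comments trimmed):

```text
marker_id    name            reference  ref_start  ref_end  n_events  net_size_difference_bp
trnQ-psbK    trnQ-psbK IGS   Cw2        19946      20028    8         170
rps2-rpoC2   rps2-rpoC2 IGS  Cw2        60046      60392    1         347
psaJ-rpl33   psaJ-rpl33 IGS  Cw2        100314     100534   3         93
```

All three planted regions are recovered, each named by its flanking genes,
with the planted net size difference. `demo/out/primers.tsv` holds one
ranked pair per marker, e.g. for `rps2-rpoC2`:

```text
forward  GCTTCATTTGAAGGGTTCGGAAGTCG   Tm 61.13 C
reverse  ATTCTGTTAACCGTCGTGAAAAGACCA  Tm 59.58 C
```

and `demo/out/panel.json` records the expected per-group product sizes —
here Cw 400 bp vs Ca 53 bp at that marker, a 347 bp gap, exactly the
planted insertion. Note the `psaJ-rpl33` entry: Ca expects {178, 179}
because one Ca accession carries a 1 bp allelic variant inside the
amplicon, so group size *sets* (not single values) drive classification.
Predicted products for any genome set come from `indel-diag ispcr`, and
`indel-diag classify --panel panel.json --bands bands.tsv` turns an
observed band table into per-sample verdicts (`Cw` / `Ca` / `mixture` /
`inconclusive`).

The published six-primer Cynanchum panel ships as data in
`indeldiag.published` and can be evaluated directly against the five
deposited accession genomes once fetched.

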