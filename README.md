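# stowaway-kit

A toolkit for the discovery, classification and population genotyping of
**Stowaway-like MITEs** (miniature inverted-repeat transposable elements) in
plant genomic sequence. Stowaway elements are short (< 500 bp), AT-rich,
non-autonomous class II transposons bounded by terminal inverted repeats
(TIRs) whose outermost bases carry a conserved `CTCCCT` motif; on insertion
they duplicate a `TA` target dinucleotide, leaving a `TA` target-site
duplication (TSD) on both sides. That simple signature makes the whole life
cycle of an element locally decodable from sequence: presence, family,
nesting inside another element, excision footprints, and presence/absence
polymorphism across accessions.

The package is aimed at researchers analysing transposon content in genomes
or clone libraries (BACs, BAC-end sequences) of non-model plants, and at
anyone needing a fully synthetic, ground-truthed benchmark for MITE-calling
methods.

## What it computes

- **Structural mining** (`stowaway_kit.miner`): scan sequence for
  `TA + CTCCCT ... reverse-complement + TA` structures, extending the TIR
  inward under a mismatch budget; candidates carry AT content and a hairpin
  score (Nussinov maximum base-pairing fraction). A k-mer-seeded local
  alignment search with TSD/TIR/flank validation covers homology-based
  mining of clone-end databases.
- **Family classification** (`stowaway_kit.families`): the 80-80-80 rule —
  two elements are in one family when a global alignment shows ≥ 80 %
  identity over ≥ 80 % of the shorter sequence, for elements ≥ 80 bp;
  families are single-linkage connected components. Per-family consensi
  (star alignment, IUPAC ties), Kimura two-parameter distances
  d = −½ ln((1−2P−Q)√(1−2Q)) and Saitou–Nei Neighbor-Joining trees in
  newick.
- **Copy number** (`stowaway_kit.copynumber`): from a BAC-library PCR
  screen, the one-element-per-positive-clone estimator
  (density = positives / (clones × clone size)) plus a Poisson-corrected
  variant λ = −ln(1 − positive fraction), both with exact Clopper–Pearson
  intervals.
- **Local structure** (`stowaway_kit.structure`): nested-insertion
  detection (including the Tourist-style `TTA` TSD), reconstruction of
  pre-insertion states, classification of locus haplotypes into
  occupied / empty / footprint / internal-deletion / clustered / complex,
  and in-silico PCR (flanking-primer and single-TIR-primer modes).
- **Synthetic genomes** (`stowaway_kit.synthetic`): AT-rich backgrounds
  with planted element families, nested insertions, locus populations and
  simulated clone libraries — each with a machine-readable truth ledger.

## Worked example

The carrot BAC screen that motivated the copy-number module: 141 clones
screened with a TIR-anchored primer, 87 positive, mean clone size
0.121 Mbp, diploid genome ≈ 980 Mbp.

```bash
$ stowaway-kit copy-number --clones 141 --positive 87 \
      --clone-size-mbp 0.121 --genome-size-mbp 980
{
  "method": "naive",
  "density_per_mbp": 5.099349393353262,
  "spacing_kb": 196.10344827586206,
  "spacing_kb_rounded": 196,
  "copies": 4997.362405486197,
  "copies_3sf": 5000,
  "lambda": null,
  "ci": [
    4304.393965969359,
    5649.625095023788
  ]
}
```

Read: one element per ~196 kb, hence ≈ 5,000 copies per diploid genome,
with a 95 % exact binomial interval of roughly 4,300–5,650. Adding
`--method poisson` corrects for clones carrying more than one element and
raises the estimate to ≈ 7,770.

A full synthetic round trip from one config file:

```bash
$ cat demo.yaml
seed: 5
simulate:
  genome_length: 150000
  n_insertions: 12
$ stowaway-kit run demo.yaml --out demo_out
```

which simulates a genome, mines it (`candidates.gff3`, `candidates.bed`,
`elements.fasta`), clusters families (`families.tsv`, `consensus.fasta`,
`families.nwk`), screens simulated clones for copy number and scans for
nested insertions, logging recall/precision against the planted truth in
`run_log.json`.

Other subcommands: `simulate`, `mine`, `homology-search`, `classify`,
`nested`, `genotype`, `pcr` (see `stowaway-kit --help`).

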