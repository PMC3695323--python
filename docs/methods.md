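# Methods

This note documents the models, algorithms and numerical conventions behind
stowaway-kit, the defaults it ships with and why, what the synthetic data
do and do not emulate, and the design choices made where more than one
reasonable option existed.

## Coordinates and sequence model

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
produced only at the I/O boundary. An element span runs from the first base
of the left TIR to one past the last base of the right TIR and **excludes**
the TSD: the flanking `TA` dinucleotides are implied by the span, which
avoids double-counting the duplicated target. Sequences are uppercase
`{A,C,G,T,N}`; `N` never matches a motif, never base-pairs, and is excluded
from AT-content tallies.

## Synthetic data generator

The generator emulates the sequence context these elements live in:

- **Background**: i.i.d. bases with P(A)=P(T)=at/2, P(C)=P(G)=(1−at)/2.
  Defaults draw the AT fraction in the observed 0.60–0.72 range of the
  elements' hosts.
- **Families**: a consensus of default length 274 bp (the length of the
  founding element of the best-studied family) with 16 bp TIRs whose
  outer 6 bp are `CTCCCT`; the right TIR is the reverse complement of the
  left. AT content of the non-motif positions is composition-controlled so
  the consensus lands within ±0.02 of the requested fraction. Copies are
  the consensus mutated by i.i.d. substitutions (uniform over the three
  alternatives, default rate 0.05/site) and single-base indels (default
  0.002/site, equal insert/delete odds); the terminal motifs are immutable.
  `generate_family(..., indel_protect_tirs=True)` additionally keeps the
  whole TIR free of indels, modelling copies whose termini remained
  structurally intact — the condition under which recovery benchmarks are
  defined. Substitutions inside the TIR beyond the motif remain possible
  in both modes.
- **Insertions** replace one `TA` with `TA + element + TA`. Sites are
  sampled uniformly from TA occurrences with a minimum spacing
  (default 100 bp); no empirical spacing distribution was available, so
  spacing is a plain configurable scalar, not a fitted model.
- **Nested insertions** place an inner element at a `TA` inside an
  existing copy, at least 20 bp clear of the outer TIRs, and record the
  parent in the truth ledger.
- **Locus populations** build per-accession haplotypes: occupied
  (flank + TA element TA + flank), empty (single TA), footprint (empty plus
  a 1–10 bp residual indel at the junction; footprints are known to vary in
  length with no published distribution, so the residual is uniform),
  internal deletion (a contiguous 20–80 % slice removed, allowed to take a
  TIR terminus with it — only the class label is guaranteed), and clustered
  (a second element within 100 bp upstream).
- **Clone libraries** are uniform random substrings with truth counts of
  fully-contained intact elements.

Every operation takes an explicit integer seed and derives an independent
numpy generator, so outputs are byte-reproducible.

**What the generator does not emulate**: real chromosomal heterogeneity
(gene space vs heterochromatin, the observed depletion near centromeres and
telomeres), insertion-site preference beyond the TA requirement,
recombination, methylation, and truncated or TIR-less fossil copies outside
the modelled variant classes. Passing benchmarks on this generator
therefore demonstrates algorithmic correctness under the stated sequence
model, not performance on a real genome assembly.

## Structural scanner

Occurrences of the terminal motif and of its reverse complement are paired
within a length window (defaults: 80–600 bp; the upper bound generously
covers the < 500 bp size class), the TIR is extended inward from the
termini while mismatched columns stay within a budget (default 2), and the
TIR must reach a minimum length (default 13 bp, the shortest observed).
With `require_tsd` (default), `TA` must sit immediately outside both
termini. A Stowaway element reads identically on both strands at the
structural level (left TIR starts with the motif ⇔ right TIR ends with its
reverse complement), so the reverse-complement scan of each record maps
onto the same loci; both are run and deduplicated, and candidates are
always reported in motif-leading orientation with strand `+`.

Overlap resolution keeps, among partially overlapping candidates, the one
with the longer TIR, then fewer TIR mismatches, then greater length, then
leftmost position. Strictly nested candidates are *both* kept and handed
to the nested-insertion detector, because true nesting occurs.

The **hairpin score** is the Nussinov maximum number of nested Watson–Crick
pairs (minimum loop 3, G·U off by default) divided by ⌊length/2⌋ — a
dependency-free, monotone proxy for secondary-structure-forming potential;
it is reported as an annotation, never used as a filter.

## Homology search

Exact 11-mers seed candidate windows; each window is refined with an
affine-gap Smith–Waterman alignment (match +1, mismatch −1, gap open −4,
extend −1). Hits require identity ≥ 0.6 over ≥ 50 % of the query. Identity
and aligned-fraction thresholds replace database-size-dependent e-values,
which are not reproducible without a specific statistics implementation.
Validation applies the clone-end mining filters: TSD present, a TIR pair
detectable within 5 bp of the hit boundaries, and ≥ 100 bp of flank on both
sides.

## Alignment, distances, trees

Global alignments are Needleman–Wunsch with affine gaps (open −4 covers the
first gap base, extend −1 each further base; end gaps penalized). Identity,
coverage (denominator: the shorter raw sequence — the stricter, symmetric
reading of "over 80 % of their length"), transition proportion P and
transversion proportion Q are tallied over columns where both rows carry a
base (pairwise deletion). K2P distance is
d = −½ ln((1−2P−Q)√(1−2Q)); arguments at or past saturation raise an
explicit error rather than returning NaN.

Family membership uses single-linkage connected components of the 80-80
relation; the literature states no linkage rule, and single linkage is the
most permissive deterministic choice. Family numbering is by descending
size, then smallest member id, so output is order-invariant.

Consensus building is a star alignment to the longest member: per-column
majority on reference coordinates, ties encoded as IUPAC codes
(T/C → Y, A/G → R, …), majority-gap columns removed. A star alignment is
adequate at intra-family divergences ≤ 20 % and avoids a progressive-MSA
dependency. Because "average similarity" can mean either statistic, both
mean pairwise identity and star-MSA column identity are provided, labelled.

Neighbor-Joining is the canonical Saitou–Nei agglomeration. Determinism is
pinned down: Q-ties break to the lexicographically smallest label pair
(internal nodes inherit the smallest leaf label beneath them); negative
branch lengths are clamped to zero with the deficit transferred to the
sibling branch, preserving the pair's summed length; the final edge is
split evenly between the last two subtrees, which preserves all leaf-pair
path lengths. On additive matrices the output reproduces path distances to
1e-9. Newick serialization orders children by smallest descendant leaf
label, so serialize→parse→serialize is idempotent.

## Copy number

The naive estimator takes one element per positive clone, exactly as the
screen it models was analysed: density = k/(n·c) elements/Mbp,
spacing = 1000/density kb, copies = G·density (n clones, k positive, c
clone size in Mbp, G genome size in Mbp). With the screen's published
inputs (141, 87, 0.121 Mbp, 980 Mbp) this yields one element per 196 kb
and ≈ 5.0 × 10³ copies. The Poisson estimator treats clone occupancy as
Poisson(λ = density·c), so λ = −ln(1−k/n); it is always ≥ the naive
estimate (−ln(1−p) ≥ p) and quantifies the multi-hit clones the naive
reading ignores — with the same inputs, ≈ 7.8 × 10³ copies. Whether any
screened clone truly carried multiple elements is unknown; the gap between
the two estimators surfaces that open question rather than resolving it.
Confidence intervals are exact Clopper–Pearson on the positive fraction,
propagated through the (monotone) estimator. Text summaries round spacing
to the nearest kb and copies to 3 significant figures; machine output keeps
raw values.

## Locus-variant classification

Decision rules, in order: (1) reference flank anchors (30 bp each side)
must align in the observed haplotype — checked both directly and after
excising any detected elements, since a clustered insertion may legally
interrupt an anchor (documented cases sit 20 and 48 bp upstream); the
anchor demand is ≥ 90 % identity over the anchor minus a footprint
allowance, because a footprint may erode up to 10 junction-proximal bases.
Failure is an error (wrong locus), not a class. (2) Two or more structural
candidates within 100 bp → *clustered*; the 100 bp window covers the
documented 20 and 48 bp cases with margin. (3) One candidate ≥ 90 % of the
reference element length → *occupied*. (4) Otherwise the haplotype is
aligned to the reconstructed empty site: zero residual bases at the
junction → *empty*; a 1–10 bp residual → *footprint*; a larger junction
insertion that aligns to the element with a contiguous gap or length
deficit ≥ 20 bp → *internal_deletion*; anything else → *complex*.
Reconstruction of a pre-insertion state excises the element plus one TSD
copy, keeping the left TA by convention (string-identical either way for a
TA duplication).

## In-silico PCR

Primer sites require at most 2 mismatches with the 3′-terminal 3 bases
exact — a standard proxy for polymerase extension fidelity, since no
empirical tolerance was available. All convergent site pairs within
5 kb are reported. Single-primer mode reuses one primer on both strands,
reproducing TIR-anchored amplification of full-length elements; note that a
TIR primer whose 5′ end begins with `TA` yields products spanning the
element plus both TSD copies (element length + 4).

## Benchmark problem sizes

The standard miner-recovery panel is ten 500 kb genomes carrying 200
planted copies in total, three families per genome with divergence drawn
U[0.01, 0.05], indel rate 0.002 outside the TIRs and intact termini; the
classification panel is 3 families × 8 copies at 5 % divergence; the
genotyping panel is 5 loci × 40 accessions with class frequencies
(0.30 occupied, 0.25 empty, 0.15 footprint, 0.15 internal deletion,
0.15 clustered). These sizes exercise every code path while keeping a full
run in tens of seconds on one core.

## Known limitations

- The scanner is motif-anchored: families whose terminal motif has decayed
  beyond the configured degenerate pattern are invisible to structural
  mode (homology mode can still find them).
- Copy-number estimators assume random clone sampling and perfect PCR;
  pooled-plate deconvolution and false negatives are out of scope.
- The genotyper assumes haplotype-resolved locus sequences; it does not
  call variants from reads.
- NJ is exact on additive matrices but, like all NJ implementations, gives
  no support values; bootstrap resampling is out of scope.
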