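# Methods

This note documents the models, conventions and numerical choices behind
`multisit`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and motif grammar

All coordinates in APIs and outputs are 1-based inclusive. Motif
consensus patterns consist of fixed residues, `X` (any of the 20 amino
acids, never a gap) and bracketed residue classes (`C[MI]LD`). Scanning
is exhaustive over all windows; counting operations (motif presence,
anchor counting) use leftmost non-overlapping hits so tandem copies are
not double-counted. Gapped rows must be degapped before residue-space
scanning; `scan_alignment_row` maps hits back to alignment columns
through the row's gap map. A column of a multiple alignment is
*absolutely conserved* only when every row carries the same residue and
no row has a gap — a 100% consensus over fewer rows does not qualify.

## Segmentation of multi-SITs

A multi-SIT is dissected into one putative mature unit per CMLD anchor.
Between consecutive anchors, the cleavage point is the first residue of a
DXDID boundary hit — the boundary residue starts the downstream fragment,
matching the convention used for CMLD→DXDID distance measurements. When
several boundary hits fall between two anchors, the hit minimising
|upstream-unit length − target (441)| wins, ties to the leftmost; when
none does, the cleavage is placed to give the upstream unit the target
length and the unit is flagged `boundary_motif_found=False`. "Analogue"
motifs can be admitted by listing extra anchor/boundary patterns in the
configuration; the default is the strict pattern only.

Raw inter-boundary segments include flank and linker residues. The
envelope of the mature unit is obtained either by fixed margins
(default (0, 0), i.e. no trimming) or, when a reference mature unit is
supplied, by globally aligning the reference to the segment with free end
gaps on the segment side: the envelope is the segment span aligned to the
full reference. Alignment scoring is BLOSUM62 with gap open 10 / extend 1
(configurable). The same scoring backs reference-position mapping and the
identity/similarity measure (identity = identical aligned residues over
alignment columns; similarity additionally counts pairs with positive
substitution score; both exclude nothing else, so gap columns count
against both).

Distance records pair each CMLD cysteine (the C is the first motif
residue) with the nearest downstream DXDID first residue; anchors with no
downstream boundary (the last unit) yield no record, so an n-unit protein
yields n−1 records. The histogram uses a 5-residue bin width by default —
fine enough to resolve a narrow band without overfitting.

## Transmembrane topology

The predictor is a deliberately simple single-pass hydropathy heuristic,
not a reimplementation of TmPred or an HMM: per-residue Kyte–Doolittle
values averaged over a centred window of 19 (shrunken at the termini),
thresholded at 1.6; runs separated by ≤ 3 residues are merged; runs
shorter than 15 are discarded; a run longer than 25 is split recursively
at its interior profile minimum, but only when both halves can still
reach 15 residues — a marginally over-long run (26–30) is kept whole
rather than shattered into sub-threshold fragments, since only a genuinely
merged double helix (≳ 31) produces two valid segments. Orientation
(cytoplasmic/extracellular faces) is not predicted. Motif membrane
context is `edge-of-TM` if the hit overlaps a segment boundary ± 5
residues, `inside-TM` if fully interior to a segment, else
`extramembrane`.

## Gene-level conventions

A gene is its CDS, start codon through stop codon inclusive; intergenic
(spacer) distance counts bases strictly between two CDSs. Protein length
excludes the terminal stop. ORF finding reports every ATG→stop span of at
least the minimum length on both strands (minus-strand ORFs in forward
coordinates); `longest_per_stop` keeps only the most upstream in-frame
start per stop. Translation uses the standard codon table unless
configured; in strict mode an internal stop is an error with its residue
position. Paralog identity is global-alignment identity (unit-cost
alignment via edlib) plus an explicit byte-identity flag, because the
gene-conversion argument rests on two copies being literally identical,
not merely similar.

In-silico PCR matches the forward primer on the plus strand and the
reverse complement of the reverse primer downstream on the same strand;
IUPAC codes match their base sets; up to a configurable number of
mismatches is tolerated, but never in a primer's 3′-terminal three bases
(mimicking polymerase extension requirements). Product length spans the
forward site start to the reverse site end, inclusive.

## Degenerate primers

`back_translate` maps each residue to the minimal IUPAC triplet covering
all its codons and reports the *codon-count* degeneracy (product of codon
counts; CMLD → 2×1×6×2 = 24). A `DegeneratePrimer`'s `degeneracy` field
is the *IUPAC-expansion* count (product of per-position ambiguity-set
sizes). The two differ whenever a residue's codon set is not a full
cross-product (Leu: 6 codons, but `YTN` spans 8 triplets); both are
documented and tested. Consensus construction takes the smallest IUPAC
code covering the observed bases per column and reports per-column
persistence (modal-base fraction). Pair design takes the leftmost window
for the forward primer and the rightmost for the reverse, trimming each
primer from its 5′ end until the degeneracy cap (default 128) is met
within the length bounds (default 17–29 nt); inosine is not used.
Melting-temperature and dimer screening are out of scope.

## Phylogenetics

Distances are p-distances (mismatch fraction over columns where both rows
are residues). Tree inference is neighbor joining via scikit-bio —
a desk-scale stand-in chosen for determinism and exactness on additive
matrices, not a substitute for likelihood inference with bootstrap on
real data; the alignment can be exported for external ML tools. Negative
NJ branch-length estimates are clamped to zero with a warning. Monophyly
is tested unrooted: a subset is monophyletic iff some edge bipartition
isolates it (the tip set below a node, or its complement).

## The synthetic-data generator

The generator is first-class, tested code: every emitted dataset carries
a `SyntheticTruth` record (unit envelopes, motif positions, TM stretches,
boundary positions, gene loci, spacer length) that round-trips losslessly
through a TSV sidecar.

**Mature unit** (default 441 residues): background residues uniform over
the 20 amino acids; ten 27-residue hydrophobic stretches at fixed offsets,
drawn from {A,I,L,F,V,M,W} with I/L/V-dominant weights (mean KD ≈ 3.9),
each delimited by six charged/polar flank residues (K,R,D,E,N,Q) in the
manner of the positive-inside rule; the first and last stretches sit
flush with the termini. One CMLD at position 71 abutting the second
stretch (edge of a hydrophobic region), four GXQ, one YQXDXVYL, and the
invariant loop residues Q104, N115, H190, Y193, S229, S372. Chance extra
anchor/boundary matches in the background are removed by redrawing a
non-planted residue, so motif counts are exact by construction. The
charged flanks and weighted hydrophobic draws are what make the planted
architecture *detectable by construction* under the default predictor:
with uniform draws the above-threshold runs of a planted helix straddle
the minimum-length and split thresholds and "exactly 10" fails in a
substantial fraction of units. With the shipped defaults, 3000/3000 seeded
units and 100/100 triplicates yield exactly 10 called segments per unit.
Because edge windows average in the charged flanks, a called segment is
systematically a few residues narrower than its planted stretch
(~78% coverage, midpoint always interior) — tests assert midpoint
containment and ≥ 70% coverage.

**Multi-SIT** (default 3 units): unit copies joined by 15-residue linkers
carrying exactly one centred boundary motif (`DSDID`, matching DXDID);
N-flank of 30 residues starting with Met and C-flank of 33, so the
default triplicate totals 3×441 + 2×15 + 63 = 1416 residues — the scale
of a real triplicate gene product. Flank/linker residues touching a unit
are charged/polar, consistent with the aspartate-rich character of real
inter-unit linkers. Point-substitution noise at `mutation_rate`
(default 0) is applied last; by default it never touches planted motifs,
invariant residues or the initiator Met (configurable off). All
randomness flows from the single spec seed.

**Gene cluster**: the multi-SIT protein is reverse-translated
deterministically (lexicographically first codon per residue) and placed
twice — byte-identical copies by default, emulating a gene-conversion
pair — separated by a 5239-bp non-coding spacer, with a diverged third
copy (default 0.1 substitutions/site, internal stops repaired) on a
second contig. Deterministic back-translation can leave entire shifted or
reverse reading frames free of stop codons, which would surface as
spurious gene-length ORFs; the CDS is therefore post-processed by
synonymous-codon stop seeding (protein unchanged, deterministic) so every
non-genuine frame has stops at least every `orf_floor` (300) bases, and
the pads around genes and spacer carry stops in all six frames. The
spacer itself is purged of ORFs ≥ `orf_floor`.

**Supplementary-scale stand-ins**: `make_unit_alignment` builds an
87-record mature-unit alignment (nine mutually similar *Synedra*-labelled
rows plus diverged rows across 15 nominal species) in alignment space —
fixed insertion-slot columns and loop deletions give degapped lengths in
[436, 446] — with CMLD ablated in exactly three records (two `Es`, one
`Ld`) and a planted tryptophan column that is absolutely conserved at
alignment position 466. `make_multisit_panel` builds 48 multi-SITs of
which exactly 43 carry a DXDID-matching motif in every inter-unit linker.
These stand-ins reproduce the *reported structure* of the corresponding
published supplementary datasets so the same computations can be
exercised end-to-end; they are synthetic and make no claim to the real
sequences' content. Consequently, passing tests demonstrate that the
algorithms measure planted facts correctly — not that real data would
yield the same numbers.

**What the generator does not emulate**: codon usage bias, introns, UTRs,
insertion/deletion noise within units (substitutions only, except the
alignment stand-in's fixed slots), compositional heterogeneity across
species, or profile-HMM-defined domain envelopes (the paper-scale
workflow's Pfam envelopes are replaced here by reference-alignment
trimming).

## Numerical and degenerate-input choices

- Conservation consensus ties break alphabetically; all-gap columns get
  consensus `-`, fraction 0.
- `mutate` substitutes each unprotected position with probability `rate`
  to a uniformly drawn *different* character, so the expected substituted
  fraction equals `rate` exactly; two independently mutated copies match
  at a site with probability (1−r)² + r²/19.
- Envelope trimming with margins that would invert a segment falls back
  to the untrimmed segment.
- `boundary_positive` requires at least two anchors; a single-unit
  protein has no inter-unit boundary to test and is counted negative.
- Empty inputs: scanning an empty sequence returns an empty hit list;
  empty FASTA reads warn and return an empty set; an empty annotation run
  produces an empty, schema-stable report.

## Problem sizes

Tests and the acceptance script run entirely on synthetic data at the
study's own scales: 441-residue units, 1416-residue triplicates, ~14-kb
cluster contigs, 87×503 alignments, 48-sequence panels, and 100 seeded
replicates for the noise-robustness check. The full suite completes in a
few seconds on one CPU.

## Known limitations

- The hydropathy heuristic is not TmPred; on real SIT sequences its
  segment count may deviate from published topology by ±1, and only the
  synthetic count property is asserted exactly.
- Unit start/end positions from reference-alignment trimming can differ
  by a few residues from envelopes defined by a profile HMM even when
  lengths agree.
- NJ on p-distances recovers relative topology among the sequences given;
  clade assignment against external reference sets and bootstrap support
  are out of scope.
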