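# multisit

A sequence-analysis toolkit for **multi-domain diatom silicon transporters
(multi-SITs)** — single reading frames that encode two or three ~440-residue
silicon-transporter (SIT) units fused head-to-tail, as found in *Synedra*
and a range of other diatoms.

Diatoms import silicic acid through SIT membrane proteins: ten
transmembrane (TM) helices, one highly conserved extramembrane **CMLD**
motif at the edge of a hydrophobic region, four **GXQ** motifs, and a
handful of invariant residues per functional unit. Multi-SIT gene products
carry several such units, joined by linkers containing the aspartate-rich
**DXDID** motif (a candidate proteolysis site) and the **YQXDXVYL** motif;
the working hypothesis is that post-translational cleavage at DXDID
releases "mature" SITs of 436–446 residues. The toolkit provides the desk
computations this kind of study runs:

- **motif scanning** with consensus patterns (fixed residues, `X`
  wildcards, `[..]` residue classes) and per-column conservation profiling
  of multiple alignments;
- **segmentation** of a multi-SIT into putative mature units, anchored on
  CMLD and cleaved at DXDID (first boundary residue starts the downstream
  fragment), with envelope trimming by alignment to a reference unit;
- **CMLD→DXDID distance** records and histograms;
- **TM topology** by windowed Kyte–Doolittle hydropathy
  (window 19, threshold 1.6, minimum run 15) and membrane-context labels
  for motif hits (`inside-TM` / `edge-of-TM` / `extramembrane`);
- **gene-level analysis**: ORF finding, translation, intergenic (spacer)
  distances, paralog identity (the gene-conversion signature of two
  byte-identical tandem copies), and in-silico PCR with IUPAC-degenerate
  primers;
- **degenerate primer design** by back-translation and nucleotide-consensus
  construction, as used to fish SIT genes out of genomic DNA via the CMLD
  coding region;
- **neighbor-joining trees** on p-distances with monophyly queries;
- a **synthetic-data generator** that emits all of the above with planted
  ground truth (unit envelopes, motif positions, TM stretches, gene loci,
  spacer length), so every stage is testable without any external data.

## Worked example

Generate the default synthetic triplicate — 3 × 441-residue units plus
linkers and flanks, 1416 residues in total, matching the scale of a real
triplicate SIT gene product — and annotate it:

```python
from multisit.simulate import MultiSitSpec, make_multi_sit, ancestral_unit
from multisit.pipeline import annotate

spec = MultiSitSpec(seed=2)
protein, truth = make_multi_sit(spec)
report = annotate({"SuSIT_like": protein}, reference=ancestral_unit(spec))
print(report.units.to_string(index=False))
print(report.distances.to_string(index=False))
```

prints

```
sequence_id ordinal  start  end  length  cmld_count  gxq_count  length_ok  boundary_found  tm_segments
 SuSIT_like       A     31  471     441           1          4       True            True           10
 SuSIT_like       B    487  927     441           1          4       True            True           10
 SuSIT_like       C    943 1383     441           1          4       True            True           10

sequence_id unit_ordinal  cmld_cys_pos  dxdid_first_pos  distance
 SuSIT_like            A           101              477       376
 SuSIT_like            B           557              933       376
```

Three mature units labelled A–C in N→C order, each 441 residues (inside
the 436–446 window), each with exactly one CMLD, at least four GXQ hits
and ten predicted TM segments; the two inter-unit boundaries give
CMLD-cysteine→DXDID distances of 376 residues each — the narrow-band
behaviour expected when the motifs' relative placement is conserved.

The same stages are available from the shell:

```
multisit simulate --seed 4 --out-prefix demo
multisit scan demo.protein.fasta --pattern CMLD --pattern DXDID
multisit segment demo.protein.fasta
multisit orfs demo.genome.fasta --min-length 3000 --longest-per-stop
multisit design-primers --peptide CMLDFIN
multisit annotate demo.protein.fasta
```

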