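# nnrr-regulon

Regulon mapping for the *Bradyrhizobium diazoefficiens* NnrR transcription
factor — a tested, reusable pipeline for the analysis chain that defines an
expanded NnrR regulon from microarray-style expression data:

1. **Detection-filtered differential expression.** A gene is differentially
   expressed in a contrast when it is called present/marginal (P/M) in at
   least 2 of 3 replicates, passes a two-sided pooled-variance Student
   *t*-test at *p* < 0.01 on log₂ intensities, and has a signed fold change
   FC ≥ 2 or ≤ −2 (FC = ratio of linear-scale group means, reported as
   −1/ratio below 1).
2. **Directional set intersection.** The candidate regulon is the overlap
   of two contrasts — ΔnnrR vs wild type (both anoxic, denitrifying) and
   wild-type anoxia vs oxia — narrowed to genes *induced* by anoxia in the
   WT (FC ≥ +2) and simultaneously *downregulated* in the mutant
   (FC ≤ −2): the signature of positive NnrR control.
3. **Transcriptional-unit grouping.** Candidates are grouped into operons
   by a distance rule (same strand, intergenic gap ≤ 200 bp) and the
   promoter window (default 600 bp) upstream of each unit's lead-gene
   start codon is extracted, strand-aware.
4. **FixK₂-box scanning.** Promoter windows are scanned on both strands
   for the 14 bp palindromic FixK₂-box consensus **TTGA/C-N₆-T/GCAA**
   (IUPAC `TTGMNNNNNNKCAA`), tolerating up to 2 mismatches over the eight
   constrained positions (Hamming distance; the six spacer positions are
   free). A divergent promoter pair can share a single intergenic box.
5. **Pfaffl qRT-PCR arithmetic.** Validation fold changes are computed as
   efficiency-corrected ratios, ratio = E_t^ΔCq_t / E_r^ΔCq_r, normalized
   to the sigma-factor gene *sigA*.

A first-class synthetic-data generator builds annotated genomes with
planted boxes and matched expression/Cq data, so the whole chain is
testable end to end with exact ground truth. The published 60-gene /
42-unit candidate table ships as a packaged transcription for regression
checks. (The study's deposited expression series is GEO accession
GSE130684; it is not required and never downloaded.)

## Worked example

Parse the packaged candidate table:

```text
$ nnrr-regulon report
{
  "gene_records": 60,
  "motif_units": 42,
  ...
}
```

60 genes organized in 42 box-associated transcriptional units, every row
with mutant FC ≤ −2 and WT FC ≥ +2 and every printed motif within 2
mismatches of the consensus.

Run the full pipeline on a seeded synthetic study (writes the input
bundle, then every stage's outputs):

```text
$ nnrr-regulon run --simulate-inputs --seed 7 --out demo_out
{
  "candidates": {
    "genes": 16,
    "units_with_box": 7
  },
  "qpcr_pfaffl": {
    "sg0006": -2.637345111271759,
    ...
  },
  "set_intersection": {
    "mutant_diff": 16,
    "nnrr_activated": 16,
    "overlap": 16,
    "wt_anoxia_diff": 16
  }
}
```

All 16 planted regulon genes (five transcriptional units of sizes
1/7/1/3/2 plus one divergent gene pair sharing a single box) pass both
contrasts, land in the directional overlap, and all 7 units report a box.
The candidate table mirrors the published table's columns:

```text
locus_tag  fc_mutant  fc_wt  gene_name  product  position  motif           operon_structure
sg0006     -3.49      6.76   -          -        -188      TTGATTGCTCGCAA  -
sg0018     -6.42      15.38  -          -        -60       TTGAACTTTTTTAA  sg0018-sg0017-...-sg0012
```

`position` is the offset of the box's 5'-most base from the lead gene's
start codon (upstream negative); member genes of a polycistron inherit
the operon string while motif/position stay on the lead row. The Pfaffl
stage recovers the planted mutant-vs-WT fold changes from the simulated
Cq table (e.g. sg0006: FC −2.6 from noisy triplicate Cq values).

Stage-by-stage subcommands (`simulate`, `de`, `venn`, `units`, `scan`,
`pfaffl`, `report`) expose the same library functions individually; YAML
configs with per-threshold overrides are accepted by `run --config`.

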