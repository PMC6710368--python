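# Methods

This note records the model choices, parameter defaults, and numerical
conventions behind the pipeline, and what the synthetic-data tests do and
do not demonstrate about real data.

## Differential-expression filter

The filter reproduces the classic present/marginal/absent (P/M/A)
microarray workflow. Three clauses gate a gene per contrast:

* **Detection.** Called P or M in at least `min_called` (default 2) of
  the replicates of a group. The original wording ("2 out of the 3
  replicates") does not say whether detection is required in one group or
  both; the default (`detection_rule="either"`) keeps a gene testable
  when it is absent under one condition but induced under the other —
  exactly the genes a regulon search is after. `detection_rule="both"`
  gives the stricter reading.
* **Significance.** Two-sided pooled-variance Student *t*-test on log₂
  intensities (`log_transform=True` default). Variance stabilization on
  intensity data is standard; a linear-scale flag exists for comparison.
  No multiple-testing correction is applied by default, matching the raw
  *p* < 0.01 threshold convention of the source analysis; with ~10,000
  genes this admits ~1% false positives by design, which the downstream
  fold-change clause and set intersection then cut down. A
  Benjamini–Hochberg mode (`p_adjust="bh"`) thresholds adjusted p-values
  instead for users who want FDR control; reported p-values stay raw.
* **Effect size.** Signed fold change of linear-scale group means
  (|FC| ≥ 2). Signed FC is the ratio when ≥ 1, else the negated
  reciprocal, so the magnitude is always ≥ 1 and the sign encodes
  direction.

Degenerate input (zero variance in both groups) yields *p* = 1 when the
means agree — the conservative choice — and *p* = 0 otherwise, which can
only occur on noise-free synthetic data; both cases are logged.

## Set logic

The candidate regulon is `significant(mutant contrast) ∩ significant(WT
contrast)`, narrowed to genes with FC ≥ +2 in WT anoxia-vs-oxia and
FC ≤ −2 in mutant-vs-WT. Genes present in only one contrast's result are
treated as non-significant there and logged rather than dropped, so
cardinality arithmetic (|A| + |B| − |A∩B| = |A∪B|) always holds on
outputs. The subset chain `candidates ⊆ activated ⊆ overlap ⊆ each
parent set` is asserted on every pipeline run.

## Operon grouping and promoter windows

The original operon predictions came from an external method without
published parameters, so grouping here uses the minimal reproducible
stand-in: consecutive same-strand genes with intergenic gap ≤ `max_gap`
(default 200 bp) form one transcriptional unit. Chains are computed over
the full annotation, so a candidate separated from the next candidate
only by a non-detected operon member stays in the same unit. The lead
gene is the transcription-direction-first member.

Box positions are reported relative to the **translation start** (first
base of the start codon), −1 for the base immediately 5' of it, measured
to the 5'-most motif base in transcription orientation. The published
positions (−41 … −459) are printed without a TSS map, so translation
start is the only anchor available to a reimplementation. The window
default is 600 bp — comfortably covering the largest printed offset — and
is **not** clipped at upstream genes by default, since printed positions
like −451 can overlap upstream ORFs; `clip_at_upstream_gene=True` enables
clipping. Windows wrap across the origin on circular replicons; an
offset→coordinate round-trip invariant is property-tested on both
strands.

## Motif model and scanning

The FixK₂ box is modelled as the degenerate consensus `TTGMNNNNNNKCAA`
(TTGA/C-N₆-T/GCAA): eight constrained positions (1–4, 11–14), six free
spacer positions. Scoring is Hamming distance over the constrained
positions only — the source provides a consensus, not base frequencies,
so a PWM would manufacture information. The default tolerance
`max_mm=2` is the smallest value consistent with the printed candidate
motifs, which deviate from the strict consensus by up to 2 constrained
positions (verified by a regression test over all 42 rows).

The model equals its own reverse complement, so a window and its reverse
complement score identically; the scanner reports each position once in
coding-strand coordinates with the strand informational. Ambiguous bases
count as mismatches by default (configurable to tolerate them). One box
per unit is reported (fewest mismatches, then smallest |position|, then
coding strand), mirroring the one-motif-per-unit table layout; the full
hit list is retained in a verbose TSV and BED6 (mismatch count in the
score field). For a divergent head-to-head pair, a shared intergenic box
is assigned to both units, each in its own frame; the two signed
positions sum to −(intergenic length + 14), which is oracle-tested.

Under a uniform base model the expected perfect-hit count in an L-bp
window is (L−13)·(1/4)⁶·(1/2)², with no strand factor because palindromic
hits coincide positionally; the empirical rate on 10⁶ bp is tested within
3σ Poisson. A consequence worth knowing: at `max_mm=2` a 600-bp random
window contains several chance hits, so "unit has a box" is a weak
single-unit statement — exactly why the pipeline reports mismatch counts
and retains verbose hits for curation.

## Pfaffl quantification

ratio = E_t^ΔCq_t / E_r^ΔCq_r with ΔCq = mean Cq(control) − mean
Cq(sample), normalized to *sigA*. Replicate Cq values are averaged
arithmetically before the delta (Cq is already log-scale; geometric
handling would be redundant). Assay efficiencies come from the input
table's `efficiency` column, must lie in (1, 2] fold/cycle, and default
to 2.0 (perfect doubling) when absent — the source does not report its
efficiencies. Zero-noise round trips through the forward simulator are
exact to well below 1e-9.

## Synthetic-data generator

What it emulates: the study's design (3 biological replicates per group;
contrasts ΔnnrR-vs-WT anoxia and WT anoxia-vs-oxia), planted regulon
effects beyond the |FC| ≥ 2 thresholds, boxes planted 0–2 mismatches at
Table-like offsets (20–200 bp upstream), mono- and polycistronic units
(default sizes 1/7/1/3/2, echoing a seven-gene nos-like operon), and one
divergent promoter pair sharing a single box.

Model choices where the source specifies none:

* **Intensity noise** is multiplicative log-normal with coefficient of
  variation `cv` (default 0.15), median-parameterized so group-mean
  ratios are unbiased for the planted FC; per-gene baselines are
  log-normal around `base_mean=500` (spread 0.5 natural-log units).
* **Detection calls** are thresholded on intensity (A < 100 ≤ M < 150 ≤
  P) with a marginal band; the upstream vendor algorithm is out of scope.
* **Background sequence** is i.i.d. uniform A/C/G/T; organism GC content
  is irrelevant to the method's correctness. Gene starts are written as
  ATG and never overwritten when planting (planting refuses to touch any
  annotated gene body).
* **Effect sizes** in the demo scenario are drawn log-uniformly
  (WT induction ~3–32-fold, mutant repression ~2.5–16-fold), inside the
  printed tables' range.

What passing tests do *not* show about real data: no probe-level
artifacts, no correlated noise between replicates or genes, no
normalization residuals, no sequence-composition realism around real
promoters, and no TSS uncertainty. The generator validates the
*arithmetic and logic* of the pipeline, not the biology of any particular
genome.

Problem sizes used by the default test run and the acceptance script —
10,000 genes for null-rate and uniformity checks, 3,000 planted genes for
sensitivity, 300–1,000 windows for scanner-oracle agreement, 60 units for
planted-box recovery — are large enough for the binomial/Poisson bounds
asserted while keeping the whole suite in seconds.

## Determinism

Every stochastic step takes an explicit seed; there is no hidden global
RNG state. The scenario builder fans one seed out to per-stage seeds, and
re-running the pipeline with an identical config is byte-identical
(tested file-by-file, and end-to-end against a committed golden candidate
table from the seed-7 demo).

## Known limitations

* The operon distance rule is deliberately minimal; expression-coherence
  or terminator evidence would change unit boundaries on real genomes.
* Consensus-Hamming scoring treats all constrained positions equally; a
  PWM or energy model would rank imperfect boxes differently.
* The headline set sizes of the original study (1,242 / 1,514 / 298 /
  175) depend on its deposited array data; this package checks their
  arithmetic structurally on constructed sets and does not re-derive them
  from raw data.
* `nnrr-regulon` maps *putative* boxes: with 2 mismatches tolerated, box
  presence alone is weak evidence and is meant to rank candidates for
  experimental validation, not to call direct targets.
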