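# Methods

## Scope and model

`polyfate` studies the erosion of gene redundancy after whole-genome
duplication (WGD) in an allohexaploid grain transcriptome. The target
organism carries three homoeologous subgenomes (A/B/D) from recent
hybridizations plus ancestral WGD paralog blocks shared across grasses.
Because no assembled target genome is assumed, every structural statement
is made *through* a diploid relative used as reference: transcript clusters
are aligned to the reference gene models, and copy number, tandem
duplication, and paralog retention are read off the pattern of those
alignments. All pipeline stages are exercised end-to-end on a synthetic
generator whose truth tables make every downstream estimate scoreable.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
sequencing chemistry.

* **Reference genome.** `n_chromosomes × genes_per_chromosome` genes with
  normally distributed lengths (SD = mean/5, floored), random uniform base
  composition, random strands, and fixed intergenic spacers. A fraction
  `paralog_block_fraction` of genes (rounded to an even count) is arranged
  in collinear blocks of `paralog_block_pairs` pairs whose partners sit in
  the same order on a different chromosome; partner sequences diverge at
  `paralog_divergence` (default 0.12 substitutions/base, a plausible
  nucleotide divergence for paleoduplicates tens of millions of years old).
  A fraction `cnv_prob` of genes gains a tandem copy inserted immediately
  downstream, inheriting the parent sequence with fresh substitutions at
  the homoeoSNP rate — so tandem copies are distinguishable from homoeologs
  only by genomic position, which is exactly how the classifier must
  separate them.
* **Hexaploid copies.** Each gene yields A/B/D transcript copies.
  `homoeolog_snp_rate` (default 1/500) is defined as the *pairwise* SNP
  density between sibling copies; each copy is therefore mutated away from
  the reference at half that rate (substitution-only, no indels, no
  transition bias — only a density is being modelled). Optional `even`
  placement puts SNP columns at regular spacing with three distinct bases,
  guaranteeing divergence inside every alignment window (used to make
  overlap clustering separate siblings deterministically; see limitations).
  Members of paralog pairs are deleted wholesale with `paralog_loss_prob`
  (pre-polyploidy pseudogenization); each copy is further deleted
  independently with `homoeolog_loss_prob`. A per-gene ancestral
  stage-presence profile (five stages, presence probability 0.7, at least
  one stage on, log-normal abundances) is inherited by all copies; with
  `expr_divergence_prob` a retained copy diverges, flipping each stage flag
  with probability 1/n_stages and always flipping at least one — so the
  fraction of copies whose profile differs from the ancestral one is an
  unbiased estimate of the planted probability.
* **Reads.** Unstranded substring reads from expressed copies only, counts
  Poisson with mean `mean_coverage · L / E[read length]` (default 25× —
  the depth regime the analysis assumes), lengths uniform in 400–900 b,
  random strand, opaque shuffled ids. No sequencing-error model, no
  homopolymer artefacts, no quality scores: the clustering stage is tested
  for its overlap logic, not error tolerance.

Everything is driven by `numpy` generators seeded from `(seed, stage
constant)`, so identical config + seed is bit-identical on disk.

**What passing tests do not show about real data:** real 454 reads carry
indels and homopolymer errors, real homoeoSNPs are not uniform, expression
presence is a noisy threshold on abundance, and real reference annotations
contain errors — parameter-recovery results here bound algorithmic, not
biological, error.

## Read clustering

Greedy single-linkage: reads join one cluster iff connected by a chain of
pairwise overlaps of ≥ 40 bases at ≥ 90% identity (both published assembly
parameters), candidates found by shared canonical 16-mers (seed length as
published; the index is sampled every 4th position, the query side scans
every position, so one shared seed suffices) and verified by an ungapped
comparison along the seeded diagonal — adequate because the generator plants
substitutions only. The remaining scoring parameters of the original
proprietary assembler are not reconstructed. Consensus is per-column
majority over a layout anchored on the longest member (ties to the
lexicographically smallest base, making output invariant to read input
order); coverage is total member bases divided by consensus length.
Contaminant screening removes reads whose best local alignment to any
contaminant reference (either strand, Biopython `PairwiseAligner`) reaches
the identity threshold over the required fraction of the read.

**Merged homoeologs.** At wheat-like homoeoSNP density (≤ 1/20 even at the
configured maximum) any overlap between sibling copies has identity ≥ 95%,
so the 90%-identity rule *cannot* separate homoeologs — they co-cluster,
which is precisely the merged-homoeolog phenomenon the coverage flag is for
(`flag_merged_homoeologs`, default multiplier 3.5, reproducing the
published >140-reads-vs-~40-mean operating point). The planted-recovery
test therefore runs clustering at a stricter verification identity (0.98)
with evenly spaced SNPs, where separation is deterministic; the engineered
invariant (≥ 5 SNPs in every 40-base window ⇒ never co-cluster at 90%) is
tested with constructed sequences. Production assemblers separate
haplotypes through consistent-variant phasing, which single-linkage
identity cannot express; this is a deliberate simplification.

## Homology scoring and classification

`score_alignment` merges the HSPs of one query–subject pair on the query
axis before summing: contested columns belong to the higher-bitscore HSP
(ties broken deterministically by coordinates), and a partially masked
HSP's identities are prorated by the retained fraction of its span. This
keeps CALP ≤ 1, which the raw formula does not guarantee on overlapping
HSPs; the equivalence with a per-column brute-force recount is fuzz-tested.
Threshold boundaries are inclusive (CIP ≥ 60, CALP ≥ 0.70, protein identity
≥ 0.50). Best-hit selection per query orders by CIP, then CALP, then
subject id. Copy counts per reference gene cap at 3 (the biological
maximum for a hexaploid); supernumerary matches are reported separately.
CNV calls require a matched tandem partner — annotated via `tandem_parent`
within `tandem_window` (default 1) gene positions on the same chromosome;
for annotations without tandem metadata no CNV is called rather than
guessing from adjacency alone. The bundled `diagonal_align` toy aligner
(k-mer seeded, ungapped, both strands) exists so tests and demos can
produce exact HSPs for simulated data; real data would use an external
aligner's 12-column output, read by `read_m8` (1-based inclusive on disk,
0-based half-open in memory).

## Virtual gene order

`detect_blocks` partitions an anchor list (in target order) into maximal
monotone runs per reference chromosome with at most `gap_limit` (default 5)
missing rank positions between neighbours — the limit is not dictated by
the underlying biology and is configurable. `build_consensus_order` lets
the top-priority reference fix the backbone and inserts each lower
reference's exclusive genes between their nearest already-placed
neighbours, processing insertions in the deciding reference's rank order
(ties by gene id); contradictory neighbours send a gene to the unplaced
list. "Most parsimonious" is not a published objective function; nearest-
neighbour interpolation that never reorders previously placed genes is this
package's reading, and the priority-dominance and no-reorder properties are
asserted directly.

## Duplicate-fate statistics

Two rounding conventions intentionally coexist because they match how such
tables are printed: assay-level percentages round half-up to integers
(43/79 → 54%), while PAV concertation percentages are truncated to one
decimal (2600/6760 = 38.46% → 38.4%). GO bias uses a per-category 2×2
Pearson chi-square of (in-category vs rest) × (expressed set vs genome
background) at α = 0.01 with *no* multiplicity correction — a deliberate
mirror of the source procedure, so its positives should be read as
candidates, not discoveries. The genome background is used as an
independent margin (the expressed set is not subtracted from it).
Differential expression is the plain equal-variance two-group t-test (the
"homoscedastic" phrasing in the source leaves a variance-moderated test
conceivable; the plain test is implemented) with genes outside the
(0.5%, 99.5%) pooled-variance quantiles and constant-zero genes excluded
before testing, and Bonferroni control at 0.05 over the tested genes.
Network WGD enrichment counts each retained duplicate pair as one extra
modern gene: 20 pairs among 170 genes ⇒ 12% enrichment and a 150-gene
pre-WGD network.

## Temporal model

Literature observations (taxon, divergence-time band, percent-shuffled
band, structural/functional mode) are reduced to midpoints and fitted by
weighted least squares to `percent = a + b·ln(t_MY)`, weights
1/half-width², with the percent half-width floored at 1 point so point
estimates get finite weight. The "total" curve pools both modes (the
pooling rule is not published; pooling is exposed as a mode). Predictions
are clamped to [0, 100]; the slope must be positive; inversion
`t = exp((level − a)/b)` flags extrapolation outside the observed midpoint
range. On the bundled compilation the pooled curve predicts ~58% shuffling
at 10 MY — consistent with the half-of-duplicates-within-10-MY reading —
while full (100%) completion is a flagged extrapolation far beyond the
data, so completion-time claims are validated only as interval properties.

## Problem sizes

Tests and the acceptance script use 500–2000 simulated genes for
parameter-recovery statistics, 20 transcripts at 25× for exact cluster
recovery, and 60 genes × 3 copies at 10× for merged-homoeolog recovery —
sizes at which the binomial/Poisson error bounds asserted by the tests are
meaningfully tight while a full run stays fast on one CPU.

## Known limitations

* No indel handling anywhere in the alignment/overlap machinery (matched to
  the substitution-only generator).
* Single-linkage clustering cannot separate haplotypes below ~10%
  divergence at the published identity threshold (see above).
* CNV classification requires tandem annotations; positional adjacency
  alone is not treated as evidence.
* The D-subgenome's much younger divergence is not modelled separately; all
  three subgenomes share one homoeoSNP rate.
* The temporal model fits five + five literature midpoints; its residual
  (~12 points RMS pooled) is descriptive, not inferential.
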