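# Methods

`orphanlc` analyses the life cycle of orphan genes — genes restricted to a
single phylogenetic lineage — in the five-species *Drosophila obscura*
framework: *D. pseudoobscura* (the focal, fully annotated species),
*D. persimilis*, *D. miranda*, *D. lowei*, and *D. affinis*. This note
documents the models, the rules the implementation follows where several
readings were possible, and what the synthetic data generator does and does
not emulate.

## Species tree and Dollo dating

The species tree is fixed:

```
(affinis,(lowei,(miranda,(persimilis,pseudoobscura)1)2)3)4
```

Every internal node lies on the path from *D. pseudoobscura* to the root and
is labelled 1–4 from the shallowest. Age class 0 means
pseudoobscura-specific; age class 5 means old (conserved outside the obscura
group, as established by the homology-based orphan classification).
Configurable topologies are out of scope: the caterpillar shape is what
makes the dating rule exact (see below).

Under Dollo parsimony the intact-ORF character is gained exactly once and
lost arbitrarily often. A gene's origin is the deepest node whose off-path
subtree contains at least one species with an **intact** ortholog.
Disrupted-but-present orthologs deliberately do not extend a gene's age: the
dating evidence is a functional ORF, and a disrupted copy is instead a loss
candidate. Because every internal node is an ancestor of the focal species,
whose copy is intact by study design, the gene was present at every internal
node of its age subtree in every minimal reconstruction; a disrupted
terminal ortholog inside the subtree therefore forces a loss on that
terminal branch, and internal-branch losses are impossible. The test suite
verifies this equivalence against an exhaustive minimal-event search over
all 81 intactness patterns.

Losses are called only on the *lowei*, *miranda*, and *persimilis* branches.
*affinis* losses cannot be polarised without an additional outgroup and are
never called. The default ("weak") support rule requires at least one intact
species on each occupied side of the candidate branch within the age
subtree; a side with no species is vacuous. A strict mode requiring the two
immediate phylogenetic neighbours to be intact is available
(`call_losses(strict=True)`); under it, losses on the branch adjacent to an
empty outer side (e.g. *persimilis* for age-class-1 genes) are never called.

**Observability censoring.** A gene lost on the branch that defines its age
class can no longer be dated to that node, so losses on the branch at tree
position *p* are observable only for age classes > *p*: *persimilis* for
classes 2–4, *miranda* for 3–4, *lowei* for 4. All ordering and trend
statistics (`loss_ordering_by_branch`, `loss_trend_tests`) restrict to these
observable cells; including the structurally-zero cells would fabricate a
trend. Age-class mixing (e.g. a class-3 gene lost in *lowei* is observed as
class 2) is inherent to the design and left uncorrected, as the observed
fractions remain unbiased when loss probabilities do not differ across the
mixed classes.

Complete deletions (no ortholog call and no genome hit below E = 1e-4) are
tabulated separately and excluded from loss fractions: a deletion cannot be
distinguished from a missing annotation. The disabling-vs-deletion share is
|disabling| / (|disabling| + |deletions|).

Loss fractions are lost/(lost+intact) per (branch, age class) cell, with an
optional normalisation dividing by the cell's median CDS length in bp
(units: fraction per bp), correcting for longer CDSs presenting a larger
mutational target. The trend test is Cochran–Armitage with integer scores
over ordered age classes, two-sided.

## ORF-disruption scanning

Premature termination codons (PTCs) are in-frame TAA/TAG/TGA strictly before
the terminal codon after 5′-truncating the sequence to a codon multiple.
Codons containing N are never called stops — an ambiguous base cannot
support a pseudogene call — so a gene whose only putative stop is
N-containing counts as intact. Frameshifts are read off a pairwise alignment
against the reference CDS: each maximal gap run whose length is not
divisible by 3 yields one event at the reference codon containing the gap
start (for insertions, the codon holding the next reference base). Compound
nearby indels count per maximal run; a net-frame interpretation (one event
iff the summed indel length is out of frame) is available behind
`net_frame=True`.

Relative position is `rel_pos = codon_index / total_codons`, where the
denominator includes the terminal stop codon. "First half" means
`rel_pos <= 0.5` (ties conservative). The conservative pseudogene mode
(`first_half`) requires at least one event in the first half of the ORF;
it is always a subset of the plain mode.

The pipeline aligns species CDSs to the reference with Biopython's global
`PairwiseAligner` (match 2, mismatch −1, gap open −6, extend −1) only when
lengths differ; equal-length pairs are compared column-wise. Inside repeat
runs the aligner may slide a gap by a few bases; event *kind* recovery is
exact, positional recovery is exact for PTCs and within a few codons for
frameshifts.

## Evolutionary rates

Raw pairwise alignments are prepared by 5′-truncation to a codon multiple
and masking every internal stop codon to NNN (flags record both actions).
dN/dS is estimated by the Nei–Gojobori (1986) counting method: fractional
synonymous/nonsynonymous sites per codon (each position contributes one
site split by the fraction of its non-stop single-nucleotide changes that
are synonymous), site counts averaged over the two sequences, substitution
counts averaged with equal weights over all minimal mutational pathways
(pathways through intermediate stop codons excluded; if all are excluded,
all pathways are used), and Jukes–Cantor correction
dX = −3/4 ln(1 − 4/3 pX). pX ≥ 3/4 or dS = 0 are flagged, not errors. This
is a deliberate methodological substitution for likelihood codon models:
transparent, dependency-free, and adequate at the shallow divergences
analysed (dS ≈ 0.05–0.25); `evorates.load_external_rates` imports
externally computed ML estimates for parity runs. Site counts always
satisfy S + N = 3 × compared codons.

The neutral reference is a set of intergenic regions length-matched to the
orphan CDS multiset: for each CDS length L a region strictly longer than L
is drawn uniformly, then a uniform subregion of exactly L bp. The output
length multiset equals the input multiset by construction; subregion starts
are uniform on the valid range. Intergenic pairs are consumed pre-aligned
(the generator emits co-linear counterparts); the real-data BLASTN-and-
realign step is out of scope.

pN/pS classifies each SNP one at a time against the reference codon
(multi-SNP codons are classified per SNP independently) and normalises by
NG86 site counts over the CDS: (pN/N)/(pS/S); a raw-count mode is exposed.
SNPs in stop codons are excluded with a warning; zero synonymous SNPs make
the ratio undefined, flagged rather than raised.

## Sequence features

* **GC content**: (G+C)/(A+C+G+T), ambiguity codes excluded from both
  numerator and denominator.
* **CAI**: geometric mean of relative adaptiveness w over informative
  codons, where w = freq / max synonymous freq. Stop codons and the
  single-codon families ATG and TGG are excluded (standard formulation);
  zero-frequency codons are floored at w = 0.01 so the log mean stays
  defined.
* **SSRs**: perfect tandem repeats of primitive 1–6 bp motifs, at least 3
  repeats and 15 bp total (the thresholds used for transcript scanning in
  this study design); among overlapping candidates the longest run wins,
  ties to the leftmost. The original mismatch-tolerant repeat model is
  deliberately not reimplemented — perfect repeats are a reproducible lower
  bound, and only the binary/percentage content feeds the downstream
  contrasts. The scanner is verified against an exhaustive enumeration
  oracle.
* **Windows**: fixed-width, anchored at 0, trailing partial window dropped;
  GC and SSR density (SSR bp / window bp) per window. Width is a parameter
  (100 kb default).
* **Intergenic lengths**: complement of the union of gene intervals,
  0-based half-open; overlapping intervals are unioned and out-of-bounds
  intervals clipped. Complement plus union always equals chromosome length.

## Expression

Size factors are median-of-ratios: s_j = median over genes (nonzero in all
samples) of count_gj / per-gene geometric mean. Note this normalisation is
globally scale-invariant (the reference is computed from the same matrix),
which the tests assert. FPKM is count × 1e9 / (length × library size).

Sex bias is log2((mean normalised male + 0.5)/(mean normalised female +
0.5)); the pseudocount of 0.5 stabilises low counts. Classification uses
|log2FC| > τ with τ = 1.0 by default (appropriate when replication is
minimal), or a Welch t-test on log2 normalised counts with
Benjamini–Hochberg FDR 0.1 when ≥ 2 replicates per sex are available. The
built-in test is intentionally simple; dispersion-based differential
expression frameworks are out of scope and their calls can be imported.

The retention–bias correlation bins male-biased genes by |log2FC|
(equal-count by default, 7 bins; equal-width optional), computes the
conserved fraction per bin, and rank-correlates fraction with bin order.
For ≤ 8 bins the two-sided p-value comes from the full permutation
distribution of Spearman's rho (the t-approximation is unreliable at n = 7);
this keeps the procedure's type-I error at or below the nominal level, which
the suite checks over 1,000 null replicates.

## Synthetic data generator

The generator emulates the downstream products of the study design — never
reads or assemblies. Defaults (one place, `SimulationConfig`):

* **Gains**: {class 0: 150, 1: 120, 2: 90, 3: 70, 4: 60, old: 300} genes.
  Per-branch gain counts are not published in machine-readable form, so the
  magnitudes are free parameters at desk scale.
* **CDS lengths**: log-normal, median ≈ 345 bp for orphans and ≈ 1470 bp
  for old genes (matching the reported medians), σ = 0.5 log units, floored
  at 25 codons.
* **Loss probabilities**: per (branch, age class); default 0.40 / 0.20 /
  0.10 / 0.04 for classes 1–4 and 0.01 for old genes, uniform across
  branches. The spacing was fixed by an a-priori power analysis: with 300
  genes per class, the joint probability that all observable per-branch
  fractions come back strictly ordered exceeds 99%, so ordering-recovery
  experiments at 100 replicates are adequately powered at the 95% bar.
  Deletions replace disabling mutations with probability
  `deletion_frac = 0.24` (mirroring a ~3:1 disabling:deletion mix).
* **Retention couplings**: the per-gene loss probability is multiplied by
  2^−(0.5·max(log2FC,0) + 0.3·(log mean − μ)), so male-biased and highly
  expressed genes are preferentially retained. This one mechanism produces,
  endogenously, the increase of male-biased fraction with age, the
  retention–bias correlation, and the conserved-vs-lost expression contrast.
  Recovery experiments that need clean class-wise loss probabilities switch
  the couplings off.
* **Divergence**: codon substitution by sequential single-nucleotide events
  with synonymous/nonsynonymous class rates proportional to the NG86
  fractional site counts and thinned by dN/dS; stop-creating changes never
  occur, and the start codon and terminal stop are frozen. The event count
  is Poisson with mean ds(S + ω N), which makes the expected per-site rates
  match the nominal targets under the estimator's own site convention. This
  is not a full codon-model rate matrix — only counting estimators consume
  the output. Per-species dS multipliers 1 / 1.5 / 2.5 / 3.5
  (persimilis/miranda/lowei/affinis) on `ds_target = 0.06`. dN/dS 0.4–0.5
  for orphans, 0.15 for old genes (purifying on both, weaker on orphans);
  intergenic counterparts evolve neutrally per-base.
* **Disruptions** enter only through `inject_disruption` (PTC written over
  the target codon, or 1–2 nt indel), keeping the loss truth unambiguous.
  SSR insertions are in-frame perfect dinucleotide repeats (18/24 bp) so
  they never masquerade as frameshifts.
* **Base composition / codon usage**: codon sampling is exponentially
  tilted toward GC-rich and high-w codons with class-specific weights (old
  > orphan; conserved orphans > lost orphans, following the main-text
  direction), against a synthetic reference usage table (geometrically
  decreasing frequencies within each family, GC-richer codons first). The
  table is a labelled stand-in, not any organism's measured usage.
* **Expression**: negative-binomial counts (dispersion 0.05, 2 replicates
  per sex) with expected counts proportional to CDS length times an
  FPKM-like log-normal intensity (orphans ~0.4 log units lower), sex bias
  as a symmetric ±log2FC/2 shift, per-sample library factors log-normal
  (σ = 0.15), and an extra `male_bias_enrichment_conserved = 1.0` log2
  shift applied to a fraction of conserved orphans.
* **Aligned fractions** are drawn so that informative orphan rows
  comfortably clear the empirically calibrated cutoff (old genes:
  1 − 0.3·Beta(1.5, 6); orphans: uniform 0.9–1.0); the cutoff machinery is
  exercised, but the generator does not emulate alignment-length decay with
  divergence.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: assembly and annotation error, alignment
ambiguity beyond single planted indels, transposons, paralogy and gene
conversion, shared polymorphism, tree-correlated substitution patterns
(species sequences evolve independently from the focal sequence),
recombination, and any regulatory mode of gene loss. Parameter-recovery
results certify the statistical machinery, not the biology.

## Numerical and reproducibility choices

* Quantiles are linear-interpolation ("type 7") order statistics; the
  aligned-fraction cutoff comparison is strict (> cutoff), reading "higher
  than" literally, so ties drop.
* Histogram bins on (0, 1] are right-closed; an event at exactly 0.5 falls
  in the lower-middle bin.
* All randomness flows from `numpy.random.default_rng` seeds; the same
  config and seed give byte-identical bundles and pipeline outputs (TSVs
  are written with a fixed `%.6g` float format, the manifest with sorted
  keys and no timestamps).
* Problem sizes for the heavy recovery experiments: 10,000 scanner round
  trips; 200 codon-pair replicates per dN/dS level at 500 codons; 100
  ordering replicates and 1,000 trend-null replicates at 300 genes per
  class; 1,000 null replicates for the retention-correlation level check.
  These sizes put Monte-Carlo error well inside each tolerance while
  keeping a full run in minutes on one core.

## Known limitations

* NG86 with equal-weight pathway averaging is slightly biased toward 1 at
  high divergence; at the dS ≈ 0.2 regime used here the bias is within the
  ±0.05 recovery tolerance.
* The synteny-conservative filter consumes precomputed flank-in-contig
  flags; real synteny assessment from assemblies is out of scope.
* `bias_retention_correlation` requires ≥ 3 non-empty bins and saturates
  (ties at a conserved fraction of 1.0) when retention is near-total, as on
  small synthetic bundles.
* The deletion classifier inherits the study's ambiguity: a gene absent
  from an assembly with no genome hit is "deleted" only insofar as the
  annotation emulation is trusted.
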