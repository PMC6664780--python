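# Methods

This note documents the models, rules and numerical choices behind
loopforge, the parameters that matter, what the synthetic cohorts emulate,
and the known limitations.

## Coordinates and input normalization

All internal coordinates are 0-based half-open on a single assembly. VCF
positions are shifted by −1 on read; BED-family inputs are taken as
0-based unless a `one_based` flag is passed (supplementary loop tables in
the wild are ambiguous on this point, so the reader never guesses).
Loops are intrachromosomal; interchromosomal BEDPE rows are dropped with
a warning. Readers reject malformed records with the offending line
number rather than repairing silently.

SV genotypes are encoded as a signed copy delta summed over homologs:
a homozygous deletion is −2, one extra copy on each homolog is +2, and
"2 extra copies on one homolog plus 1 on the other" is +3. Biallelic
DEL/DUP/INV/INS records use GT allele counts; multiallelic CNVs use
`<CNn>` ALT alleles, each homolog contributing `CN − 1`. Half-called
genotypes count as reference (they fall below the abundance filter
downstream anyway). Insertions have a zero-length reference footprint
plus an inserted-sequence length; in the 1000 Genomes callset these are
almost exclusively mobile-element insertions without CTCF motifs, but the
rewrite engine accepts an optional motif payload for them.

## Reference network construction

* **Anchor merging.** Anchor intervals separated by ≤ 500 bp (the default
  `max_gap`) are merged single-linkage, so one CTCF-binding locus is one
  anchor. Loops whose two ends land in the same merged anchor are
  dropped; loops that become the same anchor pair are clustered with
  their PET counts summed. The merge is idempotent.
* **Support filtering.** A loop survives iff *both* anchors overlap
  (≥ 1 bp) a CTCF+cohesin consensus region. Consensus of n peak sets is
  the set of maximal intervals covered by at least one peak from every
  set.
* **Motifs.** Scanning is plain log2-odds over both strands with a
  uniform 0.25 background and pseudocount 0.8·background (both
  configurable). Only scores > 0 are valid; each consensus peak keeps its
  single best hit; ties break leftmost, then + strand; windows containing
  N score −∞. Anchors whose valid motifs disagree in strand are
  *ambiguous* and their loops are excluded from orientation classes
  rather than resolved. Absolute scores depend on the background and
  pseudocount choices; orderings do not.
* **Orientation.** With unique anchor strands (left sA, right sB):
  (+,−) convergent, (+,+) tandem right, (−,−) tandem left, (−,+)
  divergent. The tandem naming follows the motif arrow: both arrows
  pointing right is tandem right.
* **CCDs.** Per chromosome, the union of loop spans is split into maximal
  runs (0-bp touching counts as connected); each run is one CCD. Borders
  are the outermost consensus-peak motifs inside the outermost anchors.
  An outermost anchor without a consensus-peak motif falls back to the
  strongest motif in its full sequence — kept even when that score is
  ≤ 0, with the CCD flagged low-confidence (requiring score > 0 here
  would leave borders undefined exactly where evidence is weakest).
  Gaps are the chromosome complement of CCDs minus assembly gaps.
* **Annotation.** Promoters are TSS ± 2 kb (protein-coding TSS table);
  a promoter is active iff it overlaps an RNAPII loop anchor or RNAPII
  consensus peak. Anchors are tagged by ≥ 1 bp overlap with enhancers and
  promoters, and tagged `connected_*` when a single RNAPII loop links
  them to a region overlapping the element.

## SV rewriting

Edits are applied to a copy of the network in reference coordinate order
(left → right; DEL < DUP < INV < INS at equal positions), each in the
already-rearranged frame via the composed liftover. Overlapping
qualifying SVs are applied in order and logged as unresolved — nested and
complex events are out of scope. After every edit, zero-degree anchors
are re-linked.

* **Deletion** removes every overlapped anchor with its loops and shifts
  downstream coordinates left. A CCD fully inside the deletion is
  removed; a CCD whose border anchor is hit is fused with its neighbor on
  that side (when there is no neighbor the border is dropped and the CCD
  flagged). Loops spanning the deletion shrink by its length.
* **Duplication** places copies in tandem immediately downstream of the
  duplicated segment (multi-copy CNVs chain, each copy after the
  previous). The original keeps loops to partners upstream of the
  segment; the most downstream copy acquires loops to downstream
  partners; loops internal to the segment are mirrored inside each copy
  with the original frequency; copies are never linked to originals or to
  each other. A duplication overlapping two adjacent CCDs fuses them
  (the junction made at the breakpoint joins their parts).
* **Inversion** mirrors overlapped anchors in place (partially overlapped
  anchors are mirrored on their clipped part) and flips motif strands.
  Each inverted anchor loses all loops and is linked to the nearest
  anchor forming a convergent pair — in either direction, by midpoint
  distance, ties to the lower coordinate; undirected anchors link to the
  nearest anchor unconditionally. If an inverted CCD border now pairs
  convergently with the CCD's opposite border, that border is removed and
  the CCD fuses with its neighbor.
* **Insertion** shifts downstream coordinates right; a motif-bearing
  insertion becomes a new anchor linked by the convergence rule, or is
  flagged isolated when it lands in a CCD gap (insertion-derived anchors
  never seed new CCD borders).
* **Re-linking** gives each orphan exactly one loop of frequency 1
  (configurable) to its nearest convergent-compatible partner, processing
  orphans left to right and skipping any that gained a loop earlier in
  the pass; orphans with no compatible partner are flagged isolated.

Genotype modes: `any_nonreference` applies every SV the sample carries
(one rewritten haplotype is reported); `homozygous_only` restricts to
|delta| ≥ 2; `individualize_haplotypes` builds two networks from phased
per-homolog deltas. Simple duplications apply one copy per event (the
per-haplotype reading of GT); mCNVs use |delta| copies when positive and
deletion semantics when negative.

CCD coordinates follow the literal shift rules during rewriting and may
retain a stale border id after a no-neighbor border drop; rewritten CCDs
carry intervals and borders but not per-loop membership lists, which are
only meaningful in the reference frame.

## 3D modeling

Each structure is a chain of beads minimizing squared deviations from
target distances. The annealer makes single-bead Gaussian moves under
Metropolis acceptance with geometric cooling (factor 0.995 per sweep,
300 sweeps, initial temperature 1) and a step size adapted toward 40%
acceptance; the best-seen configuration is then quenched with L-BFGS.
At zero temperature only downhill moves are accepted, so the
accepted-move energy trace is non-increasing; best-tracking plus quench
guarantees E_final ≤ E_initial on every run. Exactly satisfiable target
sets (metric-consistent, up to 4 beads) reach residuals below 1e-3 from
any seed — the quench converges to machine precision once annealing finds
the basin. All energies depend only on inter-bead geometry and are
rigid-motion invariant.

Distance-law parameters are not determined by the network data and are
package choices, all configurable: α_low = 1 and c = 1 for the
low-resolution power law; δ = 0.5, a = 3, υ = 0.3, γ = 1 for the anchor
law (strictly decreasing in frequency since υ > 0; unconnected pairs
contribute no term, as do zero-frequency heatmap bins); β = 0.6 with
genomic distances expressed in kilobases for the stretch term; k = 3
subanchor beads per loop, spaced evenly in genomic coordinates. Spatial
units are arbitrary; only comparisons between ensembles are meaningful.

The heatmap term E_h needs expected subanchor distances "given only the
physical constraints": these are measured on a short E_s+E_b-only
pre-relaxation, then modulated per pair by the block's normalized
singleton frequency w = f/f_max as d = d_expected · (1 + m(0.5 − w)) with
modulation strength m = 0.5 — frequencies above half the maximum pull
beads closer than the physical expectation, below push apart. The
modulation form is a package choice.

Blocks (connected components of the anchor-loop graph) are modeled
independently — anchor stage, then subloops with anchors fixed — and laid
out left to right with separations following the stretch law on the
genomic gap. Ensembles run n independent seeds (seed, seed+1, …) and are
bit-reproducible. Loci map to the bead whose genomic span contains them
(nearest bead within the modeled span otherwise; outside it is an error),
with the altered ensemble's loci lifted through the SV liftover.
Distance comparisons report per-pair medians, IQRs and a two-sided
Mann–Whitney p; "mean distance to all enhancers" aggregates within each
model before ranking.

## Enrichment, metaplots, threshold

Shuffled SV sets preserve per-chromosome, per-type counts and exact
lengths; placement is uniform, and shuffled elements may overlap each
other and the original footprint (masking of assembly gaps is an option,
off by default). Elements count as hit with ≥ 1 bp overlap, except CCD
borders and motifs, which require full containment by the SV. The test
reports log2(observed/mean(null)); its error bar is the SD of the
per-shuffle log2 fold changes (null counts floored at 0.5 inside the
log); empirical p-values use the add-one convention (k+1)/(n+1), with the
reported one-sided p following the sign of the fold change and stars at
p < 0.001 / 0.01 / 0.1. With the add-one convention the fixed-side
p-value is uniform under the null up to the discreteness of counts.

Metaplots use 200 bins — 100 equal bins over the anchor, 50 over each
500 bp flank. Per sample: mean raw signal per bin, minus the sample's
genome-wide mean, plus the maximum of all samples' means (positivity
shift); group means are ratioed per bin (log2) and averaged over anchors.
Anchors shorter than 100 bp would need sub-bp bins and are skipped.

The proximal/distal threshold is the smallest span above the mode of the
loop-span kernel density at which the density falls to half its maximum.
The density is a fine histogram smoothed with a Gaussian kernel
(Scott's-rule bandwidth by default, configurable), and the crossing is
linearly interpolated; at least 100 spans are required. Smoothing biases
the crossing by O(bandwidth²), well under 1% at the sample sizes used.
Classification is by |TSS − SV center| with ≤ counting as proximal; a
variant can be proximal for one gene and distal for another.

## eQTL scan

Expression (PEER-normalized upstream; this package does not normalize) is
log-transformed with a configurable offset (default 1e-2, protecting
zeros), standardized per gene, and constant genes dropped. The PCA filter
keeps genes whose absolute unit-norm loading on at least one of the first
100 components reaches 0.01 ("contribution" read as absolute loading,
with OR across components; a summed-loading variant is available).
Genotype classes below 1% frequency are masked per SV, SVs left with one
class or on sex chromosomes are excluded, and the genotype enters the
regression as a numeric copy delta (no dominance terms). Genes map to
the CCD containing their TSS; every encoded SV overlapping that CCD is
tested by OLS with a two-sided Wald t-test on the slope (≥ 10 usable
samples). The per-gene permutation shuffles the expression vector once
per permutation jointly for all the gene's SVs, recording the minimum p;
the adjusted p is the rank of the observed minimum among permutation
minima divided by the permutation count, floored at 1/n_perm (an add-one
variant exists). Benjamini–Hochberg across genes yields q-values; genes
pass at q ≤ 0.1 by default, and each reported association can carry a
proximal/distal tag from the threshold above.

## Synthetic cohorts: what they emulate, and what not

The fixture module generates every input with recorded ground truth, so
recovery is always checked against planted structure:

* the loop cohort plants oriented copies of a synthetic, strongly
  informative, non-palindromic 14-bp motif in random background sequence,
  with orientation classes in the exact 65/16/16/2% mix (rounding
  remainder to convergent) and jittered peak sets over the anchors;
* rewrite cases draw chain-with-extras networks (6–14 anchors, ~10%
  motif-less) and 1–3 clean, non-overlapping SVs that either contain
  whole anchors or fall between them;
* the insulated-neighborhood fixture places a promoter and an enhancer in
  adjacent strong loops whose shared insulating anchor pair is removed by
  a deletion, after which both lie on the single surviving outer loop;
* the expression cohort (200 samples by default — large enough for the
  calibration suites, small enough for routine runs) gives each 100-kb
  CCD one biallelic deletion at 30% allele frequency and plants additive
  effects on the log scale, with per-gene realized dispersions recorded
  so planted slopes are comparable after standardization;
* signal cohorts zero the affected samples' signal inside deleted
  anchors.

Passing on these cohorts demonstrates the algorithms' correctness and
the statistics' calibration under their stated assumptions. It does not
demonstrate robustness to properties of real data the generators omit:
humanlike sequence composition and repeat structure, linkage
disequilibrium between SVs, overlapping or imprecisely genotyped calls,
peak-calling noise, or expression covariates beyond what PEER removal
assumes.

## Problem sizes

Routine runs use desk-scale sizes chosen to exercise every code path:
400-loop cohorts, 500 random rewrite fixtures against the brute-force
oracle, 100-model ensembles per condition, 200 calibration replicates at
200 shuffles, 50 null and 10 planted expression cohorts at 200
permutations, and 200k-sample span densities. All are configurable
upward.

## Known limitations

Nested or overlapping SVs are applied sequentially and flagged, not
resolved; duplicated anchors straddling a segment edge follow the literal
shift rules rather than being split; RNAPII (undirected) networks use the
same engine with convergence checks disabled; the 3D engine models one
chromosome's blocks at a time, with no excluded-volume or loop-extrusion
physics beyond the three energy terms; and motif score magnitudes are
background-dependent, so only comparisons and orderings are portable.
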