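# loopforge

Toolkit for studying how structural variants (SVs) reshape the 3D
organization of the human genome at the level of individual chromatin
loops. It builds a CTCF/cohesin-supported loop network from ChIA-PET-style
interaction data, rewrites that network per individual from SV genotypes,
models reference and SV-altered structures with a multiscale
beads-on-a-string simulated-annealing engine, and runs the accompanying
statistics: permutation enrichment/depletion of variants in genomic
elements, aggregate ChIP-seq metaplots at altered anchors, and
domain-scoped SV-eQTL discovery.

Intended users are regulatory genomicists who have loop calls (PET
clusters), ChIP-seq peaks, a genome sequence, an SV callset with
genotypes, and (optionally) an expression matrix, and who want to ask:
*which variants disturb which loops and domains, what do the resulting
structures look like, and which of these disturbances move gene
expression?*

## The model in brief

**Reference network.** Loop anchors closer than 500 bp are merged; loops
are kept when both anchors overlap CTCF+cohesin consensus ChIP-seq peaks.
Each consensus peak receives its single best log-odds CTCF motif hit
(score > 0, both strands), giving every loop an orientation class from
its anchor strand pair: (+,−) convergent, (+,+) tandem right, (−,−)
tandem left, (−,+) divergent. Maximal genomic runs covered by loops form
chromatin contact domains (CCDs), delimited by the outermost CTCF motifs.

**SV rewriting.** Deletions remove intersected anchors with all their
loops (border hits fuse CCDs); duplications copy intersected anchors in
tandem — the original keeps upstream contacts, the copy acquires the
downstream ones, and internal loops are mirrored with no copy↔original
links; inversions mirror anchors, flip motif strands, and re-link each
inverted anchor to its nearest convergent-compatible partner; insertions
shift coordinates and may add a new motif-bearing anchor. Anchors
orphaned by an edit are re-linked by the same convergence rule. A
per-chromosome liftover maps between reference and rearranged frames.

**3D engine.** Bead coordinates minimize squared deviations from target
distances by Metropolis annealing with a deterministic quench:
`d_ij = c f_ij^-alpha` for heatmap bins at low resolution,
`d_ij = delta + a exp(-upsilon (f_ij - gamma))` for loop-connected anchor
pairs, and for subanchor beads the stretching, bending and heatmap terms
`E_s = sum (r_{i,i+1} - N_{i,i+1}^beta)^2`,
`E_b = 1/2 sum (1 - u_{i-1,i} . u_{i,i+1})^2`, `E_h = sum (d_ij - r_ij)^2`.

**Statistics.** Enrichment tests shuffle SVs per chromosome with lengths
and per-type counts preserved, reporting `log2(observed / mean(null))`
with an empirical one-sided p. The eQTL scan regresses standardized
log-expression on signed copy-delta genotypes for every SV in the gene's
CCD, adjusts per gene by the permutation minimum-p rank, and controls
FDR across genes with Benjamini–Hochberg.

## Worked example

Every input can be synthesized (with known ground truth) by the fixture
module — no downloads:

```python
import numpy as np
from loopforge import fixtures as fx
from loopforge.motifs import build_pwm, consensus_peaks
from loopforge.network import build_network, orientation_counts
from loopforge.rewrite import individualize
from loopforge.model3d import EnergyParams, ensemble_for_network, ensemble_distance_test

cohort = fx.make_loop_cohort(seed=0)             # genome + peaks + loops
pwm = build_pwm(cohort.pfm)
cons = consensus_peaks(list(cohort.peak_sets.values()))
net = build_network(cohort.raw_loops, cons, cohort.genome, pwm,
                    chrom_sizes=cohort.chrom_sizes)
print(len(net.loops), orientation_counts(net))

fixt = fx.insulated_neighborhood_fixture()       # promoter | insulator | enhancer
ind = individualize(fixt.network, [fixt.deletion], "S1")
params = EnergyParams()
ref = ensemble_for_network(fixt.network, params, n=100, seed=1)
alt = ensemble_for_network(ind.network, params, n=100, seed=10001)
res = ensemble_distance_test(ref, alt,
                             [("P-E", fixt.promoter, fixt.enhancers[0])],
                             liftover=ind.liftover)[0]
print(f"REF median {res.ref_median:.2f}  DEL median {res.alt_median:.2f}  "
      f"p = {res.p_value:.2e}")
```

This prints

```
400 {'convergent': 264, 'tandem_right': 64, 'tandem_left': 64, 'divergent': 8, 'ambiguous': 0, 'unoriented': 0}
REF median 2.78  DEL median 0.00  p = 5.64e-39
```

The orientation counts are the cohort's planted 66/16/16/2% class mix,
recovered entirely by motif scanning. In the insulated-neighborhood
fixture, deleting the anchor pair that separates the promoter from the
enhancer collapses their median 3D distance (they end up on the same
rewired loop), with an overwhelming rank-sum significance — the
structural signature of enhancer hijacking after boundary loss.

A `loopforge` command-line tool exposes the same stages
(`validate`, `convert`, `motifs`, `network build`, `rewrite`, `patterns`,
`model`, `enrich`, `eqtl`, `fixtures`); run `loopforge --help`.

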