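"""Deterministic synthetic fixtures: toy genomes with planted CTCF motifs,
peak sets, loop cohorts with a fixed orientation mix, SV rosters with known
expected rewrite outcomes, expression cohorts with planted additive SV
effects, and per-bp signal tracks.

Every generator records the ground truth alongside its output so that
downstream checks compare recovered structure against planted structure,
never against recorded outputs. A single integer seed drives each
generator through ``numpy.random.default_rng``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CCD,
    Anchor,
    GenomicInterval,
    Loop,
    MotifHit,
    Network,
    StructuralVariant,
    merge_intervals,
)
from .formats import RawLoop

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Orientation mix of the default loop cohort: convergent, tandem right,
#: tandem left, divergent -- the class proportions the generated reference
#: network is built to exhibit.
ORIENTATION_MIX = (0.65, 0.16, 0.16, 0.02)

_CLASS_STRANDS = {
    "convergent": ("+", "-"),
    "tandem_right": ("+", "+"),
    "tandem_left": ("-", "-"),
    "divergent": ("-", "+"),
}


def ctcf_like_pfm(dominance: int = 85, noise: int = 5) -> np.ndarray:
    """A synthetic, strongly informative, non-palindromic 14-bp count
    matrix standing in for a CTCF-binding profile."""
    consensus = "CCACCAGGTGGCAG"
    pfm = np.full((4, len(consensus)), noise, dtype=float)
    for i, base in enumerate(consensus):
        pfm["ACGT".index(base), i] = dominance
    return pfm


def pfm_consensus(pfm: np.ndarray) -> str:
    return "".join("ACGT"[i] for i in np.asarray(pfm).argmax(axis=0))


def random_sequence(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def plant_motif(seq: list, pos: int, motif: str, strand: str) -> None:
    from .motifs import revcomp

    planted = motif if strand == "+" else revcomp(motif)
    seq[pos:pos + len(motif)] = planted


# ---------------------------------------------------------------------------
# Loop cohort with a fixed orientation mix
# ---------------------------------------------------------------------------

@dataclass
class LoopCohort:
    genome: dict[str, str]
    peak_sets: dict[str, list[GenomicInterval]]
    raw_loops: list[RawLoop]
    pfm: np.ndarray
    truth_motifs: list[tuple[str, int, str]]      # chrom, start, strand
    truth_classes: list[str]                      # per loop
    chrom_sizes: dict[str, int]


def make_loop_cohort(
    seed: int = 0,
    n_loops: int = 400,
    mix: Sequence[float] = ORIENTATION_MIX,
    anchor_len: int = 600,
    intra_gap: int = 2400,
    inter_gap: int = 2000,
    chrom: str = "chrS",
) -> LoopCohort:
    """Loops between freshly planted oriented motifs, orientation classes
    in exact ``mix`` proportions (rounded), order shuffled.

    Four CTCF-like and two cohesin-like peak sets cover the anchors with
    small jitters, so the consensus machinery has real work to do.
    """
    rng = np.random.default_rng(seed)
    pfm = ctcf_like_pfm()
    motif = pfm_consensus(pfm)
    classes = []
    names = list(_CLASS_STRANDS)
    counts = [round(n_loops * p) for p in mix]
    counts[0] += n_loops - sum(counts)  # exact total
    for name, k in zip(names, counts):
        classes.extend([name] * k)
    rng.shuffle(classes)

    unit = 2 * anchor_len + intra_gap + inter_gap
    genome_len = n_loops * unit + inter_gap
    seq = list(random_sequence(rng, genome_len))
    truth_motifs: list[tuple[str, int, str]] = []
    raw_loops: list[RawLoop] = []
    anchors: list[GenomicInterval] = []
    for k, cls in enumerate(classes):
        base = inter_gap + k * unit
        s1, s2 = base, base + anchor_len + intra_gap
        st1, st2 = _CLASS_STRANDS[cls]
        for s, strand in ((s1, st1), (s2, st2)):
            pos = s + (anchor_len - len(motif)) // 2
            plant_motif(seq, pos, motif, strand)
            truth_motifs.append((chrom, pos, strand))
            anchors.append(GenomicInterval(chrom, s, s + anchor_len))
        raw_loops.append(RawLoop(chrom, s1, s1 + anchor_len,
                                 s2, s2 + anchor_len,
                                 int(rng.integers(2, 40)), "CTCF"))
    genome = {chrom: "".join(seq)}

    def jittered(j: int) -> list[GenomicInterval]:
        out = []
        for iv in anchors:
            a = max(0, iv.start - 40 + 10 * j)
            b = min(genome_len, iv.end + 40 - 10 * j)
            out.append(GenomicInterval(chrom, a, b))
        return out

    peak_sets = {f"ctcf_{i}": jittered(i) for i in range(4)}
    peak_sets["smc3"] = jittered(1)
    peak_sets["rad21"] = jittered(2)
    return LoopCohort(genome=genome, peak_sets=peak_sets, raw_loops=raw_loops,
                      pfm=pfm, truth_motifs=truth_motifs,
                      truth_classes=classes,
                      chrom_sizes={chrom: genome_len})


# ---------------------------------------------------------------------------
# Hand-plannable networks
# ---------------------------------------------------------------------------

def network_from_plan(
    chrom: str,
    anchors: Sequence[tuple[int, int, Optional[str]]],
    loops: Sequence[tuple[int, int, int]],
    motif_len: int = 14,
    with_ccds: bool = True,
) -> Network:
    """Build a network from (start, end, strand) anchors and (i, j, freq)
    loops; strand None gives a motif-less (undirected) anchor."""
    net = Network()
    for idx, (s, e, strand) in enumerate(anchors):
        anc = Anchor(id=idx, chrom=chrom, start=s, end=e)
        if strand is not None:
            m_start = (s + e) // 2 - motif_len // 2
            anc.motifs = [MotifHit(
                GenomicInterval(chrom, m_start, m_start + motif_len),
                strand, 5.0)]
        net.add_anchor(anc)
    for i, j, f in loops:
        a, b = (i, j) if i < j else (j, i)
        net.loops.append(Loop(a, b, f, "CTCF"))
    if with_ccds:
        simple_ccds(net)
    return net


def simple_ccds(net: Network) -> None:
    """Set CCDs from maximal runs of loop spans; borders at the outermost
    anchors (no motif-based refinement)."""
    net.ccds = []
    for chrom in net.chroms():
        spans = []
        for lp in net.loops:
            a, b = net.ordered_pair(lp)
            if a.chrom == chrom:
                spans.append((a.start, b.end))
        if not spans:
            continue
        anchors = net.anchors_on(chrom)
        for s, e in merge_intervals(spans, touch=True):
            inside = [a for a in anchors if s <= a.start and a.end <= e]
            net.ccds.append(CCD(chrom=chrom, start=s, end=e,
                                left_anchor=inside[0].id,
                                right_anchor=inside[-1].id))
    net.ccds.sort(key=lambda c: (c.chrom, c.start))


# ---------------------------------------------------------------------------
# Random rewrite cases
# ---------------------------------------------------------------------------

@dataclass
class RewriteCase:
    network: Network
    svs: list[StructuralVariant]
    sample: str


def make_rewrite_case(rng: np.random.Generator, chrom: str = "chrR",
                      max_svs: int = 3) -> RewriteCase:
    """A random chain-with-extras network plus 1..max_svs clean SVs.

    SV intervals either fully contain whole anchors or fall between them,
    and never overlap each other, so every rewrite rule has a well-defined
    expected outcome.
    """
    n_anchors = int(rng.integers(6, 15))
    anchors = []
    pos = 10_000
    for _ in range(n_anchors):
        width = int(rng.integers(300, 900))
        strand = None if rng.random() < 0.10 else ("+" if rng.random() < 0.5 else "-")
        anchors.append((pos, pos + width, strand))
        pos += width + int(rng.integers(4_000, 20_000))
    loops = []
    seen = set()
    for i in range(n_anchors - 1):
        if rng.random() < 0.8:
            loops.append((i, i + 1, int(rng.integers(1, 30))))
            seen.add((i, i + 1))
    for _ in range(int(rng.integers(0, 4))):
        i = int(rng.integers(0, n_anchors - 2))
        j = int(rng.integers(i + 2, min(i + 5, n_anchors)))
        if (i, j) not in seen:
            loops.append((i, j, int(rng.integers(1, 30))))
            seen.add((i, j))
    # make sure nothing starts orphaned
    deg: dict[int, int] = {}
    for i, j, _f in loops:
        deg[i] = deg.get(i, 0) + 1
        deg[j] = deg.get(j, 0) + 1
    for i in range(n_anchors):
        if deg.get(i, 0) == 0:
            j = i + 1 if i + 1 < n_anchors else i - 1
            key = (min(i, j), max(i, j))
            if key not in seen:
                loops.append((key[0], key[1], 1))
                seen.add(key)
                deg[i] = deg.get(i, 0) + 1
                deg[j] = deg.get(j, 0) + 1
    net = network_from_plan(chrom, anchors, loops)

    svs: list[StructuralVariant] = []
    n_svs = int(rng.integers(1, max_svs + 1))
    used: list[tuple[int, int]] = []
    for k in range(n_svs):
        for _attempt in range(30):
            svtype = str(rng.choice(["DEL", "DUP", "INV", "INS"],
                                    p=[0.4, 0.25, 0.2, 0.15]))
            if svtype == "INS":
                gap_i = int(rng.integers(0, n_anchors - 1))
                left_end = anchors[gap_i][1]
                right_start = anchors[gap_i + 1][0]
                if right_start - left_end < 2_000:
                    continue
                p = int(rng.integers(left_end + 500, right_start - 500))
                s, e = p, p
                sv = StructuralVariant(
                    id=f"sv{k}", chrom=chrom, start=p, end=p, svtype="INS",
                    genotypes={"S1": 1}, ins_length=int(rng.integers(200, 2_000)),
                    ins_motif_offset=50 if rng.random() < 0.6 else None,
                    ins_motif_strand="+" if rng.random() < 0.5 else "-",
                )
                span = (p, p + 1)
            else:
                first = int(rng.integers(0, n_anchors))
                last = min(first + int(rng.integers(0, 3)), n_anchors - 1)
                margin_l = int(rng.integers(100, 1_500))
                margin_r = int(rng.integers(100, 1_500))
                s = max(0, anchors[first][0] - margin_l)
                e = anchors[last][1] + margin_r
                if rng.random() < 0.25:  # anchor-missing SV in a gap
                    gap_i = int(rng.integers(0, n_anchors - 1))
                    left_end = anchors[gap_i][1]
                    right_start = anchors[gap_i + 1][0]
                    if right_start - left_end < 3_000:
                        continue
                    s = left_end + 300
                    e = right_start - 300
                delta = {"DEL": -int(rng.integers(1, 3)),
                         "DUP": int(rng.integers(1, 3)),
                         "INV": int(rng.integers(1, 3))}[svtype]
                sv = StructuralVariant(id=f"sv{k}", chrom=chrom, start=s,
                                       end=e, svtype=svtype,
                                       genotypes={"S1": delta})
                span = (s, e)
            if any(s0 < span[1] and span[0] < e0 for s0, e0 in used):
                continue
            used.append(span)
            svs.append(sv)
            break
    svs.sort(key=lambda v: v.start)
    return RewriteCase(network=net, svs=svs, sample="S1")


# ---------------------------------------------------------------------------
# Insulated-neighborhood (promoter/enhancer) fixture
# ---------------------------------------------------------------------------

@dataclass
class InsulatedNeighborhood:
    network: Network
    deletion: StructuralVariant
    promoter: tuple[str, int]
    enhancers: list[tuple[str, int]]
    sample: str = "S1"


def insulated_neighborhood_fixture(chrom: str = "chrT") -> InsulatedNeighborhood:
    """A CCD where one anchor pair insulates a promoter from an enhancer.

    Anchors A(+)...B(-) | C(+)...D(-): strong loops A-B (promoter inside,
    near B) and C-D (enhancer inside, near C), plus a weak outer loop A-D.
    The deletion removes B and C; the survivors' A-D loop then hosts both
    promoter and enhancer, collapsing their 3D separation.
    """
    net = network_from_plan(
        chrom,
        anchors=[(10_000, 10_500, "+"), (30_000, 30_500, "-"),
                 (31_000, 31_500, "+"), (60_000, 60_500, "-")],
        loops=[(0, 1, 20), (2, 3, 20), (0, 3, 2)],
    )
    deletion = StructuralVariant(id="del_insulator", chrom=chrom,
                                 start=29_800, end=31_600, svtype="DEL",
                                 genotypes={"S1": -2})
    return InsulatedNeighborhood(
        network=net,
        deletion=deletion,
        promoter=(chrom, 29_000),
        enhancers=[(chrom, 33_000)],
    )


# ---------------------------------------------------------------------------
# Enrichment fixtures
# ---------------------------------------------------------------------------

def make_random_elements(rng: np.random.Generator, n: int = 200,
                         length: int = 500, chrom: str = "chrE",
                         chrom_len: int = 1_000_000) -> list[GenomicInterval]:
    starts = rng.integers(0, chrom_len - length, n)
    return [GenomicInterval(chrom, int(s), int(s) + length) for s in starts]


def make_sv_set(rng: np.random.Generator, n: int = 40, length: int = 2_000,
                chrom: str = "chrE", chrom_len: int = 1_000_000,
                svtype: str = "DEL") -> list[StructuralVariant]:
    starts = rng.integers(0, chrom_len - length, n)
    return [
        StructuralVariant(id=f"e{k}", chrom=chrom, start=int(s),
                          end=int(s) + length, svtype=svtype,
                          genotypes={"S1": -1 if svtype == "DEL" else 1})
        for k, s in enumerate(starts)
    ]


def depletion_fixture(rng: np.random.Generator, chrom: str = "chrE",
                      chrom_len: int = 1_000_000):
    """Elements confined to an SV desert: every SV avoids [0, 200 kb)."""
    elements = [GenomicInterval(chrom, int(s), int(s) + 500)
                for s in rng.integers(0, 200_000 - 500, 50)]
    svs = [StructuralVariant(id=f"d{k}", chrom=chrom, start=int(s),
                             end=int(s) + 5_000, svtype="DEL",
                             genotypes={"S1": -1})
           for k, s in enumerate(rng.integers(250_000, chrom_len - 5_000, 60))]
    return elements, svs, {chrom: chrom_len}


# ---------------------------------------------------------------------------
# Signal-track fixture for the aggregate metaplot
# ---------------------------------------------------------------------------

@dataclass
class SignalCohort:
    anchors: list[GenomicInterval]
    tracks: dict[str, dict[str, np.ndarray]]
    affected: list[str]
    unaffected: list[str]


def make_signal_cohort(rng: np.random.Generator, n_anchors: int = 4,
                       n_per_group: int = 4, chrom: str = "chrM",
                       anchor_len: int = 1_000, zero_affected: bool = True
                       ) -> SignalCohort:
    """Per-bp tracks with peaks over anchors; affected samples lose all
    signal inside the anchors (the deletion signature)."""
    spacing = anchor_len + 4_000
    chrom_len = n_anchors * spacing + 4_000
    anchors = [GenomicInterval(chrom, 2_000 + i * spacing,
                               2_000 + i * spacing + anchor_len)
               for i in range(n_anchors)]
    affected = [f"aff{i}" for i in range(n_per_group)]
    unaffected = [f"ctl{i}" for i in range(n_per_group)]
    tracks: dict[str, dict[str, np.ndarray]] = {}
    for sample in affected + unaffected:
        sig = 1.0 + 0.2 * rng.random(chrom_len)
        for iv in anchors:
            sig[iv.start:iv.end] += 8.0
        if zero_affected and sample in affected:
            for iv in anchors:
                sig[iv.start:iv.end] = 0.0
        tracks[sample] = {chrom: sig}
    return SignalCohort(anchors=anchors, tracks=tracks,
                        affected=affected, unaffected=unaffected)


# ---------------------------------------------------------------------------
# Expression cohort with planted SV effects
# ---------------------------------------------------------------------------

@dataclass
class EqtlCohort:
    expression: pd.DataFrame          # genes x samples, raw positive scale
    svs: list[StructuralVariant]
    network: Network                  # carries the CCD segmentation
    tss_table: list[tuple[str, str, int, str]]
    samples: list[str]
    truth: dict[str, dict]            # gene -> {planted, sv, slope, log_sd}


def make_eqtl_cohort(
    seed: int = 0,
    n_samples: int = 200,
    n_genes: int = 200,
    n_planted: int = 20,
    slope: float = 1.0,
    noise_sd: float = 1.0,
    genes_per_ccd: int = 4,
    allele_freq: float = 0.3,
    chrom: str = "chrQ",
) -> EqtlCohort:
    """A cohort of diploid samples with one biallelic deletion per CCD and
    additive planted effects on the log-expression scale.

    Expression for gene g: log x = 5 + slope_g * delta + N(0, noise_sd),
    with slope_g = ``slope`` for planted genes and 0 otherwise; delta is
    the signed copy delta of the CCD's deletion (allele frequency
    ``allele_freq``). ``noise_sd = 0`` makes recovery exact.
    """
    if n_planted > n_genes:
        raise ValueError("cannot plant more genes than exist")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:03d}" for i in range(n_samples)]
    n_ccds = (n_genes + genes_per_ccd - 1) // genes_per_ccd
    ccd_len = 100_000
    net = Network()
    svs = []
    for c in range(n_ccds):
        base = c * (ccd_len + 20_000)
        net.ccds.append(CCD(chrom=chrom, start=base, end=base + ccd_len,
                            left_anchor=-1, right_anchor=-1))
        alleles = rng.binomial(1, allele_freq, (n_samples, 2))
        deltas = -(alleles.sum(axis=1))
        genotypes = {s: int(d) for s, d in zip(samples, deltas) if d != 0}
        svs.append(StructuralVariant(
            id=f"ccd{c}_del", chrom=chrom, start=base + 40_000,
            end=base + 43_000, svtype="DEL", genotypes=genotypes,
            haplotypes={s: (int(-a[0]), int(-a[1]))
                        for s, a in zip(samples, alleles)},
        ))
    planted = set(rng.choice(n_genes, size=n_planted, replace=False).tolist())
    tss_table = []
    rows = []
    truth: dict[str, dict] = {}
    gene_names = [f"G{i:04d}" for i in range(n_genes)]
    for gi, gene in enumerate(gene_names):
        ci = gi // genes_per_ccd
        base = ci * (ccd_len + 20_000)
        tss_table.append((gene, chrom, base + 10_000 + (gi % genes_per_ccd) * 5_000, "+"))
        delta = np.array([svs[ci].delta(s) for s in samples], dtype=float)
        beta = slope if gi in planted else 0.0
        y = 5.0 + beta * delta + rng.normal(0.0, noise_sd, n_samples)
        rows.append(np.exp(y))
        truth[gene] = {"planted": gi in planted, "sv": svs[ci].id,
                       "slope": beta, "log_sd": float(np.std(y, ddof=1)) or 1.0}
    expression = pd.DataFrame(rows, index=gene_names, columns=samples)
    return EqtlCohort(expression=expression, svs=svs, network=net,
                      tss_table=tss_table, samples=samples, truth=truth)


# ---------------------------------------------------------------------------
# VCF text for round-trip tests
# ---------------------------------------------------------------------------

def sv_vcf_text(svs: Sequence[StructuralVariant], samples: Sequence[str],
                contigs: dict[str, int]) -> str:
    """Serialize SVs in the 1000 Genomes phase-3 SV dialect (GT-based;
    multiallelic CNVs use <CNn> ALT alleles)."""
    lines = [
        "##fileformat=VCFv4.1",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##ALT=<ID=INV,Description="Inversion">',
        '##ALT=<ID=INS,Description="Insertion">',
        '##ALT=<ID=CN0,Description="CN0">',
    ]
    for name, size in contigs.items():
        lines.append(f"##contig=<ID={name},length={size}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for sv in sorted(svs, key=lambda v: (v.chrom, v.start)):
        pos = sv.start + 1
        if sv.svtype == "INS":
            info = f"SVTYPE=INS;SVLEN={sv.ins_length}"
            alt = "<INS>"
        elif sv.svtype == "mCNV":
            info = f"SVTYPE=CNV;END={sv.end}"
            alt = None  # filled below from observed copy numbers
        else:
            info = f"SVTYPE={sv.svtype};END={sv.end}"
            alt = f"<{sv.svtype}>"
        if sv.svtype == "mCNV":
            cns = sorted({cn for hap in sv.haplotypes.values() for cn in
                          (hap[0] + 1, hap[1] + 1)} - {1})
            alt = ",".join(f"<CN{cn}>" for cn in cns) or "<CN2>"
            index = {cn: k + 1 for k, cn in enumerate(cns)}
            gts = []
            for s in samples:
                h = sv.haplotypes.get(s, (0, 0))
                gts.append(f"{index.get(h[0] + 1, 0)}|{index.get(h[1] + 1, 0)}")
        else:
            gts = []
            for s in samples:
                h = sv.haplotypes.get(s)
                if h is None:
                    d = sv.genotypes.get(s, 0)
                    h = (1 if abs(d) >= 1 else 0, 1 if abs(d) >= 2 else 0)
                gts.append(f"{1 if h[0] else 0}|{1 if h[1] else 0}")
        lines.append(f"{sv.chrom}\t{pos}\t{sv.id}\tN\t{alt}\t.\tPASS\t{info}"
                     f"\tGT\t" + "\t".join(gts))
    return "\n".join(lines) + "\n"
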