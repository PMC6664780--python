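"""Assemble the reference interaction network.

Pipeline: merge nearby anchors of raw PET clusters, keep loops whose
anchors are co-occupied by CTCF and cohesin (consensus peaks), place one
best oriented CTCF motif per consensus peak, classify loop orientation,
segment chromosomes into chromatin contact domains (CCDs) bounded by the
outermost CTCF motifs, and annotate anchors with enhancers/promoters.
"""

from __future__ import annotations

import json
import warnings
from typing import Optional, Sequence

from .core import (
    CCD,
    CTCF,
    Anchor,
    GenomicInterval,
    Loop,
    MotifHit,
    Network,
    merge_intervals,
)
from .formats import RawLoop
from .motifs import Pwm, scan_all_valid, scan_best_motif

PROMOTER_HALFWIDTH = 2000


# ---------------------------------------------------------------------------
# Anchor merging
# ---------------------------------------------------------------------------

def merge_anchors(raw_loops: Sequence[RawLoop], max_gap: int = 500) -> Network:
    """Single-linkage merge of anchors closer than ``max_gap`` bp.

    Loops mapping to the same merged anchor pair are clustered and their
    PET counts summed; self-loops (both ends in one merged anchor) are
    dropped. Idempotent: merging a merged network changes nothing.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    # collect anchor intervals per chromosome
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for lp in raw_loops:
        by_chrom.setdefault(lp.chrom, []).append((lp.start1, lp.end1))
        by_chrom.setdefault(lp.chrom, []).append((lp.start2, lp.end2))

    net = Network()
    merged_index: dict[str, list[tuple[int, int, int]]] = {}  # chrom -> (s, e, id)
    for chrom in sorted(by_chrom):
        ivs = sorted(set(by_chrom[chrom]))
        clusters: list[list[int]] = []
        for s, e in ivs:
            if clusters and s - clusters[-1][1] <= max_gap:
                clusters[-1][1] = max(clusters[-1][1], e)
            else:
                clusters.append([s, e])
        rows = []
        for s, e in clusters:
            aid = net.new_anchor_id()
            net.add_anchor(Anchor(id=aid, chrom=chrom, start=s, end=e))
            rows.append((s, e, aid))
        merged_index[chrom] = rows

    def locate(chrom: str, s: int, e: int) -> int:
        # merged intervals are disjoint; find the one containing [s, e)
        for cs, ce, aid in merged_index[chrom]:
            if cs <= s and e <= ce:
                return aid
        raise RuntimeError("anchor not covered by any merged cluster")

    agg: dict[tuple[int, int], Loop] = {}
    for lp in raw_loops:
        a = locate(lp.chrom, lp.start1, lp.end1)
        b = locate(lp.chrom, lp.start2, lp.end2)
        if a == b:
            continue  # both ends merged into one locus
        key = (a, b) if a < b else (b, a)
        if key in agg:
            agg[key].frequency += lp.frequency
        else:
            agg[key] = Loop(a=key[0], b=key[1], frequency=lp.frequency,
                            mediator=lp.mediator)
    net.loops = [agg[k] for k in sorted(agg)]
    return net


# ---------------------------------------------------------------------------
# Consensus support and motif assignment
# ---------------------------------------------------------------------------

def filter_supported(
    net: Network, consensus: Sequence[GenomicInterval], flag: str = "ctcf_cohesin_consensus"
) -> Network:
    """Keep loops whose BOTH anchors overlap (>= 1 bp) a consensus region."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in consensus:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)

    supported: set[int] = set()
    for aid, anc in net.anchors.items():
        for iv in by_chrom.get(anc.chrom, []):
            if iv.start < anc.end and anc.start < iv.end:
                anc.support.add(flag)
                supported.add(aid)
                break

    out = Network()
    kept_loops = [lp for lp in net.loops if lp.a in supported and lp.b in supported]
    kept_ids = {lp.a for lp in kept_loops} | {lp.b for lp in kept_loops}
    out.anchors = {i: net.anchors[i] for i in kept_ids}
    out.loops = [Loop(lp.a, lp.b, lp.frequency, lp.mediator) for lp in kept_loops]
    out._next_id = net._next_id
    return out


def assign_motifs(
    net: Network,
    consensus: Sequence[GenomicInterval],
    genome: dict[str, str],
    pwm: Pwm,
    min_score: float = 0.0,
) -> None:
    """Place per-consensus-peak best motifs into anchors (in place).

    Each consensus peak overlapping an anchor contributes its single best
    valid motif; an anchor whose motifs disagree in strand is ambiguous.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in consensus:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for anc in net.anchors.values():
        anc.motifs = []
        seq_all = genome.get(anc.chrom)
        if seq_all is None:
            continue
        for peak in by_chrom.get(anc.chrom, []):
            if not (peak.start < anc.end and anc.start < peak.end):
                continue
            hit = scan_best_motif(
                seq_all[peak.start:peak.end], pwm, chrom=anc.chrom,
                offset=peak.start, min_score=min_score,
            )
            if hit is not None and anc.start <= hit.interval.start and hit.interval.end <= anc.end:
                anc.motifs.append(hit)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def classify_orientation(net: Network, loop: Loop) -> str:
    """Orientation class from the strand pair of the two anchors' motifs.

    With unique strands (left anchor sA, right anchor sB):
    (+,-) convergent, (+,+) tandem_right, (-,-) tandem_left, (-,+) divergent.
    Contradictory strands within an anchor -> ambiguous; a missing motif ->
    unoriented.
    """
    a, b = net.ordered_pair(loop)
    if a.ambiguous or b.ambiguous:
        return "ambiguous"
    sa, sb = a.strand, b.strand
    if sa is None or sb is None:
        return "unoriented"
    return {
        ("+", "-"): "convergent",
        ("+", "+"): "tandem_right",
        ("-", "-"): "tandem_left",
        ("-", "+"): "divergent",
    }[(sa, sb)]


def orientation_counts(net: Network) -> dict[str, int]:
    counts = {k: 0 for k in ("convergent", "tandem_right", "tandem_left",
                             "divergent", "ambiguous", "unoriented")}
    for lp in net.loops:
        counts[classify_orientation(net, lp)] += 1
    return counts


# ---------------------------------------------------------------------------
# CCD calling
# ---------------------------------------------------------------------------

def call_ccds(
    net: Network,
    genome: Optional[dict[str, str]] = None,
    pwm: Optional[Pwm] = None,
    chrom_sizes: Optional[dict[str, int]] = None,
    assembly_gaps: Sequence[GenomicInterval] = (),
) -> None:
    """Segment each chromosome into CCDs and gaps (stored on ``net``).

    A CCD is a maximal run of the union of loop spans (0-bp touching counts
    as connected). Its borders are the outermost consensus-peak CTCF motifs
    inside the outermost anchors; an outermost anchor without such a motif
    falls back to the strongest motif in its full sequence (kept regardless
    of the score-0 rule, flagged low-confidence), or to the anchor edge.
    """
    net.ccds = []
    net.gaps = []
    for chrom in net.chroms():
        anchors = net.anchors_on(chrom)
        spans = []
        for lp in net.loops:
            a, b = net.ordered_pair(lp)
            if a.chrom == chrom:
                spans.append((a.start, b.end))
        if not spans:
            if chrom_sizes and chrom in chrom_sizes:
                net.gaps.append(GenomicInterval(chrom, 0, chrom_sizes[chrom]))
            continue
        for run_s, run_e in merge_intervals(spans, touch=True):
            members = [
                i for i, lp in enumerate(net.loops)
                if net.anchors[lp.a].chrom == chrom
                and run_s <= min(net.anchors[lp.a].start, net.anchors[lp.b].start)
                and max(net.anchors[lp.a].end, net.anchors[lp.b].end) <= run_e
            ]
            inside = [a for a in anchors if run_s <= a.start and a.end <= run_e]
            left_anc, right_anc = inside[0], inside[-1]
            lb, lb_low = _border_motif(left_anc, genome, pwm, leftmost=True)
            rb, rb_low = _border_motif(right_anc, genome, pwm, leftmost=False)
            start = lb.interval.start if lb else left_anc.start
            end = rb.interval.end if rb else right_anc.end
            net.ccds.append(
                CCD(chrom=chrom, start=start, end=end,
                    left_anchor=left_anc.id, right_anchor=right_anc.id,
                    left_border=lb, right_border=rb, loop_ids=members,
                    low_confidence=lb_low or rb_low or lb is None or rb is None)
            )
        # gaps: complement of CCD runs, minus assembly gaps
        size = (chrom_sizes or {}).get(chrom)
        runs = [(c.start, c.end) for c in net.ccds if c.chrom == chrom]
        bound = size if size is not None else max(e for _, e in runs)
        gap_ivs = []
        prev = 0
        for s, e in sorted(runs):
            if s > prev:
                gap_ivs.append((prev, s))
            prev = max(prev, e)
        if size is not None and prev < size:
            gap_ivs.append((prev, size))
        asm = [(g.start, g.end) for g in assembly_gaps if g.chrom == chrom]
        for s, e in gap_ivs:
            for ss, ee in _subtract((s, e), asm):
                net.gaps.append(GenomicInterval(chrom, ss, ee))


def _border_motif(anchor: Anchor, genome, pwm, leftmost: bool):
    """Border motif of an outermost anchor; returns (hit, low_confidence)."""
    if anchor.motifs:
        key = (lambda m: m.interval.start) if leftmost else (lambda m: m.interval.end)
        return (min(anchor.motifs, key=key) if leftmost
                else max(anchor.motifs, key=key)), False
    if genome is not None and pwm is not None and anchor.chrom in genome:
        seq = genome[anchor.chrom][anchor.start:anchor.end]
        hit = scan_best_motif(seq, pwm, chrom=anchor.chrom, offset=anchor.start,
                              min_score=float("-inf"))
        if hit is not None:
            return hit, True
    return None, True


def _subtract(interval: tuple[int, int], minus: list[tuple[int, int]]):
    s, e = interval
    pieces = [(s, e)]
    for ms, me in sorted(minus):
        nxt = []
        for ps, pe in pieces:
            if me <= ps or ms >= pe:
                nxt.append((ps, pe))
            else:
                if ps < ms:
                    nxt.append((ps, ms))
                if me < pe:
                    nxt.append((me, pe))
        pieces = nxt
    return [p for p in pieces if p[0] < p[1]]


# ---------------------------------------------------------------------------
# Functional annotation
# ---------------------------------------------------------------------------

def annotate_anchors(
    net: Network,
    enhancers: Sequence[GenomicInterval] = (),
    tss_table: Sequence[tuple[str, str, int, str]] = (),
    rnapii_net: Optional[Network] = None,
    rnapii_peaks: Sequence[GenomicInterval] = (),
    chrom_sizes: Optional[dict[str, int]] = None,
) -> None:
    """Tag anchors with enhancer/promoter overlap and RNAPII connectivity.

    Promoters are TSS +/- 2 kb; a promoter is active iff it overlaps an
    RNAPII loop anchor or an RNAPII consensus peak. A CTCF anchor is tagged
    ``connected_enhancer``/``connected_promoter`` when an RNAPII loop links
    a region overlapping it to a region overlapping the element.
    """
    promoters: list[tuple[GenomicInterval, bool]] = []
    rnapii_anchor_ivs = (
        [a.interval for a in rnapii_net.anchors.values()] if rnapii_net else []
    )
    for gene, chrom, tss, _strand in tss_table:
        size = (chrom_sizes or {}).get(chrom)
        s, e = max(0, tss - PROMOTER_HALFWIDTH), tss + PROMOTER_HALFWIDTH
        if size is not None and tss >= size:
            warnings.warn(f"TSS of {gene} beyond {chrom} end; skipped")
            continue
        if size is not None:
            e = min(e, size)
        iv = GenomicInterval(chrom, s, e)
        active = any(iv.overlaps(x) for x in rnapii_anchor_ivs) or any(
            iv.overlaps(x) for x in rnapii_peaks
        )
        promoters.append((iv, active))

    for anc in net.anchors.values():
        iv = anc.interval
        if any(iv.overlaps(e) for e in enhancers):
            anc.functional.add("enhancer")
        for piv, active in promoters:
            if iv.overlaps(piv):
                anc.functional.add("active_promoter" if active else "inactive_promoter")

    if rnapii_net is not None:
        # one-step reachability through RNAPII loops
        for lp in rnapii_net.loops:
            ra = rnapii_net.anchors[lp.a].interval
            rb = rnapii_net.anchors[lp.b].interval
            for x, y in ((ra, rb), (rb, ra)):
                x_enh = any(x.overlaps(e) for e in enhancers)
                x_prom = any(x.overlaps(p) for p, _ in promoters)
                if not (x_enh or x_prom):
                    continue
                for anc in net.anchors.values():
                    if anc.interval.overlaps(y):
                        if x_enh:
                            anc.functional.add("connected_enhancer")
                        if x_prom:
                            anc.functional.add("connected_promoter")


# ---------------------------------------------------------------------------
# Convenience pipeline + serialization
# ---------------------------------------------------------------------------

def build_network(
    raw_loops: Sequence[RawLoop],
    consensus: Sequence[GenomicInterval],
    genome: dict[str, str],
    pwm: Pwm,
    max_gap: int = 500,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> Network:
    """merge -> filter by consensus support -> motifs -> CCDs."""
    net = merge_anchors(raw_loops, max_gap=max_gap)
    net = filter_supported(net, consensus)
    assign_motifs(net, consensus, genome, pwm)
    call_ccds(net, genome=genome, pwm=pwm, chrom_sizes=chrom_sizes)
    return net


def network_to_json(net: Network) -> str:
    def motif(m):
        if m is None:
            return None
        return {"chrom": m.interval.chrom, "start": m.interval.start,
                "end": m.interval.end, "strand": m.strand, "score": m.score}

    doc = {
        "anchors": [
            {"id": a.id, "chrom": a.chrom, "start": a.start, "end": a.end,
             "motifs": [motif(m) for m in a.motifs],
             "support": sorted(a.support), "functional": sorted(a.functional),
             "flags": sorted(a.flags)}
            for a in sorted(net.anchors.values(), key=lambda x: x.id)
        ],
        "loops": [
            {"a": lp.a, "b": lp.b, "frequency": lp.frequency,
             "mediator": lp.mediator}
            for lp in net.loops
        ],
        "ccds": [
            {"chrom": c.chrom, "start": c.start, "end": c.end,
             "left_anchor": c.left_anchor, "right_anchor": c.right_anchor,
             "left_border": motif(c.left_border),
             "right_border": motif(c.right_border),
             "loop_ids": c.loop_ids, "low_confidence": c.low_confidence}
            for c in net.ccds
        ],
        "gaps": [{"chrom": g.chrom, "start": g.start, "end": g.end}
                 for g in net.gaps],
    }
    return json.dumps(doc, indent=1)


def network_from_json(text: str) -> Network:
    def motif(d):
        if d is None:
            return None
        return MotifHit(GenomicInterval(d["chrom"], d["start"], d["end"]),
                        d["strand"], d["score"])

    doc = json.loads(text)
    net = Network()
    for a in doc["anchors"]:
        net.add_anchor(Anchor(
            id=a["id"], chrom=a["chrom"], start=a["start"], end=a["end"],
            motifs=[motif(m) for m in a["motifs"]],
            support=set(a["support"]), functional=set(a["functional"]),
            flags=set(a["flags"]),
        ))
    net.loops = [Loop(l["a"], l["b"], l["frequency"], l["mediator"])
                 for l in doc["loops"]]
    net.ccds = [CCD(chrom=c["chrom"], start=c["start"], end=c["end"],
                    left_anchor=c["left_anchor"], right_anchor=c["right_anchor"],
                    left_border=motif(c["left_border"]),
                    right_border=motif(c["right_border"]),
                    loop_ids=list(c["loop_ids"]),
                    low_confidence=c["low_confidence"])
                for c in doc["ccds"]]
    net.gaps = [GenomicInterval(g["chrom"], g["start"], g["end"])
                for g in doc["gaps"]]
    return net
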