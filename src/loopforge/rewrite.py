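"""Rewrite a reference interaction network with an individual's SVs.

The rules, per SV type:

* **deletion** -- anchors overlapping the deleted interval are removed with
  all their loops; downstream coordinates shift left. A CCD fully covered
  is removed; a CCD whose border anchor is deleted is fused with the
  neighboring CCD on that side (or keeps a low-confidence edge when there
  is no neighbor).
* **duplication** -- anchors overlapping the duplicated segment are copied
  in tandem immediately downstream. The original keeps its upstream loops;
  the most downstream copy acquires the downstream ones; loops internal to
  the duplicated fragment are mirrored inside each copy, with no links
  between copies and originals. A duplication crossing the boundary
  between two CCDs fuses them.
* **inversion** -- overlapped anchors are mirrored in place with flipped
  motif strands; each loses all loops and is re-linked to the nearest
  anchor with which it forms a convergent pair (nearest anchor
  unconditionally for undirected anchors). An inverted CCD border that now
  converges with the opposite border of its CCD loses border status and
  the CCD fuses with its neighbor.
* **insertion** -- downstream coordinates shift right; a motif-bearing
  insertion becomes a new anchor linked by the convergent rule (flagged
  isolated when it lands in a CCD gap).

After every SV application, zero-degree anchors are re-linked to their
nearest convergent-compatible partner (frequency 1 by default).

Coordinates of the rewritten network live in the rearranged personal
genome; a :class:`Liftover` per chromosome maps back to the reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import CCD, Anchor, GenomicInterval, Loop, MotifHit, Network, StructuralVariant

_TYPE_ORDER = {"DEL": 0, "DUP": 1, "mCNV": 1, "INV": 2, "INS": 3}

_SENTINEL_LEN = 1 << 43


# ---------------------------------------------------------------------------
# Liftover
# ---------------------------------------------------------------------------

@dataclass
class _Seg:
    length: int
    ref_s: int          # reference start (for kind == "map")
    strand: str         # '+' or '-'
    kind: str           # "map" or "ins"
    primary: bool       # primary copy, used for forward lookup


class Liftover:
    """Monotone-by-segment coordinate map reference <-> rearranged.

    Segments are kept in rearranged (alt) order; alt offsets are derived
    from cumulative lengths. Deleted reference positions forward-map to
    the breakpoint (with ``exact=True`` they map to None); inserted alt
    positions backward-map to None.
    """

    def __init__(self, chrom_len: int = _SENTINEL_LEN) -> None:
        self.segs: list[_Seg] = [_Seg(chrom_len, 0, "+", "map", True)]

    # -- queries -----------------------------------------------------------
    def _alt_starts(self) -> list[int]:
        starts, acc = [], 0
        for seg in self.segs:
            starts.append(acc)
            acc += seg.length
        return starts

    def forward(self, ref_pos: int, exact: bool = False) -> Optional[int]:
        """Map a reference position to the rearranged frame."""
        best_break = 0
        for alt_s, seg in zip(self._alt_starts(), self.segs):
            if seg.kind != "map" or not seg.primary:
                continue
            if seg.ref_s <= ref_pos < seg.ref_s + seg.length:
                if seg.strand == "+":
                    return alt_s + (ref_pos - seg.ref_s)
                return alt_s + (seg.ref_s + seg.length - 1 - ref_pos)
            if seg.ref_s + seg.length <= ref_pos:
                best_break = alt_s + seg.length
        return None if exact else best_break

    def backward(self, alt_pos: int) -> Optional[int]:
        """Map a rearranged position back to the reference (None if inserted)."""
        for alt_s, seg in zip(self._alt_starts(), self.segs):
            if alt_s <= alt_pos < alt_s + seg.length:
                if seg.kind == "ins":
                    return None
                if seg.strand == "+":
                    return seg.ref_s + (alt_pos - alt_s)
                return seg.ref_s + seg.length - 1 - (alt_pos - alt_s)
        return None

    # -- edits (alt-frame intervals) ---------------------------------------
    def _split_at(self, alt_pos: int) -> None:
        acc = 0
        for i, seg in enumerate(self.segs):
            if acc < alt_pos < acc + seg.length:
                off = alt_pos - acc
                left = _Seg(off, seg.ref_s, seg.strand, seg.kind, seg.primary)
                if seg.kind == "map" and seg.strand == "-":
                    right_ref = seg.ref_s
                    left.ref_s = seg.ref_s + (seg.length - off)
                    right = _Seg(seg.length - off, right_ref, seg.strand,
                                 seg.kind, seg.primary)
                else:
                    right = _Seg(seg.length - off, seg.ref_s + (off if seg.kind == "map" else 0),
                                 seg.strand, seg.kind, seg.primary)
                self.segs[i:i + 1] = [left, right]
                return
            acc += seg.length

    def _range_indices(self, alt_s: int, alt_e: int) -> tuple[int, int]:
        self._split_at(alt_s)
        self._split_at(alt_e)
        starts = self._alt_starts()
        i0 = next(i for i, s in enumerate(starts) if s == alt_s)
        i1 = next((i for i, s in enumerate(starts) if s == alt_e), len(self.segs))
        return i0, i1

    def delete(self, alt_s: int, alt_e: int) -> None:
        i0, i1 = self._range_indices(alt_s, alt_e)
        del self.segs[i0:i1]

    def insert(self, alt_pos: int, length: int) -> None:
        self._split_at(alt_pos)
        acc = 0
        for i, seg in enumerate(self.segs):
            if acc == alt_pos:
                self.segs.insert(i, _Seg(length, 0, "+", "ins", False))
                return
            acc += seg.length
        self.segs.append(_Seg(length, 0, "+", "ins", False))

    def duplicate(self, alt_s: int, alt_e: int, copies: int) -> None:
        i0, i1 = self._range_indices(alt_s, alt_e)
        block = [
            _Seg(s.length, s.ref_s, s.strand, s.kind, False)
            for s in self.segs[i0:i1]
        ]
        self.segs[i1:i1] = [
            _Seg(s.length, s.ref_s, s.strand, s.kind, False)
            for _ in range(copies) for s in block
        ]

    def invert(self, alt_s: int, alt_e: int) -> None:
        i0, i1 = self._range_indices(alt_s, alt_e)
        flipped = []
        for seg in reversed(self.segs[i0:i1]):
            strand = "-" if seg.strand == "+" else "+"
            flipped.append(_Seg(seg.length, seg.ref_s, strand, seg.kind, seg.primary))
        self.segs[i0:i1] = flipped


# ---------------------------------------------------------------------------
# Edit records / result container
# ---------------------------------------------------------------------------

@dataclass
class EditRecord:
    sv_id: str
    svtype: str
    chrom: str
    cur_start: int
    cur_end: int
    anchors_removed: int = 0
    anchors_added: int = 0
    loops_removed: int = 0
    loops_added: int = 0
    ccds_fused: int = 0
    notes: list[str] = field(default_factory=list)


@dataclass
class IndividualizedNetwork:
    network: Network
    liftover: dict[str, Liftover]
    applied: list[EditRecord]
    sample: Optional[str] = None
    allele_mode: str = "any_nonreference"


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _shift_pos(pos: int, at: int, by: int) -> int:
    return pos + by if pos >= at else pos

def _shift_downstream(net: Network, chrom: str, at: int, by: int) -> None:
    for anc in net.anchors.values():
        if anc.chrom != chrom or anc.end <= at:
            continue
        anc.start = _shift_pos(anc.start, at, by)
        anc.end = anc.end + by if anc.start >= at or anc.end > at else anc.end
        anc.motifs = [
            MotifHit(GenomicInterval(m.interval.chrom,
                                     _shift_pos(m.interval.start, at, by),
                                     _shift_pos(m.interval.end - 1, at, by) + 1),
                     m.strand, m.score)
            for m in anc.motifs
        ]
    for ccd in net.ccds:
        if ccd.chrom != chrom:
            continue
        new_end = _shift_pos(ccd.end, at, by) if ccd.end > at else ccd.end
        new_start = _shift_pos(ccd.start, at, by)
        ccd.start, ccd.end = new_start, max(new_end, new_start + 1)
        for attr in ("left_border", "right_border"):
            m = getattr(ccd, attr)
            if m is not None and m.interval.start >= at:
                setattr(ccd, attr, MotifHit(
                    GenomicInterval(m.interval.chrom, m.interval.start + by,
                                    m.interval.end + by),
                    m.strand, m.score))


def _hit_anchors(net: Network, chrom: str, s: int, e: int) -> list[Anchor]:
    out = [a for a in net.anchors.values()
           if a.chrom == chrom and a.start < e and s < a.end]
    out.sort(key=lambda a: (a.start, a.end, a.id))
    return out


def _compatible(self_strand: Optional[str], self_mid: float,
                partner_strand: Optional[str], partner_mid: float) -> bool:
    """Can (self, partner) form a convergent pair? Undirected self: always."""
    if self_strand is None:
        return True
    if partner_strand is None:
        return False
    if partner_mid < self_mid:
        return partner_strand == "+" and self_strand == "-"
    if partner_mid > self_mid:
        return self_strand == "+" and partner_strand == "-"
    return False


def _nearest_partner(net: Network, anchor: Anchor) -> Optional[Anchor]:
    """Nearest compatible anchor by midpoint distance; ties -> lower coord."""
    mid = anchor.midpoint
    strand = None if anchor.ambiguous else anchor.strand
    best = None
    for other in net.anchors_on(anchor.chrom):
        if other.id == anchor.id:
            continue
        o_strand = None if other.ambiguous else other.strand
        if not _compatible(strand, mid, o_strand, other.midpoint):
            continue
        key = (abs(other.midpoint - mid), other.midpoint, other.id)
        if best is None or key < best[0]:
            best = (key, other)
    return None if best is None else best[1]


def _add_loop(net: Network, a: int, b: int, frequency: int, mediator: str) -> bool:
    if a == b:
        return False
    key = (a, b) if a < b else (b, a)
    for lp in net.loops:
        if lp.key() == key:
            return False
    net.loops.append(Loop(key[0], key[1], frequency, mediator))
    return True


def _remove_ccd_border(net: Network, ccd: CCD, side: str, rec: EditRecord) -> None:
    """Drop one border of ``ccd``: fuse with the neighbor on that side."""
    same = sorted((c for c in net.ccds if c.chrom == ccd.chrom),
                  key=lambda c: c.start)
    idx = same.index(ccd)
    neighbor = same[idx - 1] if side == "left" and idx > 0 else (
        same[idx + 1] if side == "right" and idx + 1 < len(same) else None)
    if neighbor is None:
        if side == "left":
            ccd.left_border = None
        else:
            ccd.right_border = None
        ccd.low_confidence = True
        rec.notes.append(f"CCD border ({side}) dropped, no neighbor to fuse")
        return
    left, right = (neighbor, ccd) if side == "left" else (ccd, neighbor)
    fused = CCD(chrom=ccd.chrom, start=left.start, end=right.end,
                left_anchor=left.left_anchor, right_anchor=right.right_anchor,
                left_border=left.left_border, right_border=right.right_border,
                loop_ids=[], low_confidence=left.low_confidence or right.low_confidence)
    net.ccds.remove(ccd)
    net.ccds.remove(neighbor)
    net.ccds.append(fused)
    net.ccds.sort(key=lambda c: (c.chrom, c.start))
    rec.ccds_fused += 1


def _fuse_adjacent(net: Network, a: CCD, b: CCD, rec: EditRecord) -> None:
    left, right = (a, b) if a.start <= b.start else (b, a)
    fused = CCD(chrom=left.chrom, start=left.start, end=right.end,
                left_anchor=left.left_anchor, right_anchor=right.right_anchor,
                left_border=left.left_border, right_border=right.right_border,
                loop_ids=[], low_confidence=left.low_confidence or right.low_confidence)
    net.ccds.remove(a)
    net.ccds.remove(b)
    net.ccds.append(fused)
    net.ccds.sort(key=lambda c: (c.chrom, c.start))
    rec.ccds_fused += 1


# ---------------------------------------------------------------------------
# SV applications (current-frame coordinates)
# ---------------------------------------------------------------------------

def apply_deletion(net: Network, chrom: str, start: int, end: int,
                   liftover: Optional[Liftover] = None,
                   rec: Optional[EditRecord] = None,
                   relink_frequency: int = 1) -> EditRecord:
    rec = rec or EditRecord("", "DEL", chrom, start, end)
    if chrom not in {a.chrom for a in net.anchors.values()}:
        warnings.warn(f"deletion on {chrom}: chromosome absent from network")
        return rec
    length = end - start
    hit = _hit_anchors(net, chrom, start, end)
    hit_ids = {a.id for a in hit}

    # CCD bookkeeping before anchors disappear
    for ccd in [c for c in net.ccds if c.chrom == chrom]:
        if start <= ccd.start and ccd.end <= end:
            net.ccds.remove(ccd)
            rec.notes.append("CCD fully covered by deletion, removed")
    for side, attr in (("left", "left_anchor"), ("right", "right_anchor")):
        for ccd in [c for c in net.ccds
                    if c.chrom == chrom and getattr(c, attr) in hit_ids]:
            _remove_ccd_border(net, ccd, side, rec)

    # drop anchors + incident loops
    before_loops = len(net.loops)
    net.loops = [lp for lp in net.loops
                 if lp.a not in hit_ids and lp.b not in hit_ids]
    rec.loops_removed += before_loops - len(net.loops)
    for aid in hit_ids:
        del net.anchors[aid]
    rec.anchors_removed += len(hit_ids)

    _shift_downstream(net, chrom, end, -length)
    if liftover is not None:
        liftover.delete(start, end)
    added = relink_orphans(net, chrom=chrom, frequency=relink_frequency)
    rec.loops_added += added
    return rec


def apply_duplication(net: Network, chrom: str, start: int, end: int,
                      copies: int = 1,
                      liftover: Optional[Liftover] = None,
                      rec: Optional[EditRecord] = None,
                      relink_frequency: int = 1) -> EditRecord:
    if copies <= 0:
        raise ValueError("duplication requires copies >= 1")
    rec = rec or EditRecord("", "DUP", chrom, start, end)
    length = end - start
    hit = _hit_anchors(net, chrom, start, end)
    hit_ids = {a.id for a in hit}

    # CCD fusion when the duplication crosses a boundary between two CCDs
    same = sorted((c for c in net.ccds if c.chrom == chrom), key=lambda c: c.start)
    for left, right in zip(same, same[1:]):
        if start < left.end and end > right.start:
            _fuse_adjacent(net, left, right, rec)
            break

    _shift_downstream(net, chrom, end, copies * length)

    # partition loops of hit anchors
    upstream_kept: list[Loop] = []
    internal: list[Loop] = []
    to_move: list[Loop] = []   # downstream loops -> acquired by last copy
    for lp in list(net.loops):
        a_hit, b_hit = lp.a in hit_ids, lp.b in hit_ids
        if a_hit and b_hit:
            internal.append(lp)
        elif a_hit or b_hit:
            hit_id = lp.a if a_hit else lp.b
            partner = net.anchors[lp.other(hit_id)]
            if partner.midpoint < start:
                upstream_kept.append(lp)
            else:
                to_move.append(lp)

    copy_ids: dict[tuple[int, int], int] = {}  # (orig id, copy index) -> new id
    for c in range(1, copies + 1):
        offset = (end - start) + (c - 1) * length
        for a in hit:
            new = Anchor(
                id=net.new_anchor_id(), chrom=chrom,
                start=a.start + offset, end=a.end + offset,
                motifs=[MotifHit(GenomicInterval(chrom,
                                                 m.interval.start + offset,
                                                 m.interval.end + offset),
                                 m.strand, m.score) for m in a.motifs],
                support=set(a.support), functional=set(a.functional),
                flags=set(a.flags) | {"duplicate"},
            )
            net.add_anchor(new)
            copy_ids[(a.id, c)] = new.id
            rec.anchors_added += 1

    # mirrored internal loops inside each copy; no cross links
    for c in range(1, copies + 1):
        for lp in internal:
            if _add_loop(net, copy_ids[(lp.a, c)], copy_ids[(lp.b, c)],
                         lp.frequency, lp.mediator):
                rec.loops_added += 1
    # downstream loops move from the original to the last copy
    for lp in to_move:
        hit_id = lp.a if lp.a in hit_ids else lp.b
        new_id = copy_ids[(hit_id, copies)]
        if lp.a == hit_id:
            lp.a = new_id
        else:
            lp.b = new_id
        if lp.a > lp.b:
            lp.a, lp.b = lp.b, lp.a

    if liftover is not None:
        liftover.duplicate(start, end, copies)
    added = relink_orphans(net, chrom=chrom, frequency=relink_frequency)
    rec.loops_added += added
    return rec


def apply_inversion(net: Network, chrom: str, start: int, end: int,
                    liftover: Optional[Liftover] = None,
                    rec: Optional[EditRecord] = None,
                    relink_frequency: int = 1) -> EditRecord:
    rec = rec or EditRecord("", "INV", chrom, start, end)
    hit = _hit_anchors(net, chrom, start, end)

    def mirror(pos: int) -> int:
        return start + (end - pos)

    for a in hit:
        s, e = max(a.start, start), min(a.end, end)
        a.start, a.end = mirror(e), mirror(s)
        a.motifs = [
            MotifHit(GenomicInterval(chrom,
                                     mirror(min(m.interval.end, end)),
                                     mirror(max(m.interval.start, start))),
                     "-" if m.strand == "+" else "+", m.score)
            for m in a.motifs
        ]
    if not any(a.motifs for a in hit):
        rec.notes.append("no motif-bearing anchor inverted; coordinate mirror only")

    hit_ids = {a.id for a in hit}
    before = len(net.loops)
    net.loops = [lp for lp in net.loops
                 if lp.a not in hit_ids and lp.b not in hit_ids]
    rec.loops_removed += before - len(net.loops)

    for a in sorted(hit, key=lambda x: (x.start, x.end, x.id)):
        partner = _nearest_partner(net, a)
        if partner is None:
            a.flags.add("isolated")
            rec.notes.append(f"inverted anchor {a.id}: no compatible partner")
            continue
        if _add_loop(net, a.id, partner.id, relink_frequency,
                     "CTCF" if a.motifs else "RNAPII"):
            rec.loops_added += 1
        # border rule: inverted border converging with the opposite border
        for ccd in [c for c in net.ccds if c.chrom == chrom]:
            if ccd.left_anchor == a.id and ccd.right_anchor == partner.id:
                _remove_ccd_border(net, ccd, "left", rec)
            elif ccd.right_anchor == a.id and ccd.left_anchor == partner.id:
                _remove_ccd_border(net, ccd, "right", rec)

    if liftover is not None:
        liftover.invert(start, end)
    added = relink_orphans(net, chrom=chrom, frequency=relink_frequency)
    rec.loops_added += added
    return rec


def apply_insertion(net: Network, chrom: str, pos: int, length: int,
                    motif_offset: Optional[int] = None,
                    motif_strand: Optional[str] = None,
                    motif_length: int = 19,
                    liftover: Optional[Liftover] = None,
                    rec: Optional[EditRecord] = None,
                    relink_frequency: int = 1) -> EditRecord:
    rec = rec or EditRecord("", "INS", chrom, pos, pos)
    _shift_downstream(net, chrom, pos, length)
    if motif_offset is not None:
        m_start = pos + motif_offset
        anchor = Anchor(id=net.new_anchor_id(), chrom=chrom,
                        start=m_start, end=m_start + motif_length,
                        flags={"inserted"})
        if motif_strand is not None:
            anchor.motifs = [MotifHit(
                GenomicInterval(chrom, m_start, m_start + motif_length),
                motif_strand, 1.0)]
        net.add_anchor(anchor)
        rec.anchors_added += 1
        in_ccd = any(c.chrom == chrom and c.start <= m_start < c.end
                     for c in net.ccds)
        if not in_ccd and net.ccds:
            anchor.flags.add("isolated")
            rec.notes.append("inserted motif in a gap; left isolated")
        else:
            partner = _nearest_partner(net, anchor)
            if partner is None:
                anchor.flags.add("isolated")
                rec.notes.append("inserted motif: no compatible partner")
            elif _add_loop(net, anchor.id, partner.id, relink_frequency,
                           "CTCF" if anchor.motifs else "RNAPII"):
                rec.loops_added += 1
    if liftover is not None:
        liftover.insert(pos, length)
    added = relink_orphans(net, chrom=chrom, frequency=relink_frequency)
    rec.loops_added += added
    return rec


def relink_orphans(net: Network, chrom: Optional[str] = None,
                   frequency: int = 1) -> int:
    """Link every zero-degree, non-isolated anchor to its nearest
    convergent-compatible partner; returns the number of loops added."""
    degree: dict[int, int] = {aid: 0 for aid in net.anchors}
    for lp in net.loops:
        degree[lp.a] += 1
        degree[lp.b] += 1
    orphans = [a for a in net.anchors.values()
               if degree[a.id] == 0 and "isolated" not in a.flags
               and (chrom is None or a.chrom == chrom)]
    orphans.sort(key=lambda a: (a.chrom, a.start, a.end, a.id))
    added = 0
    for a in orphans:
        if degree[a.id] > 0:  # fixed by an earlier relink this pass
            continue
        partner = _nearest_partner(net, a)
        if partner is None:
            a.flags.add("isolated")
            warnings.warn(f"orphan anchor {a.id} on {a.chrom}: no compatible partner")
            continue
        if _add_loop(net, a.id, partner.id, frequency,
                     "CTCF" if a.motifs else "RNAPII"):
            degree[a.id] += 1
            degree[partner.id] += 1
            added += 1
    return added


# ---------------------------------------------------------------------------
# Individualization
# ---------------------------------------------------------------------------

def _qualifying(svs: Sequence[StructuralVariant], sample: str,
                allele_mode: str) -> list[StructuralVariant]:
    if allele_mode == "any_nonreference":
        return [sv for sv in svs if sv.delta(sample) != 0]
    if allele_mode == "homozygous_only":
        return [sv for sv in svs if sv.is_homozygous(sample)]
    raise ValueError(f"unknown allele_mode {allele_mode!r}")


def individualize(
    net: Network,
    svs: Sequence[StructuralVariant],
    sample: str,
    allele_mode: str = "any_nonreference",
    chrom_sizes: Optional[dict[str, int]] = None,
    relink_frequency: int = 1,
) -> IndividualizedNetwork:
    """Apply one sample's qualifying SVs to a copy of the network.

    SVs are applied in reference coordinate order (left to right;
    DEL < DUP < INV < INS at equal positions), composing the liftover so
    each later SV is placed in the already-rearranged frame.

    ``per_haplotype`` mode is available through
    :func:`individualize_haplotypes` when phased genotypes are present.
    """
    if allele_mode == "per_haplotype":
        raise ValueError("use individualize_haplotypes() for per_haplotype mode")
    qualifying = _qualifying(svs, sample, allele_mode)
    return _apply_all(net, qualifying, sample, allele_mode, chrom_sizes,
                      relink_frequency)


def individualize_haplotypes(
    net: Network,
    svs: Sequence[StructuralVariant],
    sample: str,
    chrom_sizes: Optional[dict[str, int]] = None,
    relink_frequency: int = 1,
) -> tuple[IndividualizedNetwork, IndividualizedNetwork]:
    """One rewritten network per haplotype, from phased genotypes."""
    for sv in svs:
        if sv.genotypes.get(sample) and sample not in sv.haplotypes:
            raise ValueError(f"{sv.id}: no phased genotype for {sample}")
    out = []
    for hap in (0, 1):
        chosen = [sv for sv in svs
                  if sv.haplotypes.get(sample, (0, 0))[hap] != 0]
        out.append(_apply_all(net, chosen, sample, f"haplotype{hap + 1}",
                              chrom_sizes, relink_frequency))
    return out[0], out[1]


def _apply_all(net, qualifying, sample, allele_mode, chrom_sizes,
               relink_frequency) -> IndividualizedNetwork:
    work = net.copy()
    lifts: dict[str, Liftover] = {}
    records: list[EditRecord] = []
    ordered = sorted(
        qualifying, key=lambda sv: (sv.chrom, sv.start, _TYPE_ORDER[sv.svtype], sv.id)
    )
    applied_spans: dict[str, list[tuple[int, int]]] = {}
    for sv in ordered:
        lift = lifts.setdefault(
            sv.chrom, Liftover((chrom_sizes or {}).get(sv.chrom, _SENTINEL_LEN))
        )
        cur_s = lift.forward(sv.start)
        cur_e = lift.forward(sv.end) if sv.end > sv.start else cur_s
        rec = EditRecord(sv.id, sv.svtype, sv.chrom, cur_s, cur_e)
        for s0, e0 in applied_spans.get(sv.chrom, []):
            if sv.start < e0 and s0 < sv.end:
                rec.notes.append("overlaps a previously applied SV; unresolved")
        delta = sv.delta(sample) if sample is not None else 1
        if sv.svtype == "DEL" or (sv.svtype == "mCNV" and delta < 0):
            if cur_e > cur_s:
                apply_deletion(work, sv.chrom, cur_s, cur_e, lift, rec,
                               relink_frequency)
            else:
                rec.notes.append("region already removed; skipped")
        elif sv.svtype == "DUP" or (sv.svtype == "mCNV" and delta > 0):
            copies = abs(delta) if sv.svtype == "mCNV" else 1
            if cur_e > cur_s:
                apply_duplication(work, sv.chrom, cur_s, cur_e, copies, lift,
                                  rec, relink_frequency)
            else:
                rec.notes.append("region already removed; skipped")
        elif sv.svtype == "INV":
            if cur_e > cur_s:
                apply_inversion(work, sv.chrom, cur_s, cur_e, lift, rec,
                                relink_frequency)
            else:
                rec.notes.append("region already removed; skipped")
        elif sv.svtype == "INS":
            apply_insertion(work, sv.chrom, cur_s, sv.ins_length,
                            motif_offset=sv.ins_motif_offset,
                            motif_strand=sv.ins_motif_strand,
                            liftover=lift, rec=rec,
                            relink_frequency=relink_frequency)
        else:  # mCNV with delta == 0 qualifies in no mode, defensive
            rec.notes.append("copy-neutral; skipped")
        records.append(rec)
        applied_spans.setdefault(sv.chrom, []).append((sv.start, sv.end))
    return IndividualizedNetwork(network=work, liftover=lifts,
                                 applied=records, sample=sample,
                                 allele_mode=allele_mode)


# ---------------------------------------------------------------------------
# SV patterns per CCD
# ---------------------------------------------------------------------------

@dataclass
class PatternSummary:
    patterns: dict[tuple[int, frozenset], set]  # (ccd index, sv ids) -> samples
    n_unique: int
    fraction_single_type: float
    n_multi: int
    fraction_multi_same_type: float
    shared_all_groups: int


def extract_patterns(
    net: Network,
    svs: Sequence[StructuralVariant],
    samples: Sequence[str],
    populations: Optional[dict[str, str]] = None,
) -> PatternSummary:
    """Unique per-CCD sets of anchor-intersecting SVs across samples.

    Two patterns are identical iff their anchor-intersecting SV id sets are
    equal; patterns never span CCDs.
    """
    ccd_anchors: list[list[Anchor]] = []
    for ccd in net.ccds:
        ccd_anchors.append([
            a for a in net.anchors.values()
            if a.chrom == ccd.chrom and a.start < ccd.end and ccd.start < a.end
        ])
    sv_by_id = {sv.id: sv for sv in svs}
    # precompute: sv -> ccd indices whose anchors it intersects
    sv_hits: dict[str, list[int]] = {}
    for sv in svs:
        iv = sv.interval
        hits = []
        for ci, anchors in enumerate(ccd_anchors):
            if net.ccds[ci].chrom != sv.chrom:
                continue
            if any(a.start < iv.end and iv.start < a.end for a in anchors):
                hits.append(ci)
        if hits:
            sv_hits[sv.id] = hits

    patterns: dict[tuple[int, frozenset], set] = {}
    for sample in samples:
        per_ccd: dict[int, set[str]] = {}
        for sv in svs:
            if sv.delta(sample) == 0 or sv.id not in sv_hits:
                continue
            for ci in sv_hits[sv.id]:
                per_ccd.setdefault(ci, set()).add(sv.id)
        for ci, ids in per_ccd.items():
            patterns.setdefault((ci, frozenset(ids)), set()).add(sample)

    n = len(patterns)
    single = multi = multi_same = 0
    for (ci, ids), _samp in patterns.items():
        types = {sv_by_id[i].svtype for i in ids}
        if len(types) == 1:
            single += 1
        if len(ids) >= 2:
            multi += 1
            if len(types) == 1:
                multi_same += 1
    shared_all = 0
    if populations:
        groups = set(populations.values())
        for _key, samp in patterns.items():
            if {populations.get(s) for s in samp} >= groups:
                shared_all += 1
    return PatternSummary(
        patterns=patterns,
        n_unique=n,
        fraction_single_type=single / n if n else 0.0,
        n_multi=multi,
        fraction_multi_same_type=multi_same / multi if multi else 0.0,
        shared_all_groups=shared_all,
    )
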