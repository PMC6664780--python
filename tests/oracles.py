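"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own data structures and code paths:
the rewrite oracle works on plain dicts/lists applying the documented edit
rules one SV at a time; the motif oracle scores every window naively; the
regression oracle uses the closed-form OLS formulas.
"""

from __future__ import annotations

import math

import numpy as np

MOTIF_INS_LEN = 19  # insertion-derived anchor width used by the library


# ---------------------------------------------------------------------------
# Naive motif scanning
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_score(window: str, weights: np.ndarray) -> float:
    total = 0.0
    for k, b in enumerate(window):
        if b not in "ACGT":
            return -math.inf
        total += weights["ACGT".index(b), k]
    return total


def naive_best_hit(seq: str, weights: np.ndarray, min_score: float = 0.0):
    """Exhaustive best (pos, strand, score) over all windows, or None."""
    L = weights.shape[1]
    best = None
    for pos in range(len(seq) - L + 1):
        window = seq[pos:pos + L]
        for strand, w in (("+", window), ("-", naive_revcomp(window))):
            s = naive_score(w, weights)
            if s <= min_score:
                continue
            key = (-s, pos, strand)  # max score, then leftmost, then '+'
            if best is None or key < best[0]:
                best = (key, (pos, strand, s))
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# Closed-form OLS
# ---------------------------------------------------------------------------

def ols_slope_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    from scipy import stats

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    s2 = np.sum(resid ** 2) / (n - 2)
    se = math.sqrt(s2 / sxx)
    t = slope / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return float(slope), float(p)


# ---------------------------------------------------------------------------
# Graph-rewrite oracle
# ---------------------------------------------------------------------------

class RewriteOracle:
    """Plain-data reimplementation of the SV rewrite rules (one chromosome).

    State: anchors {id: {start, end, strand, isolated}}, loops
    {(a, b): freq}, ccds [[start, end, left_id, right_id]].
    """

    def __init__(self, net):
        chroms = {a.chrom for a in net.anchors.values()}
        assert len(chroms) == 1, "oracle handles single-chromosome fixtures"
        self.chrom = chroms.pop()
        self.anchors = {}
        for a in net.anchors.values():
            strand = None
            if a.motifs and len({m.strand for m in a.motifs}) == 1:
                strand = a.motifs[0].strand
            self.anchors[a.id] = {
                "start": a.start, "end": a.end, "strand": strand,
                "isolated": "isolated" in a.flags,
            }
        self.loops = {}
        for lp in net.loops:
            key = (min(lp.a, lp.b), max(lp.a, lp.b))
            self.loops[key] = self.loops.get(key, 0) + lp.frequency
        self.ccds = [[c.start, c.end, c.left_anchor, c.right_anchor]
                     for c in sorted(net.ccds, key=lambda c: c.start)]
        self.next_id = max(self.anchors, default=-1) + 1
        self.offset_log: list[tuple[int, int]] = []  # (ref position, cumulative delta)

    # -- helpers -----------------------------------------------------------
    def mid(self, aid: int) -> float:
        a = self.anchors[aid]
        return (a["start"] + a["end"]) / 2.0

    def degree(self, aid: int) -> int:
        return sum(1 for a, b in self.loops if aid in (a, b))

    def hit(self, s: int, e: int) -> list[int]:
        out = [aid for aid, a in self.anchors.items()
               if a["start"] < e and s < a["end"]]
        out.sort(key=lambda i: (self.anchors[i]["start"],
                                self.anchors[i]["end"], i))
        return out

    def add_loop(self, a: int, b: int, freq: int) -> bool:
        if a == b:
            return False
        key = (min(a, b), max(a, b))
        if key in self.loops:
            return False
        self.loops[key] = freq
        return True

    def nearest_partner(self, aid: int):
        a = self.anchors[aid]
        mid = self.mid(aid)
        strand = a["strand"]
        best = None
        for oid, o in self.anchors.items():
            if oid == aid:
                continue
            omid = self.mid(oid)
            if strand is not None:
                if o["strand"] is None:
                    continue
                if omid < mid and not (o["strand"] == "+" and strand == "-"):
                    continue
                if omid > mid and not (strand == "+" and o["strand"] == "-"):
                    continue
                if omid == mid:
                    continue
            key = (abs(omid - mid), omid, oid)
            if best is None or key < best[0]:
                best = (key, oid)
        return None if best is None else best[1]

    def relink(self) -> None:
        orphans = [aid for aid in self.anchors
                   if self.degree(aid) == 0 and not self.anchors[aid]["isolated"]]
        orphans.sort(key=lambda i: (self.anchors[i]["start"],
                                    self.anchors[i]["end"], i))
        for aid in orphans:
            if self.degree(aid) > 0:
                continue
            partner = self.nearest_partner(aid)
            if partner is None:
                self.anchors[aid]["isolated"] = True
                continue
            self.add_loop(aid, partner, 1)

    def shift(self, at: int, by: int) -> None:
        for a in self.anchors.values():
            if a["end"] <= at:
                continue
            if a["start"] >= at:
                a["start"] += by
            a["end"] += by
        for c in self.ccds:
            new_end = c[1] + by if c[1] > at else c[1]
            new_start = c[0] + by if c[0] >= at else c[0]
            c[0], c[1] = new_start, max(new_end, new_start + 1)

    def fuse_with_neighbor(self, ccd, side: str) -> None:
        if ccd not in self.ccds:
            return
        idx = self.ccds.index(ccd)
        nb = None
        if side == "left" and idx > 0:
            nb = self.ccds[idx - 1]
        elif side == "right" and idx + 1 < len(self.ccds):
            nb = self.ccds[idx + 1]
        if nb is None:
            return  # border dropped, CCD kept
        left, right = (nb, ccd) if side == "left" else (ccd, nb)
        fused = [left[0], right[1], left[2], right[3]]
        self.ccds.remove(ccd)
        self.ccds.remove(nb)
        self.ccds.append(fused)
        self.ccds.sort(key=lambda c: c[0])

    # -- SV applications ---------------------------------------------------
    def deletion(self, s: int, e: int) -> None:
        hit = set(self.hit(s, e))
        for c in [c for c in self.ccds if s <= c[0] and c[1] <= e]:
            self.ccds.remove(c)
        for side, pos in (("left", 2), ("right", 3)):
            for c in [c for c in sorted(self.ccds, key=lambda x: x[0])
                      if c[pos] in hit]:
                self.fuse_with_neighbor(c, side)
        self.loops = {k: f for k, f in self.loops.items()
                      if k[0] not in hit and k[1] not in hit}
        for aid in hit:
            del self.anchors[aid]
        self.shift(e, -(e - s))
        self.relink()

    def duplication(self, s: int, e: int, copies: int) -> None:
        hit = self.hit(s, e)
        hit_set = set(hit)
        length = e - s
        same = sorted(self.ccds, key=lambda c: c[0])
        for left, right in zip(same, same[1:]):
            if s < left[1] and e > right[0]:
                fused = [left[0], right[1], left[2], right[3]]
                self.ccds.remove(left)
                self.ccds.remove(right)
                self.ccds.append(fused)
                self.ccds.sort(key=lambda c: c[0])
                break
        self.shift(e, copies * length)
        upstream, internal, moving = [], [], []
        for (a, b), f in list(self.loops.items()):
            ah, bh = a in hit_set, b in hit_set
            if ah and bh:
                internal.append(((a, b), f))
            elif ah or bh:
                h = a if ah else b
                partner = b if ah else a
                if self.mid(partner) < s:
                    upstream.append(((a, b), f))
                else:
                    moving.append(((a, b), f, h))
        copy_ids = {}
        for c in range(1, copies + 1):
            offset = c * length
            for aid in hit:
                a = self.anchors[aid]
                nid = self.next_id
                self.next_id += 1
                self.anchors[nid] = {"start": a["start"] + offset,
                                     "end": a["end"] + offset,
                                     "strand": a["strand"],
                                     "isolated": a["isolated"]}
                copy_ids[(aid, c)] = nid
        for c in range(1, copies + 1):
            for (a, b), f in internal:
                self.add_loop(copy_ids[(a, c)], copy_ids[(b, c)], f)
        for (a, b), f, h in moving:
            del self.loops[(a, b)]
            nid = copy_ids[(h, copies)]
            other = b if a == h else a
            self.loops[(min(nid, other), max(nid, other))] = f
        self.relink()

    def inversion(self, s: int, e: int) -> None:
        hit = self.hit(s, e)
        hit_set = set(hit)
        for aid in hit:
            a = self.anchors[aid]
            cs, ce = max(a["start"], s), min(a["end"], e)
            a["start"], a["end"] = s + (e - ce), s + (e - cs)
            if a["strand"] is not None:
                a["strand"] = "+" if a["strand"] == "-" else "-"
        self.loops = {k: f for k, f in self.loops.items()
                      if k[0] not in hit_set and k[1] not in hit_set}
        for aid in sorted(hit, key=lambda i: (self.anchors[i]["start"],
                                              self.anchors[i]["end"], i)):
            partner = self.nearest_partner(aid)
            if partner is None:
                self.anchors[aid]["isolated"] = True
                continue
            self.add_loop(aid, partner, 1)
            for c in list(self.ccds):
                if c[2] == aid and c[3] == partner:
                    self.fuse_with_neighbor(c, "left")
                elif c[3] == aid and c[2] == partner:
                    self.fuse_with_neighbor(c, "right")
        self.relink()

    def insertion(self, pos: int, length: int, motif_offset, motif_strand) -> None:
        self.shift(pos, length)
        if motif_offset is not None:
            m_start = pos + motif_offset
            nid = self.next_id
            self.next_id += 1
            self.anchors[nid] = {"start": m_start,
                                 "end": m_start + MOTIF_INS_LEN,
                                 "strand": motif_strand, "isolated": False}
            in_ccd = any(c[0] <= m_start < c[1] for c in self.ccds)
            if not in_ccd and self.ccds:
                self.anchors[nid]["isolated"] = True
            else:
                partner = self.nearest_partner(nid)
                if partner is None:
                    self.anchors[nid]["isolated"] = True
                else:
                    self.add_loop(nid, partner, 1)
        self.relink()

    # -- driver ------------------------------------------------------------
    def apply_all(self, svs, sample: str) -> None:
        """Qualifying SVs, left to right, with cumulative offset mapping.

        Fixture SVs never overlap, so the current-frame position of each SV
        is its reference position plus the summed length change of the SVs
        already applied to its left.
        """
        order = {"DEL": 0, "DUP": 1, "mCNV": 1, "INV": 2, "INS": 3}
        chosen = [sv for sv in svs if sv.genotypes.get(sample, 0) != 0]
        chosen.sort(key=lambda sv: (sv.start, order[sv.svtype], sv.id))
        delta_len = 0
        for sv in chosen:
            s = sv.start + delta_len
            e = sv.end + delta_len
            if sv.svtype == "DEL":
                self.deletion(s, e)
                delta_len -= e - s
            elif sv.svtype == "DUP":
                self.duplication(s, e, 1)
                delta_len += e - s
            elif sv.svtype == "INV":
                self.inversion(s, e)
            elif sv.svtype == "INS":
                self.insertion(s, sv.ins_length, sv.ins_motif_offset,
                               sv.ins_motif_strand)
                delta_len += sv.ins_length
            self.offset_log.append((sv.end, delta_len))

    def expected_forward(self, ref_pos: int) -> int:
        delta = 0
        for ref_end, cum in self.offset_log:
            if ref_end <= ref_pos:
                delta = cum
        return ref_pos + delta
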