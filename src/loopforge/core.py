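"""Core domain types shared by every loopforge module.

All coordinates are 0-based half-open on a single assembly. Loops are
intrachromosomal pairs of anchors ordered by genomic position; chromatin
contact domains (CCDs) are maximal segments continuously covered by loops.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Optional

CTCF = "CTCF"
RNAPII = "RNAPII"

SV_TYPES = ("DEL", "DUP", "mCNV", "INV", "INS")

ORIENTATIONS = (
    "convergent",
    "tandem_right",
    "tandem_left",
    "divergent",
    "ambiguous",
    "unoriented",
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not self.start < self.end:
            raise ValueError(
                f"require start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TrackRecord:
    """A scored/stranded interval as read from BED-like tracks."""

    interval: GenomicInterval
    score: Optional[float] = None
    strand: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand is not None and self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class MotifHit:
    """A valid PWM hit: interval, strand and log-odds score (bits)."""

    interval: GenomicInterval
    strand: str
    score: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class Anchor:
    """One side of a loop: an interval, its best CTCF motif, support flags.

    ``motifs`` holds every valid (score > 0) per-peak motif found inside the
    anchor; ``strand`` is defined only when those motifs agree.
    """

    id: int
    chrom: str
    start: int
    end: int
    motifs: list[MotifHit] = field(default_factory=list)
    support: set[str] = field(default_factory=set)
    functional: set[str] = field(default_factory=set)
    flags: set[str] = field(default_factory=set)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def best_motif(self) -> Optional[MotifHit]:
        if not self.motifs:
            return None
        return max(self.motifs, key=lambda m: m.score)

    @property
    def strand(self) -> Optional[str]:
        """Unique motif strand, or None when absent or contradictory."""
        strands = {m.strand for m in self.motifs}
        if len(strands) == 1:
            return next(iter(strands))
        return None

    @property
    def ambiguous(self) -> bool:
        return len({m.strand for m in self.motifs}) > 1


@dataclass
class Loop:
    """A pairwise interaction between two anchors (a before b)."""

    a: int
    b: int
    frequency: int = 1
    mediator: str = CTCF

    def other(self, anchor_id: int) -> int:
        if anchor_id == self.a:
            return self.b
        if anchor_id == self.b:
            return self.a
        raise KeyError(anchor_id)

    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


@dataclass
class CCD:
    """A chromatin contact domain with border motifs and member loops."""

    chrom: str
    start: int
    end: int
    left_anchor: int
    right_anchor: int
    left_border: Optional[MotifHit] = None
    right_border: Optional[MotifHit] = None
    loop_ids: list[int] = field(default_factory=list)
    low_confidence: bool = False

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass
class StructuralVariant:
    """A typed SV interval with per-sample signed copy-delta genotypes.

    For DEL/DUP/mCNV the genotype is the summed copy change across homologs
    (homozygous deletion = -2); for INV/INS it is the non-reference allele
    count. Insertions are zero-footprint: ``start == end`` is allowed via
    ``ins_length`` and the reference interval is ``[start, start+1)``-free.
    """

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    genotypes: dict[str, int] = field(default_factory=dict)
    vaf: float = 0.0
    populations: dict[str, str] = field(default_factory=dict)
    ins_length: int = 0
    ins_motif_offset: Optional[int] = None
    ins_motif_strand: Optional[str] = None
    # per-homolog signed deltas, when phase is known: sample -> (hap1, hap2)
    haplotypes: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.svtype == "INS":
            if self.ins_length <= 0:
                raise ValueError("INS requires ins_length > 0")
        elif not self.start < self.end:
            raise ValueError("non-INS SV requires start < end")

    @property
    def length(self) -> int:
        return self.ins_length if self.svtype == "INS" else self.end - self.start

    @property
    def interval(self) -> GenomicInterval:
        end = self.end if self.end > self.start else self.start + 1
        return GenomicInterval(self.chrom, self.start, end)

    def delta(self, sample: str) -> int:
        return self.genotypes.get(sample, 0)

    def is_homozygous(self, sample: str) -> bool:
        d = self.genotypes.get(sample, 0)
        if self.svtype in ("DEL",):
            return d <= -2
        if self.svtype in ("INV", "INS"):
            return d >= 2
        # CNVs: homozygous when copy number changed on both homologs; with
        # the summed encoding we use |delta| >= 2 as the practical criterion.
        return abs(d) >= 2


class Network:
    """Anchors + loops + CCDs of one interaction network.

    Anchors are stored by integer id; loops refer to anchor ids. The class
    is a plain mutable container -- all topology edits live in
    :mod:`loopforge.rewrite`.
    """

    def __init__(
        self,
        anchors: Optional[dict[int, Anchor]] = None,
        loops: Optional[list[Loop]] = None,
        ccds: Optional[list[CCD]] = None,
        gaps: Optional[list[GenomicInterval]] = None,
    ) -> None:
        self.anchors: dict[int, Anchor] = anchors or {}
        self.loops: list[Loop] = loops or []
        self.ccds: list[CCD] = ccds or []
        self.gaps: list[GenomicInterval] = gaps or []
        self._next_id = max(self.anchors, default=-1) + 1

    # ---- bookkeeping -----------------------------------------------------
    def new_anchor_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    def add_anchor(self, anchor: Anchor) -> None:
        self.anchors[anchor.id] = anchor
        self._next_id = max(self._next_id, anchor.id + 1)

    def chroms(self) -> list[str]:
        return sorted({a.chrom for a in self.anchors.values()})

    def anchors_on(self, chrom: str) -> list[Anchor]:
        out = [a for a in self.anchors.values() if a.chrom == chrom]
        out.sort(key=lambda a: (a.start, a.end, a.id))
        return out

    def degree(self, anchor_id: int) -> int:
        return sum(1 for lp in self.loops if anchor_id in (lp.a, lp.b))

    def loops_of(self, anchor_id: int) -> list[Loop]:
        return [lp for lp in self.loops if anchor_id in (lp.a, lp.b)]

    def loop_span(self, loop: Loop) -> GenomicInterval:
        a, b = self.anchors[loop.a], self.anchors[loop.b]
        return GenomicInterval(a.chrom, min(a.start, b.start), max(a.end, b.end))

    def ordered_pair(self, loop: Loop) -> tuple[Anchor, Anchor]:
        a, b = self.anchors[loop.a], self.anchors[loop.b]
        if (b.start, b.end) < (a.start, a.end):
            a, b = b, a
        return a, b

    def copy(self) -> "Network":
        return _copy.deepcopy(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<Network {len(self.anchors)} anchors, {len(self.loops)} loops, "
            f"{len(self.ccds)} CCDs>"
        )


def merge_intervals(
    intervals: Iterable[tuple[int, int]], touch: bool = True
) -> list[tuple[int, int]]:
    """Union of (start, end) pairs; 0-bp touching merges when ``touch``."""
    ivs = sorted(intervals)
    out: list[list[int]] = []
    for s, e in ivs:
        if out and (s < out[-1][1] or (touch and s == out[-1][1])):
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]
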