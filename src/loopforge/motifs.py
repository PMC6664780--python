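"""Consensus-peak construction and PWM scanning for oriented CTCF motifs.

Scanning is plain log-odds over both strands; only hits with score > 0 are
valid and each scanned region keeps its single best hit. Allele rescans
compare the best valid hit before and after a substitution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import GenomicInterval, MotifHit

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Pwm:
    """Log-odds position weight matrix (bits), 4 x L, rows A/C/G/T."""

    weights: np.ndarray
    background: np.ndarray
    pseudocount: float

    @property
    def length(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.weights.argmax(axis=0))


def build_pwm(
    pfm: np.ndarray,
    background: Optional[Sequence[float]] = None,
    pseudocount: float = 0.8,
) -> Pwm:
    """Build a log2-odds PWM from a count matrix.

    weight[b, i] = log2((count[b, i] + pc * bg[b]) / column_total) - log2(bg[b]).
    """
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4:
        raise ValueError("PFM must be 4 x L")
    if (pfm < 0).any():
        raise ValueError("PFM counts must be nonnegative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 probabilities summing to 1")
    if (pfm.sum(axis=0) == 0).any():
        raise ValueError("PFM column with zero total count")
    smoothed = pfm + pseudocount * bg[:, None]
    probs = smoothed / smoothed.sum(axis=0, keepdims=True)
    weights = np.log2(probs) - np.log2(bg)[:, None]
    return Pwm(weights=weights, background=bg, pseudocount=pseudocount)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)  # 4 = N / other
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def window_scores(seq: str, pwm: Pwm) -> tuple[np.ndarray, np.ndarray]:
    """Log-odds scores of every window on (+, -) strands.

    Windows containing a non-ACGT base score -inf. Reverse-strand windows
    are scored on the reverse complement of the window sequence.
    """
    L = pwm.length
    enc = _encode(seq)
    n = len(seq) - L + 1
    if n <= 0:
        return np.empty(0), np.empty(0)
    # weights padded with a -inf row for N
    w = np.vstack([pwm.weights, np.full((1, L), -np.inf)])
    idx = np.lib.stride_tricks.sliding_window_view(enc, L)
    fwd = w[idx, np.arange(L)].sum(axis=1)
    # reverse strand: complement bases, reversed positions
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int8)
    rev = w[comp[idx][:, ::-1], np.arange(L)].sum(axis=1)
    return fwd, rev


def scan_best_motif(
    seq: str,
    pwm: Pwm,
    chrom: str = "seq",
    offset: int = 0,
    min_score: float = 0.0,
) -> Optional[MotifHit]:
    """Best valid motif hit over both strands, or None.

    Ties are broken leftmost-first, then + strand. ``offset`` shifts the
    reported interval into chromosome coordinates.
    """
    if len(seq) < pwm.length:
        warnings.warn("sequence shorter than motif; no scan performed")
        return None
    fwd, rev = window_scores(seq, pwm)
    best = max(fwd.max(initial=-np.inf), rev.max(initial=-np.inf))
    if not np.isfinite(best) or best <= min_score:
        return None
    # leftmost, then + strand
    pos_f = np.flatnonzero(fwd == best)
    pos_r = np.flatnonzero(rev == best)
    cand = []
    if pos_f.size:
        cand.append((int(pos_f[0]), 0))
    if pos_r.size:
        cand.append((int(pos_r[0]), 1))
    pos, is_rev = min(cand)
    return MotifHit(
        interval=GenomicInterval(chrom, offset + pos, offset + pos + pwm.length),
        strand="-" if is_rev else "+",
        score=float(best),
    )


def scan_all_valid(
    seq: str, pwm: Pwm, chrom: str = "seq", offset: int = 0, min_score: float = 0.0
) -> list[MotifHit]:
    """All valid hits (score > min_score) on both strands, leftmost first."""
    if len(seq) < pwm.length:
        return []
    fwd, rev = window_scores(seq, pwm)
    hits = []
    for strand, scores in (("+", fwd), ("-", rev)):
        for pos in np.flatnonzero(scores > min_score):
            hits.append(
                MotifHit(
                    GenomicInterval(chrom, offset + int(pos), offset + int(pos) + pwm.length),
                    strand,
                    float(scores[pos]),
                )
            )
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def rescore_with_allele(
    seq: str, variant_allele: str, offset: int, pwm: Pwm
) -> tuple[Optional[MotifHit], Optional[MotifHit]]:
    """Best valid hit before and after substituting ``variant_allele``.

    ``offset`` is the 0-based position of the substituted base within
    ``seq``; multi-base alleles substitute in place.
    """
    if not variant_allele or any(b not in "ACGT" for b in variant_allele.upper()):
        raise ValueError(f"allele must be over ACGT, got {variant_allele!r}")
    if not (0 <= offset and offset + len(variant_allele) <= len(seq)):
        raise ValueError("substitution outside sequence bounds")
    alt_seq = seq[:offset] + variant_allele.upper() + seq[offset + len(variant_allele):]
    ref = scan_best_motif(seq, pwm)
    alt = scan_best_motif(alt_seq, pwm)
    return ref, alt


# ---------------------------------------------------------------------------
# Consensus peaks
# ---------------------------------------------------------------------------

def consensus_peaks(
    peak_sets: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """n-way consensus: maximal regions covered by a peak from every set.

    The result is the intersection of each set's merged coverage; output is
    sorted and non-overlapping.
    """
    if len(peak_sets) < 2:
        raise ValueError("need at least 2 peak sets for a consensus")
    if any(len(s) == 0 for s in peak_sets):
        warnings.warn("empty peak set in consensus input; result is empty")
        return []
    merged = [_merge_by_chrom(s) for s in peak_sets]
    result = merged[0]
    for other in merged[1:]:
        result = _intersect(result, other)
        if not result:
            return []
    return [GenomicInterval(c, s, e) for c, s, e in result]


def _merge_by_chrom(peaks) -> list[tuple[str, int, int]]:
    by: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by.setdefault(p.chrom, []).append((p.start, p.end))
    out = []
    for chrom in sorted(by):
        ivs = sorted(by[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


def _intersect(a, b):
    out = []
    by_chrom_b: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in b:
        by_chrom_b.setdefault(c, []).append((s, e))
    by_chrom_a: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in a:
        by_chrom_a.setdefault(c, []).append((s, e))
    for chrom in sorted(set(by_chrom_a) & set(by_chrom_b)):
        xs, ys = by_chrom_a[chrom], by_chrom_b[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            s = max(xs[i][0], ys[j][0])
            e = min(xs[i][1], ys[j][1])
            if s < e:
                out.append((chrom, s, e))
            if xs[i][1] < ys[j][1]:
                i += 1
            else:
                j += 1
    return out
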