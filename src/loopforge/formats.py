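"""Readers and writers for the external formats the toolkit touches.

Every reader normalizes into 0-based half-open coordinates. VCF positions
(1-based) are shifted on read; BED dialects are taken as already 0-based
unless ``one_based=True`` is passed. Readers reject malformed records with
an error naming the offending line, or drop them with a warning where the
spec of the format makes the record merely unusable (e.g. interchromosomal
loop rows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core import GenomicInterval, StructuralVariant, TrackRecord

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised when a file does not conform to its declared format."""


@dataclass(frozen=True)
class RawLoop:
    """A loop as read from BEDPE, before anchor merging."""

    chrom: str
    start1: int
    end1: int
    start2: int
    end2: int
    frequency: int
    mediator: str


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

def read_bed(path: PathLike, one_based: bool = False) -> list[GenomicInterval]:
    """Read BED3+ (extra columns ignored)."""
    shift = 1 if one_based else 0
    out = []
    for lineno, parts in _tab_lines(path):
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
        try:
            iv = GenomicInterval(parts[0], int(parts[1]) - shift, int(parts[2]) - shift)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        out.append(iv)
    return out


def read_track(path: PathLike) -> list[TrackRecord]:
    """Read BED6/narrowPeak rows into :class:`TrackRecord`."""
    out = []
    for lineno, parts in _tab_lines(path):
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
        try:
            iv = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            name = parts[3] if len(parts) > 3 else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else None
            out.append(TrackRecord(iv, score=score, strand=strand, name=name))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# BEDPE loops
# ---------------------------------------------------------------------------

def read_bedpe_loops(
    path: PathLike, mediator: str, one_based: bool = False
) -> list[RawLoop]:
    """Read PET clusters from BEDPE (chrom1 s1 e1 chrom2 s2 e2 count).

    Anchors are returned in genomic order; interchromosomal rows are dropped
    with a warning (the interactions modeled here are intrachromosomal).
    """
    shift = 1 if one_based else 0
    out: list[RawLoop] = []
    n_skipped = 0
    for lineno, parts in _tab_lines(path):
        if len(parts) < 7:
            raise FormatError(f"{path}:{lineno}: expected >= 7 columns, got {len(parts)}")
        try:
            c1, s1, e1 = parts[0], int(parts[1]) - shift, int(parts[2]) - shift
            c2, s2, e2 = parts[3], int(parts[4]) - shift, int(parts[5]) - shift
            freq = int(parts[6])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        if s1 >= e1 or s2 >= e2:
            raise FormatError(f"{path}:{lineno}: anchor with start >= end")
        if freq < 1:
            raise FormatError(f"{path}:{lineno}: PET count must be >= 1")
        if c1 != c2:
            n_skipped += 1
            continue
        if (s2, e2) < (s1, e1):
            s1, e1, s2, e2 = s2, e2, s1, e1
        out.append(RawLoop(c1, s1, e1, s2, e2, freq, mediator))
    if n_skipped:
        warnings.warn(
            f"{path}: dropped {n_skipped} interchromosomal loop record(s)"
        )
    return out


def write_bedpe_loops(loops: Sequence[RawLoop], path: PathLike) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                f"{lp.chrom}\t{lp.start1}\t{lp.end1}\t{lp.chrom}\t"
                f"{lp.start2}\t{lp.end2}\t{lp.frequency}\n"
            )


# ---------------------------------------------------------------------------
# SV VCF (1000 Genomes phase-3 SV dialect)
# ---------------------------------------------------------------------------

_CNV_ALIASES = {"CNV": "mCNV", "MCNV": "mCNV", "DEL": "DEL", "DUP": "DUP",
                "INV": "INV", "INS": "INS", "ALU": "INS", "LINE1": "INS",
                "SVA": "INS", "DUP:TANDEM": "DUP"}


def read_sv_vcf(path: PathLike) -> list[StructuralVariant]:
    """Read SVs with per-sample signed copy-delta genotypes.

    DEL/DUP/INV/INS use GT allele counts; multiallelic CNVs (``<CNn>`` ALT
    alleles) use per-homolog copy numbers, the genotype being the summed
    per-homolog change relative to one copy each. SNP/indel records are
    skipped with a counter; half-called genotypes count as reference.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out: list[StructuralVariant] = []
    n_skipped = n_halfcalled = 0
    for rec in vcf:
        svtype = rec.INFO.get("SVTYPE")
        if svtype is None:
            n_skipped += 1
            continue
        svtype = _CNV_ALIASES.get(str(svtype).upper())
        if svtype is None:
            n_skipped += 1
            continue
        start = rec.POS - 1  # VCF is 1-based
        alts = [str(a) for a in (rec.ALT or [])]
        multi_cn = any(a.startswith("<CN") for a in alts)
        if multi_cn:
            svtype = "mCNV"
        if svtype == "INS":
            svlen = rec.INFO.get("SVLEN")
            ins_len = abs(int(svlen)) if svlen is not None else max(
                (len(a) for a in alts if not a.startswith("<")), default=1
            )
            end = start  # zero-length reference footprint
        else:
            end_info = rec.INFO.get("END")
            if end_info is None:
                svlen = rec.INFO.get("SVLEN")
                if svlen is None:
                    warnings.warn(f"{rec.ID}: non-INS SV without END/SVLEN, rejected")
                    continue
                end = start + abs(int(svlen))
            else:
                end = int(end_info)
            ins_len = 0
            if end <= start:
                warnings.warn(f"{rec.ID}: END <= POS, rejected")
                continue

        genotypes: dict[str, int] = {}
        gts = rec.genotypes  # [allele1, allele2, phased]
        for sample, gt in zip(samples, gts):
            alleles = [a for a in gt[:-1] if a is not None and a >= 0]
            if len(alleles) < len(gt) - 1:
                n_halfcalled += 1
            if not alleles:
                continue
            if multi_cn:
                delta = sum(_allele_cn(a, alts) - 1 for a in alleles)
            elif svtype == "DEL":
                delta = -sum(1 for a in alleles if a > 0)
            elif svtype == "DUP":
                delta = sum(1 for a in alleles if a > 0)
            else:  # INV / INS: non-reference allele count
                delta = sum(1 for a in alleles if a > 0)
            if delta:
                genotypes[sample] = delta

        af = rec.INFO.get("AF")
        vaf = float(af[0] if isinstance(af, (tuple, list)) else af) if af is not None else (
            len(genotypes) / (2 * len(samples)) if samples else 0.0
        )
        out.append(
            StructuralVariant(
                id=rec.ID or f"sv_{rec.CHROM}_{start}",
                chrom=rec.CHROM,
                start=start,
                end=end,
                svtype=svtype,
                genotypes=genotypes,
                vaf=vaf,
                ins_length=ins_len,
            )
        )
    if n_halfcalled:
        warnings.warn(
            f"{path}: {n_halfcalled} half-called genotype(s) treated as reference"
        )
    if n_skipped:
        warnings.warn(f"{path}: skipped {n_skipped} non-SV record(s)")
    return out


def _allele_cn(allele_index: int, alts: list[str]) -> int:
    if allele_index == 0:
        return 1
    alt = alts[allele_index - 1]
    if alt.startswith("<CN") and alt.endswith(">"):
        return int(alt[3:-1])
    return 1


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

def read_jaspar_pfm(path: PathLike) -> np.ndarray:
    """Read a JASPAR-style position frequency matrix as a 4 x L array.

    Rows are A, C, G, T. Accepts both the bracketed dialect
    (``A [ 87 167 ... ]``) and bare whitespace-separated rows; a leading
    ``>`` header line is allowed.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            if "[" in line:
                line = line[line.index("[") + 1:]
            line = line.replace("]", " ")
            fields = line.split()
            if fields and fields[0].upper() in "ACGT" and len(fields[0]) == 1:
                fields = fields[1:]
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise FormatError(f"{path}: unparsable PFM row {line!r}") from exc
    if len(rows) != 4:
        raise FormatError(f"{path}: expected 4 PFM rows (A,C,G,T), got {len(rows)}")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: PFM rows have unequal lengths {sorted(lengths)}")
    if next(iter(lengths)) < 1:
        raise FormatError(f"{path}: empty PFM")
    pfm = np.asarray(rows, dtype=float)
    if (pfm < 0).any():
        raise FormatError(f"{path}: negative counts in PFM")
    return pfm


def write_jaspar_pfm(pfm: np.ndarray, path: PathLike, name: str = "motif") -> None:
    pfm = np.asarray(pfm, dtype=float)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for base, row in zip("ACGT", pfm):
            fh.write(f"{base} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a whole FASTA into memory (fixture-sized genomes)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Structures (xyz-like, one MODEL block per structure)
# ---------------------------------------------------------------------------

def write_structures(ensemble, path: PathLike) -> None:
    """Serialize an ensemble of bead-chain structures.

    One ``MODEL``/``ENDMDL`` block per structure; one line per bead with its
    genomic span and full-precision coordinates so the paired reader
    round-trips bit-exactly.
    """
    structures = getattr(ensemble, "structures", ensemble)
    if not structures:
        raise ValueError("refusing to write an empty ensemble")
    with open(path, "w") as fh:
        for i, st in enumerate(structures, start=1):
            if not np.isfinite(st.coords).all():
                raise ValueError(f"structure {i}: non-finite coordinate")
            fh.write(f"MODEL {i} level={st.level}\n")
            for (chrom, s, e), (x, y, z) in zip(st.beads, st.coords):
                fh.write(f"{chrom}\t{s}\t{e}\t{float(x)!r}\t{float(y)!r}\t{float(z)!r}\n")
            fh.write("ENDMDL\n")


def read_structures(path: PathLike):
    """Read structures written by :func:`write_structures`."""
    from .model3d import Structure

    out = []
    beads: list[tuple[str, int, int]] = []
    coords: list[tuple[float, float, float]] = []
    level = "anchor"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("MODEL"):
                beads, coords = [], []
                for tok in line.split():
                    if tok.startswith("level="):
                        level = tok[6:]
            elif line.startswith("ENDMDL"):
                out.append(Structure(beads=beads, coords=np.array(coords), level=level))
            else:
                parts = line.split("\t")
                if len(parts) != 6:
                    raise FormatError(f"{path}:{lineno}: expected 6 columns")
                beads.append((parts[0], int(parts[1]), int(parts[2])))
                coords.append((float(parts[3]), float(parts[4]), float(parts[5])))
    return out


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_expression_tsv(path: PathLike):
    """Genes x samples expression matrix (first column gene IDs)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", index_col=0)


def read_tss_table(path: PathLike) -> list[tuple[str, str, int, str]]:
    """TSS table rows: gene, chrom, tss(0-based), strand."""
    out = []
    for lineno, parts in _tab_lines(path):
        if len(parts) < 4:
            raise FormatError(f"{path}:{lineno}: expected gene/chrom/tss/strand")
        out.append((parts[0], parts[1], int(parts[2]), parts[3]))
    return out


def read_chrom_sizes(path: PathLike) -> dict[str, int]:
    out = {}
    for lineno, parts in _tab_lines(path):
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected chrom/size")
        out[parts[0]] = int(parts[1])
    return out


def _tab_lines(path: PathLike):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")
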