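"""CCD-scoped SV-eQTL discovery.

Expression (assumed PEER-normalized upstream) is log-transformed and
standardized per gene; PCA on the gene space selects the genes
contributing most to inter-individual variance; every SV lying in the
same chromatin contact domain (CCD) as a selected gene's TSS is tested by
least-squares regression of expression on the signed copy-delta genotype
(Wald t-test on the slope). Per gene, expression is permuted relative to
genotypes, the minimum p over the gene's SVs recorded per permutation,
and the observed minimum p ranked in that null to give an adjusted p.
Benjamini-Hochberg across genes yields q-values; genes pass at q <= FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Network, StructuralVariant

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}


# ---------------------------------------------------------------------------
# Expression preprocessing
# ---------------------------------------------------------------------------

def preprocess(matrix: pd.DataFrame, pseudolog_offset: float = 1e-2
               ) -> pd.DataFrame:
    """log(x + offset), then per-gene standardization; constant genes drop.

    Rows are genes, columns samples; values must be nonnegative.
    """
    if (matrix.values < 0).any():
        raise ValueError("expression values must be nonnegative")
    logged = np.log(matrix + pseudolog_offset)
    sd = logged.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropping {int(constant.sum())} constant gene(s)")
        logged = logged.loc[~constant]
        sd = sd.loc[~constant]
    return logged.sub(logged.mean(axis=1), axis=0).div(sd, axis=0)


def select_genes_pca(matrix: pd.DataFrame, n_components: int = 100,
                     min_contribution: float = 0.01,
                     combine: str = "max") -> list[str]:
    """Genes whose loading on any of the first components is large enough.

    PCA runs with samples as observations and genes as variables on the
    standardized matrix. A gene is retained iff the absolute value of its
    unit-norm loading on at least one of the first ``n_components``
    components is >= ``min_contribution`` (``combine='sum'``: the summed
    absolute loading over those components crosses the threshold instead).
    """
    X = matrix.values.T  # samples x genes
    n_samples = X.shape[0]
    rank = min(n_samples - 1, X.shape[1])
    if n_components > rank:
        warnings.warn(f"n_components reduced from {n_components} to {rank}")
        n_components = rank
    Xc = X - X.mean(axis=0)
    _u, _s, vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = np.abs(vt[:n_components])  # components x genes, unit rows
    if combine == "max":
        score = loadings.max(axis=0)
    elif combine == "sum":
        score = loadings.sum(axis=0)
    else:
        raise ValueError(f"unknown combine {combine!r}")
    return [g for g, s in zip(matrix.index, score) if s >= min_contribution]


# ---------------------------------------------------------------------------
# Genotype encoding
# ---------------------------------------------------------------------------

@dataclass
class GenotypeVector:
    sv: StructuralVariant
    values: np.ndarray          # float, NaN where masked
    n_classes: int


def encode_genotypes(
    svs: Sequence[StructuralVariant],
    samples: Sequence[str],
    min_freq: float = 0.01,
    exclude_sex: bool = True,
) -> list[GenotypeVector]:
    """Signed copy-delta vectors over samples, rare classes masked.

    Genotype classes with population frequency below ``min_freq`` are
    masked (their samples dropped for that SV); SVs on sex chromosomes or
    left with fewer than two classes are excluded.
    """
    out = []
    n = len(samples)
    for sv in svs:
        if exclude_sex and sv.chrom in SEX_CHROMS:
            continue
        vec = np.array([float(sv.delta(s)) for s in samples])
        classes, counts = np.unique(vec, return_counts=True)
        rare = classes[counts / n < min_freq]
        for cls in rare:
            vec[vec == cls] = np.nan
        kept = np.unique(vec[~np.isnan(vec)])
        if len(kept) < 2:
            continue
        out.append(GenotypeVector(sv=sv, values=vec, n_classes=len(kept)))
    return out


# ---------------------------------------------------------------------------
# Per-pair regression
# ---------------------------------------------------------------------------

def test_gene_sv(expr: np.ndarray, genotype: np.ndarray,
                 min_samples: int = 10) -> tuple[float, float]:
    """OLS slope of expression on genotype and its two-sided Wald p."""
    ok = ~np.isnan(genotype) & ~np.isnan(expr)
    y, g = expr[ok], genotype[ok]
    if len(y) < min_samples:
        raise ValueError(f"only {len(y)} usable samples (< {min_samples})")
    if np.all(g == g[0]):
        raise ValueError("zero genotype variance")
    res = stats.linregress(g, y)
    return float(res.slope), float(res.pvalue)


def _batch_min_p(Y: np.ndarray, genotypes: Sequence[np.ndarray]) -> np.ndarray:
    """Minimum two-sided regression p across SVs, per row of Y.

    Vectorized Wald t-test via the correlation identity
    t = r * sqrt(df / (1 - r^2)).
    """
    n_rows = Y.shape[0]
    min_p = np.full(n_rows, 1.0)
    for g in genotypes:
        ok = ~np.isnan(g)
        gv = g[ok]
        df = len(gv) - 2
        if df <= 0 or np.all(gv == gv[0]):
            continue
        Ysub = Y[:, ok]
        gc = gv - gv.mean()
        Yc = Ysub - Ysub.mean(axis=1, keepdims=True)
        denom = np.sqrt((Yc ** 2).sum(axis=1) * (gc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Yc @ gc) / denom
            r = np.clip(r, -1.0, 1.0)
            t = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p = np.where(np.isnan(p), 1.0, p)
        min_p = np.minimum(min_p, p)
    return min_p


def permute_gene(expr: np.ndarray, genotypes: Sequence[np.ndarray],
                 n_perm: int = 1000,
                 rng: Optional[np.random.Generator] = None,
                 convention: str = "rank") -> float:
    """Permutation-adjusted p for a gene against its CCD's SVs.

    Each permutation shuffles the expression vector across samples once
    (jointly for all SVs), re-tests every SV and records the minimum p.
    ``rank`` convention (default): p_adj = #{perm <= obs}/n_perm floored
    at 1/n_perm; ``add_one``: (1 + #{perm <= obs}) / (1 + n_perm).
    """
    rng = rng if rng is not None else np.random.default_rng()
    obs = float(_batch_min_p(expr[None, :], genotypes)[0])
    perms = np.array([rng.permutation(expr) for _ in range(n_perm)])
    null = _batch_min_p(perms, genotypes)
    k = int(np.sum(null <= obs))
    if convention == "rank":
        return max(k, 1) / n_perm
    if convention == "add_one":
        return (k + 1) / (n_perm + 1)
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# Discovery pipeline
# ---------------------------------------------------------------------------

@dataclass
class EqtlRecord:
    gene: str
    sv_id: str
    slope: float
    p_wald: float
    p_adj: float
    q: float
    n_genotype_classes: int
    distance_class: Optional[str] = None


@dataclass
class EqtlResult:
    records: list[EqtlRecord]
    gene_p_adj: dict[str, float]
    gene_q: dict[str, float]
    n_genes_tested: int

    @property
    def significant_genes(self) -> list[str]:
        return sorted({r.gene for r in self.records})


def assign_genes_to_ccds(
    tss_table: Sequence[tuple[str, str, int, str]],
    net: Network,
) -> dict[str, int]:
    """gene -> CCD index by TSS containment; untested genes are logged."""
    out = {}
    for gene, chrom, tss, _strand in tss_table:
        found = None
        for ci, ccd in enumerate(net.ccds):
            if ccd.chrom == chrom and ccd.start <= tss < ccd.end:
                found = ci
                break
        if found is None:
            warnings.warn(f"TSS of {gene} falls in a CCD gap; gene untested")
        else:
            out[gene] = found
    return out


def discover(
    matrix: pd.DataFrame,
    svs: Sequence[StructuralVariant],
    net: Network,
    tss_table: Sequence[tuple[str, str, int, str]],
    fdr: float = 0.10,
    n_perm: int = 1000,
    seed: int = 0,
    min_freq: float = 0.01,
    min_samples: int = 10,
    already_standardized: bool = False,
    select_genes: bool = False,
    n_components: int = 100,
    proximity_threshold: Optional[float] = None,
) -> EqtlResult:
    """Full CCD-scoped eQTL scan at the given FDR.

    ``matrix`` is genes x samples. When ``select_genes`` is set, the PCA
    gene filter runs first. Genes whose TSS falls outside every CCD are
    untested; genes with no testable SV in their CCD are absent from the
    output.
    """
    expr = matrix if already_standardized else preprocess(matrix)
    if select_genes:
        keep = select_genes_pca(expr, n_components=n_components)
        expr = expr.loc[keep]
    samples = list(expr.columns)
    vectors = encode_genotypes(svs, samples, min_freq=min_freq)
    gene_ccd = assign_genes_to_ccds(
        [row for row in tss_table if row[0] in set(expr.index)], net
    )
    # SVs per CCD (interval containment of the SV midpoint is too strict;
    # residence = >= 1 bp overlap with the CCD interval)
    ccd_vectors: dict[int, list[GenotypeVector]] = {}
    for gv in vectors:
        iv = gv.sv.interval
        for ci, ccd in enumerate(net.ccds):
            if ccd.chrom == iv.chrom and ccd.start < iv.end and iv.start < ccd.end:
                ccd_vectors.setdefault(ci, []).append(gv)

    rng = np.random.default_rng(seed)
    genes, p_adjs, per_gene = [], [], {}
    for gene in expr.index:
        ci = gene_ccd.get(gene)
        if ci is None or ci not in ccd_vectors:
            continue
        gvs = ccd_vectors[ci]
        y = expr.loc[gene].values.astype(float)
        pairs = []
        for gv in gvs:
            try:
                slope, p = test_gene_sv(y, gv.values, min_samples=min_samples)
            except ValueError:
                continue
            pairs.append((gv, slope, p))
        if not pairs:
            continue
        p_adj = permute_gene(y, [gv.values for gv, _s, _p in pairs],
                             n_perm=n_perm, rng=rng)
        genes.append(gene)
        p_adjs.append(p_adj)
        per_gene[gene] = pairs

    if not genes:
        return EqtlResult([], {}, {}, 0)
    _rej, qvals, _a, _b = multipletests(p_adjs, alpha=fdr, method="fdr_bh")
    gene_q = dict(zip(genes, qvals))
    gene_p = dict(zip(genes, p_adjs))
    tss_by_gene = {row[0]: row[2] for row in tss_table}
    records = []
    for gene in genes:
        if gene_q[gene] > fdr:
            continue
        for gv, slope, p in per_gene[gene]:
            dist_class = None
            if proximity_threshold is not None and gene in tss_by_gene:
                from .enrichment import classify_proximal_distal
                dist_class = classify_proximal_distal(
                    gv.sv, tss_by_gene[gene], proximity_threshold)
            records.append(EqtlRecord(
                gene=gene, sv_id=gv.sv.id, slope=slope, p_wald=p,
                p_adj=gene_p[gene], q=float(gene_q[gene]),
                n_genotype_classes=gv.n_classes,
                distance_class=dist_class,
            ))
    return EqtlResult(records=records, gene_p_adj=gene_p,
                      gene_q=gene_q, n_genes_tested=len(genes))
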