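"""Marker QC, association scans, hit intersection and gene annotation.

The association procedure mirrors a multi-method GWAS workflow: filter
markers on minor-allele frequency and call rate, scan every SNP with more
than one method, keep only hits significant in *every* method (the
intersection is the reliability filter), map consensus SNPs to genes by
interval overlap, and summarise which genes are unique to one trait
versus shared.  The two scan methods here — marginal simple regression
and principal-component-adjusted regression — are deliberately generic:
they exercise the multi-method contract without re-implementing any
particular multi-locus mixed-model package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .exceptions import ValidationError


@dataclass
class GenotypeMatrix:
    """Dosage matrix (lines x SNPs) with per-SNP metadata.

    Dosages are minor-allele counts in {0, 1, 2}; missing entries are NaN.
    Positions are 1-based base pairs.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    line_ids: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        for name in ("snp_ids", "chrom", "pos", "ref", "alt"):
            if len(getattr(self, name)) != m:
                raise ValidationError(f"{name} length != number of SNPs")
        if len(self.line_ids) != n:
            raise ValidationError("line_ids length != number of lines")
        if len(set(self.snp_ids)) != m:
            raise ValidationError("SNP ids must be unique")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing lines, per SNP."""
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency over non-missing alleles, per SNP."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, index],
            np.asarray(self.snp_ids)[index],
            np.asarray(self.chrom)[index],
            np.asarray(self.pos)[index],
            np.asarray(self.ref)[index],
            np.asarray(self.alt)[index],
            self.line_ids,
        )

    def snp_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": self.snp_ids, "chrom": self.chrom, "pos": self.pos}
        )


@dataclass(frozen=True)
class HitSet:
    """SNPs significant for one method at one threshold."""

    method: str
    snps: frozenset
    threshold: float


def filter_markers(
    G: GenotypeMatrix, maf_min: float = 0.05, callrate_min: float = 0.9
) -> GenotypeMatrix:
    """Retain SNPs with call rate >= callrate_min and MAF >= maf_min.

    MAF is computed over non-missing alleles only (missing entries are
    excluded, never imputed, for QC).  Removing every SNP produces a
    warning and an empty matrix, not an exception.
    """
    if G.n_snps == 0:
        raise ValidationError("empty genotype matrix")
    keep = (G.call_rate() >= callrate_min) & (G.maf() >= maf_min)
    if not keep.any():
        warnings.warn("all SNPs removed by QC filters", stacklevel=2)
    return G.take_snps(np.nonzero(keep)[0])


def genomewide_threshold(n_snps: int) -> float:
    """Bonferroni-style genome-wide cutoff p <= 1/N."""
    if n_snps < 1:
        raise ValidationError("need at least one SNP")
    return 1.0 / n_snps


def _mean_impute(d: np.ndarray) -> np.ndarray:
    col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    out = np.where(np.isnan(d), col_mean[None, :], d)
    return out


def genotype_pcs(G: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """Top-k principal components of the standardized, imputed dosages."""
    X = _mean_impute(G.dosages)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = X / sd
    # n x n eigen-decomposition (lines << SNPs)
    cov = X @ X.T
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order]


def _residualize(v: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(covariates)
    return v - q @ (q.T @ v)


def assoc_scan(
    G: GenotypeMatrix,
    y: np.ndarray,
    method: str = "marginal",
    n_pcs: int = 3,
) -> pd.DataFrame:
    """Per-SNP association p-values for one trait.

    ``method`` is ``"marginal"`` (simple linear regression Wald test) or
    ``"pc_adjusted"`` (the same test with the top ``n_pcs`` genotype
    principal components as covariates).  Missing dosages are mean-imputed
    per SNP for testing only.  Monomorphic SNPs get p = 1 and are flagged.

    Returns a DataFrame with columns snp_id, beta, p, monomorphic.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != G.n_lines:
        raise ValidationError("phenotype length != number of lines")
    X = _mean_impute(G.dosages)

    if method == "marginal":
        covar = np.ones((G.n_lines, 1))
    elif method == "pc_adjusted":
        covar = np.column_stack([np.ones(G.n_lines), genotype_pcs(G, n_pcs)])
    else:
        raise ValidationError(f"unknown method {method!r}")

    Xr = _residualize(X, covar)
    yr = _residualize(y, covar)
    df = G.n_lines - covar.shape[1] - 1
    if df < 1:
        raise ValidationError("not enough lines for the requested model")

    sxx = (Xr**2).sum(axis=0)
    syy = float((yr**2).sum())
    sxy = Xr.T @ yr
    mono = sxx <= 1e-12
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = sxy / sxx_safe
    if syy <= 0:
        p = np.ones(G.n_snps)
        t2 = np.zeros(G.n_snps)
    else:
        r2 = np.clip(sxy**2 / (sxx_safe * syy), 0.0, 1.0 - 1e-15)
        t2 = r2 * df / (1.0 - r2)
        p = 2.0 * stats.t.sf(np.sqrt(t2), df)
    p = np.where(mono, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    beta = np.where(mono, 0.0, beta)
    return pd.DataFrame(
        {"snp_id": G.snp_ids, "beta": beta, "p": p, "monomorphic": mono}
    )


def hits_from_scan(scan: pd.DataFrame, method: str, threshold: float) -> HitSet:
    """Threshold one scan into a HitSet (p <= threshold)."""
    sig = scan.loc[scan["p"] <= threshold, "snp_id"]
    return HitSet(method=method, snps=frozenset(sig), threshold=threshold)


def intersect_hits(hitsets) -> frozenset:
    """Consensus SNPs: significant in every method."""
    hs = list(hitsets)
    if not hs:
        raise ValidationError("need at least one hitset")
    out = frozenset(hs[0].snps)
    for h in hs[1:]:
        out &= h.snps
    return out


def run_association(
    G: GenotypeMatrix,
    y: np.ndarray,
    methods=("marginal", "pc_adjusted"),
    threshold: float | None = None,
) -> tuple[dict[str, pd.DataFrame], list[HitSet], frozenset]:
    """Scan with every method, threshold (default 1/N), intersect."""
    if threshold is None:
        threshold = genomewide_threshold(G.n_snps)
    scans = {m: assoc_scan(G, y, m) for m in methods}
    hitsets = [hits_from_scan(s, m, threshold) for m, s in scans.items()]
    return scans, hitsets, intersect_hits(hitsets)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval, 1-based inclusive at both ends."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(f"gene {self.gene_id}: start > end")


def annotate_genes(
    snps: pd.DataFrame,
    genes,
    flank: int = 0,
) -> pd.DataFrame:
    """Assign genes to SNPs by interval overlap.

    A gene is assigned to a SNP iff the SNP position lies in
    [start - flank, end + flank] on the same chromosome (1-based inclusive
    at both ends).  ``snps`` needs columns snp_id, chrom, pos; ``genes``
    is an iterable of GeneAnnotation.  SNPs on chromosomes absent from the
    annotation are skipped with a warning.

    Returns a DataFrame with columns snp_id, gene_id.
    """
    genes = list(genes)
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # intervaltree is half-open; +1 makes the gene end inclusive
        trees.setdefault(str(g.chrom), IntervalTree()).addi(
            g.start - flank, g.end + flank + 1, g.gene_id
        )
    rows = []
    unknown = set()
    for snp_id, chrom, pos in zip(snps["snp_id"], snps["chrom"], snps["pos"]):
        tree = trees.get(str(chrom))
        if tree is None:
            unknown.add(str(chrom))
            continue
        for iv in sorted(tree[int(pos)]):
            rows.append({"snp_id": snp_id, "gene_id": iv.data})
    if unknown:
        warnings.warn(
            f"SNPs on chromosomes absent from the annotation skipped: "
            f"{sorted(unknown)}",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["snp_id", "gene_id"]).drop_duplicates()


@dataclass
class SharedGeneSummary:
    """Unique/shared gene tabulation plus the trait-gene network."""

    unique_per_trait: dict[str, int]
    n_unique: int   # genes associated with exactly one trait
    n_shared: int   # genes associated with two or more traits
    edges: pd.DataFrame          # columns trait, gene
    gene_degree: pd.Series       # traits per gene


def shared_gene_summary(mapping: dict[str, set]) -> SharedGeneSummary:
    """Tabulate unique vs shared genes across traits.

    ``mapping`` maps trait name -> set of gene ids.  A gene is *unique*
    when its bipartite degree is 1 (one associated trait) and *shared*
    when the degree is >= 2; unique + shared = total distinct genes.
    """
    if not mapping:
        raise ValidationError("empty trait-gene mapping")
    import networkx as nx

    B = nx.Graph()
    for trait, gene_set in mapping.items():
        B.add_node(("trait", trait))
        for g in gene_set:
            B.add_edge(("trait", trait), ("gene", g))
    degree = {
        node[1]: deg for node, deg in B.degree() if node[0] == "gene"
    }
    gene_degree = pd.Series(degree, dtype=int).sort_index()
    n_unique = int((gene_degree == 1).sum())
    n_shared = int((gene_degree >= 2).sum())
    unique_per_trait = {
        t: sum(1 for g in gs if degree.get(g) == 1) for t, gs in mapping.items()
    }
    edges = pd.DataFrame(
        [(t, g) for t, gs in mapping.items() for g in sorted(gs)],
        columns=["trait", "gene"],
    )
    return SharedGeneSummary(unique_per_trait, n_unique, n_shared, edges,
                             gene_degree)


def hypergeom_enrichment(
    selected, term_to_genes: dict[str, set], universe
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in ``selected``.

    p is the probability of drawing at least the observed overlap when
    sampling |selected| genes without replacement from the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValidationError("selected genes must be a subset of the universe")
    M, n_draw = len(universe), len(selected)
    rows = []
    for term, genes in term_to_genes.items():
        genes = set(genes) & universe
        k = len(genes & selected)
        p = float(stats.hypergeom.sf(k - 1, M, len(genes), n_draw))
        rows.append(
            {"term": term, "overlap": k, "term_size": len(genes),
             "p": min(p, 1.0)}
        )
    return pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"])
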