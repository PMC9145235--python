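"""Simulated genotype matrices with planted QTL.

Dosages are 0/1/2 counts of the minor allele.  Each SNP's minor-allele
count is drawn uniformly from the requested MAF window and distributed at
random over the 2n haplotypes, so the realised MAF always lies inside the
window before missingness is applied.  A quantitative phenotype is built
from the planted QTL with noise scaled so the QTL jointly explain the
requested fraction of phenotypic variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..assoc import GenotypeMatrix
from ..exceptions import ValidationError


@dataclass(frozen=True)
class GenoSimSpec:
    """Scale, allele-frequency window, missingness and planted QTL."""

    n_lines: int = 202
    m_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    qtl: tuple[tuple[int, float], ...] = ()  # (snp index, additive effect)
    h2_marker: float = 0.0  # variance fraction explained by the QTL jointly
    n_chrom: int = 10
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie in (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise ValidationError("missing_rate must lie in [0, 1)")
        if not (0 <= self.h2_marker < 1):
            raise ValidationError("h2_marker must lie in [0, 1)")
        for idx, _ in self.qtl:
            if not (0 <= idx < self.m_snps):
                raise ValidationError(f"qtl index {idx} out of range")


@dataclass
class GenoTruth:
    """Planted QTL, genetic values and achieved marker heritability."""

    qtl: tuple[tuple[int, float], ...]
    genetic_values: np.ndarray
    noise_sd: float
    realized_h2: float


def generate_genotypes(
    spec: GenoSimSpec,
) -> tuple[GenotypeMatrix, np.ndarray, GenoTruth]:
    """Draw a genotype matrix and QTL-driven phenotype.

    Returns (genotypes, phenotype, truth).  The phenotype is computed from
    the complete dosages before missing entries are masked, so the planted
    signal is exact regardless of missingness.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_lines, spec.m_snps
    two_n = 2 * n
    lo_k = math.ceil(two_n * spec.maf_range[0])
    hi_k = math.floor(two_n * spec.maf_range[1])
    if lo_k < 1 or hi_k < lo_k:
        raise ValidationError("maf_range admits no integer allele count")

    k = rng.integers(lo_k, hi_k + 1, size=m)
    # place k[j] minor alleles at random among the 2n haplotypes of SNP j
    u = rng.random((m, two_n))
    ranks = u.argsort(axis=1).argsort(axis=1)
    hap = ranks < k[:, None]
    dosages = hap.reshape(m, n, 2).sum(axis=2).T.astype(float)  # (n, m)

    # phenotype from the full dosages
    qtl_idx = np.array([i for i, _ in spec.qtl], dtype=int)
    effects = np.array([b for _, b in spec.qtl], dtype=float)
    if qtl_idx.size and spec.h2_marker > 0:
        g = dosages[:, qtl_idx] @ effects
        var_g = g.var()
        if var_g <= 0:
            raise ValidationError("planted QTL carry no variance")
        noise_sd = math.sqrt(var_g * (1 - spec.h2_marker) / spec.h2_marker)
        y = g + rng.normal(0.0, noise_sd, n)
        realized = float(var_g / y.var())
    else:
        g = np.zeros(n)
        noise_sd = 1.0
        y = rng.normal(0.0, 1.0, n)
        realized = 0.0

    if spec.missing_rate > 0:
        miss = rng.random((n, m)) < spec.missing_rate
        dosages = dosages.copy()
        dosages[miss] = np.nan

    per_chrom = max(m // spec.n_chrom, 1)
    chrom = np.minimum(np.arange(m) // per_chrom, spec.n_chrom - 1) + 1
    pos = np.zeros(m, dtype=np.int64)
    for c in np.unique(chrom):
        sel = chrom == c
        pos[sel] = 1000 + 1000 * np.arange(sel.sum())

    G = GenotypeMatrix(
        dosages=dosages,
        snp_ids=np.array([f"snp{j:06d}" for j in range(m)]),
        chrom=np.array([str(c) for c in chrom]),
        pos=pos,
        ref=np.full(m, "A"),
        alt=np.full(m, "G"),
        line_ids=np.array([f"L{i:04d}" for i in range(n)]),
    )
    truth = GenoTruth(spec.qtl, g, noise_sd, realized)
    return G, y, truth
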