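"""Readers and writers for the tabular genetics formats.

Genotypes travel either as a minimal VCF (unphased GT field, missing as
``./.``) or as a TSV dosage matrix (lines x SNPs, header row of SNP ids,
``NA`` for missing).  Gene annotations are read from GFF3 gene features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import GeneAnnotation, GenotypeMatrix
from .exceptions import ValidationError

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 with one GT sample column per line."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(str(c) for c in G.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in G.line_ids)
            + "\n"
        )
        for j in range(G.n_snps):
            gts = [
                "./." if np.isnan(d) else _GT_CODE[float(d)]
                for d in G.dosages[:, j]
            ]
            fh.write(
                f"{G.chrom[j]}\t{int(G.pos[j])}\t{G.snp_ids[j]}\t{G.ref[j]}\t"
                f"{G.alt[j]}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read dosages (ALT-allele counts) from a VCF with GT fields."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    line_ids = np.array(vcf.samples)
    snp_ids, chrom, pos, ref, alt, cols = [], [], [], [], [], []
    for var in vcf:
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}_{var.POS}")
        chrom.append(str(var.CHROM))
        pos.append(int(var.POS))
        ref.append(var.REF)
        alt.append(var.ALT[0] if var.ALT else ".")
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = var.gt_types.astype(float)
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], np.nan)
        cols.append(dos)
    vcf.close()
    if not cols:
        raise ValidationError("VCF contains no variants")
    return GenotypeMatrix(
        dosages=np.column_stack(cols),
        snp_ids=np.array(snp_ids),
        chrom=np.array(chrom),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref),
        alt=np.array(alt),
        line_ids=line_ids,
    )


def write_dosage_tsv(G: GenotypeMatrix, path) -> None:
    """Lines x SNPs dosage TSV, header row of SNP ids, NA for missing."""
    df = pd.DataFrame(G.dosages, index=G.line_ids, columns=G.snp_ids)
    df.to_csv(path, sep="\t", na_rep="NA", index_label="line")


def read_dosage_tsv(path, snp_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a dosage TSV; SNP coordinates default to chrom '1', pos 1..m.

    ``snp_meta`` may supply columns snp_id, chrom, pos (and optionally
    ref/alt) to attach real coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    m = df.shape[1]
    ids = np.array(df.columns)
    if snp_meta is not None:
        meta = snp_meta.set_index("snp_id").loc[ids]
        chrom = meta["chrom"].astype(str).to_numpy()
        pos = meta["pos"].to_numpy(np.int64)
        ref = meta.get("ref", pd.Series(["A"] * m, index=ids)).to_numpy()
        alt = meta.get("alt", pd.Series(["G"] * m, index=ids)).to_numpy()
    else:
        chrom = np.array(["1"] * m)
        pos = np.arange(1, m + 1, dtype=np.int64)
        ref = np.full(m, "A")
        alt = np.full(m, "G")
    return GenotypeMatrix(
        dosages=df.to_numpy(float),
        snp_ids=ids,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        line_ids=np.array(df.index.astype(str)),
    )


def read_gff3_genes(path, feature_type: str = "gene") -> list[GeneAnnotation]:
    """Parse gene features (1-based inclusive intervals) from a GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                chrom=str(feat.seqid),
                start=int(feat.start),
                end=int(feat.end),
                strand=feat.strand or "+",
            )
        )
    if not genes:
        raise ValidationError(f"no {feature_type} features found in {path}")
    return genes
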