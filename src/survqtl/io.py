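"""Readers and writers for the on-disk formats the pipeline touches.

Genotypes travel as VCF 4.2 (biallelic records only; GT required, GQ/DP
carried when present).  Expression uses the GTEx-style BED dialect: columns
``#chr  start  end  gene_id`` followed by one column per sample, with the
0-based half-open ``start`` encoding TSS-1 (so TSS = start + 1).  Clinical
and covariate tables are plain TSV.  Every writer round-trips through its
reader on supported content.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    GenotypeMatrix,
    variant_id,
)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_covariates",
    "write_covariates",
]


def read_genotypes(path) -> GenotypeMatrix:
    """Read a biallelic VCF into a :class:`GenotypeMatrix`.

    Dosage is the ALT-allele count of GT; uncalled genotypes become missing
    (NaN).  A multi-allelic record raises with the offending site named.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosages, gqs, dps = [], [], [], []
    has_gq = has_dp = False
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={rec.ALT}); split upstream"
            )
        alt = rec.ALT[0]
        rsid = rec.ID if rec.ID not in (None, ".", "") else None
        rows.append(
            {
                "variant_id": variant_id(rec.CHROM, rec.POS, rec.REF, alt),
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": alt,
                "rsid": rsid,
            }
        )
        dose = np.full(len(samples), np.nan)
        for j, gt in enumerate(rec.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                dose[j] = float(sum(alleles))
        dosages.append(dose)

        for field, store in (("GQ", gqs), ("DP", dps)):
            row = np.full(len(samples), np.nan)
            try:
                vals = rec.format(field)
            except KeyError:
                vals = None
            if vals is not None:
                vals = np.asarray(vals, dtype=float).reshape(len(samples), -1)[:, 0]
                ok = np.isfinite(vals) & (vals >= 0)  # negatives = missing sentinel
                if ok.any():
                    if field == "GQ":
                        has_gq = True
                    else:
                        has_dp = True
                    row[ok] = vals[ok]
            store.append(row)
    vcf.close()

    variants = pd.DataFrame(rows)
    if len(variants):
        variants = variants.set_index("variant_id")
        dosage = np.vstack(dosages)
    else:
        variants = pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "rsid"]
        ).rename_axis("variant_id")
        dosage = np.zeros((0, len(samples)))
    return GenotypeMatrix(
        variants=variants,
        samples=samples,
        dosage=dosage,
        gq=np.vstack(gqs) if has_gq and len(variants) else None,
        dp=np.vstack(dps) if has_dp and len(variants) else None,
    )


def write_genotypes(g: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file."""
    with_gq = g.gq is not None
    with_dp = g.dp is not None
    fmt = "GT" + (":GQ" if with_gq else "") + (":DP" if with_dp else "")
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if with_gq:
        lines.append(
            '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">'
        )
    if with_dp:
        lines.append(
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">'
        )
    for chrom in pd.unique(g.variants["chrom"]):
        lines.append(f"##contig=<ID={chrom}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
    lines.append("\t".join(header[:-1] + ["INFO", "FORMAT"] + list(g.samples)))

    # rows are written in stored order (generators emit coordinate-sorted
    # tables already); reordering here would break read/write identity
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for i in range(g.n_variants):
        row = g.variants.iloc[i]
        fields = [
            str(row["chrom"]),
            str(int(row["pos"])),
            row["rsid"] if isinstance(row.get("rsid"), str) else ".",
            row["ref"],
            row["alt"],
            ".",
            "PASS",
            ".",
            fmt,
        ]
        for j in range(g.n_samples):
            d = g.dosage[i, j]
            cell = gt_map.get(d, "./.")
            if with_gq:
                q = g.gq[i, j]
                cell += ":" + (str(int(q)) if np.isfinite(q) else ".")
            if with_dp:
                dp = g.dp[i, j]
                cell += ":" + (str(int(dp)) if np.isfinite(dp) else ".")
            fields.append(cell)
        lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_expression(path, counts_path=None, gene_info: pd.DataFrame = None) -> ExpressionMatrix:
    """Read a GTEx-dialect expression BED (TPM) into an :class:`ExpressionMatrix`.

    TSS is the 0-based ``start`` column converted to 1-based (start + 1).
    ``counts_path`` optionally supplies a second BED with identical layout
    holding read counts.  ``gene_info`` (indexed by gene_id) may add strand
    and biotype; absent annotation defaults to '+' / 'unknown'.
    """
    tpm_genes, tpm, samples = _read_bed(path)
    counts = None
    if counts_path is not None:
        c_genes, counts, c_samples = _read_bed(counts_path)
        if list(c_genes.index) != list(tpm_genes.index) or c_samples != samples:
            raise ValueError("counts BED does not match TPM BED layout")
    genes = tpm_genes
    genes["strand"] = "+"
    genes["biotype"] = "unknown"
    if gene_info is not None:
        for col in ("strand", "biotype"):
            if col in gene_info.columns:
                genes[col] = gene_info[col].reindex(genes.index).fillna(genes[col])
    return ExpressionMatrix(genes=genes, samples=samples, tpm=tpm, counts=counts)


def _read_bed(path):
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected chrom/start/end/gene_id + samples")
    df.columns = ["chrom", "start", "end", "gene_id"] + list(df.columns[4:])
    samples = list(df.columns[4:])
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id in {path}: {dups[:5]}")
    body = df[samples]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any() and len(df):
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value at row {r + 1} (gene "
            f"{df['gene_id'].iloc[r]}), column {samples[c]}"
        )
    genes = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str).to_numpy(),
            # 0-based BED start -> 1-based TSS
            "tss": df["start"].astype(int).to_numpy() + 1,
        },
        index=pd.Index(df["gene_id"].to_numpy(), name="gene_id"),
    )
    return genes, numeric.to_numpy(dtype=float), samples


def write_expression(e: ExpressionMatrix, path, which: str = "tpm") -> None:
    """Write TPM (or counts) as a GTEx-dialect expression BED."""
    mat = e.tpm if which == "tpm" else e.counts
    if mat is None:
        raise ValueError(f"expression matrix has no {which}")
    out = pd.DataFrame(
        {
            "#chr": e.genes["chrom"].to_numpy(),
            "start": e.genes["tss"].to_numpy() - 1,
            "end": e.genes["tss"].to_numpy(),
            "gene_id": e.genes.index.to_numpy(),
        }
    )
    for j, s in enumerate(e.samples):
        out[s] = mat[:, j]
    out.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ClinicalTable(df)


def write_clinical(c: ClinicalTable, path) -> None:
    c.df.rename_axis("sample_id").to_csv(path, sep="\t")


def read_covariates(path) -> pd.DataFrame:
    """Read a covariate x sample TSV (GTEx dialect) -> samples x covariates."""
    return pd.read_csv(path, sep="\t", index_col=0).T


def write_covariates(cov: pd.DataFrame, path) -> None:
    """Write samples x covariates as a covariate x sample TSV (GTEx dialect)."""
    cov.T.rename_axis("ID").to_csv(path, sep="\t")
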