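"""Readers and writers for the pipeline's on-disk formats.

Tabular formats are plain TSV via pandas; VCF is written through pysam with
GT fields from rounded dosages; gene annotation is exported both as BED
(0-based half-open) and as a 1-based TSS TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import GenotypePanel, ExpressionTruth


def write_dosage_tsv(panel: GenotypePanel, path: str | Path) -> None:
    df = pd.DataFrame(panel.dosages.T,
                      index=panel.variants["snp"],
                      columns=[f"S{i + 1}" for i in
                               range(panel.n_individuals)])
    meta = panel.variants.set_index("snp")
    out = pd.concat([meta, df], axis=1)
    out.to_csv(path, sep="\t", index_label="snp")


def read_dosage_tsv(path: str | Path, block_size: int = 1) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_cols = ["chrom", "pos", "ref", "alt", "maf"]
    variants = df[meta_cols].reset_index().rename(columns={"index": "snp"})
    variants["chrom"] = variants["chrom"].astype(str)
    dos = df.drop(columns=meta_cols).to_numpy(dtype=float).T
    return GenotypePanel(dosages=dos, variants=variants,
                         block_size=block_size)


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as VCF with GT from rounded dosages (alt counts)."""
    import pysam

    header = pysam.VariantHeader()
    chroms = sorted(set(panel.variants["chrom"].astype(str)))
    for c in chroms:
        header.contigs.add(c, length=int(panel.variants["pos"].max()) + 10_000)
    header.formats.add("GT", 1, "String", "Genotype")
    samples = [f"S{i + 1}" for i in range(panel.n_individuals)]
    for s in samples:
        header.add_sample(s)
    g = np.round(panel.dosages).astype(int)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for j, row in panel.variants.iterrows():
            rec = vf.new_record(contig=str(row["chrom"]),
                                start=int(row["pos"]) - 1,
                                stop=int(row["pos"]),
                                alleles=(row["ref"], row["alt"]),
                                id=row["snp"])
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = ((0, 0), (0, 1), (1, 1))[g[i, j]]
            vf.write(rec)


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    """Genes x samples orientation, matching common expression releases."""
    expr.T.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).T


def write_annotation(annot: pd.DataFrame, bed_path: str | Path,
                     tss_path: str | Path) -> None:
    bed = pd.DataFrame({
        "chrom": annot["chrom"],
        "start": annot["start"] - 1,  # to 0-based half-open
        "end": annot["end"],
        "name": annot.index,
        "score": 0,
        "strand": annot["strand"],
    })
    bed.to_csv(bed_path, sep="\t", index=False, header=False)
    annot[["chrom", "tss", "strand"]].to_csv(tss_path, sep="\t",
                                             index_label="gene")


def write_sumstats(sumstats: pd.DataFrame, path: str | Path) -> None:
    sumstats[["SNP", "CHR", "BP", "A1", "A2", "Z", "N"]].to_csv(
        path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["CHR"] = df["CHR"].astype(str)
    if "BETA" not in df:
        df["BETA"] = df["Z"] / np.sqrt(df["N"])
        df["SE"] = 1 / np.sqrt(df["N"])
    return df


def write_truth(truth: ExpressionTruth, path: str | Path) -> None:
    payload = {
        "hub_gene": truth.hub_gene,
        "module_genes": truth.module_genes,
        "loadings": truth.loadings,
        "hub_variant": truth.hub_variant,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
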