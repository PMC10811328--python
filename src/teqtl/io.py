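"""Readers and writers for the pipeline's on-disk formats.

Phenotypes travel as QTLtools-style BED (0-based half-open intervals,
one column per sample after the six annotation columns); genotypes as a
dosage TSV (variants x patients, with chrom/pos/maf columns) or minimal
VCF; peaks as plain BED; everything else as TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CohortDesign, PhenotypeTable, TruthTable, VariantSet

__all__ = [
    "write_phenotype_bed",
    "read_phenotype_bed",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_vcf",
    "read_vcf",
    "read_peaks_bed",
    "write_design",
    "read_design",
    "write_truth",
    "read_truth",
]


def write_phenotype_bed(table: PhenotypeTable, path) -> None:
    """QTLtools-style phenotype BED: #chr start end id info strand samples..."""
    feats = table.features
    out = pd.DataFrame(
        {
            "#chr": feats["chrom"],
            "start": feats["start"],
            "end": feats["end"],
            "id": feats.index,
            "info": feats["feature_class"],
            "strand": feats["strand"],
        }
    )
    vals = table.values.T  # features x samples
    out = pd.concat([out.reset_index(drop=True), vals.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_phenotype_bed(path, stage: str = "counts") -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"#chr": str})
    meta = df[["#chr", "start", "end", "id", "info", "strand"]]
    features = pd.DataFrame(
        {
            "chrom": meta["#chr"].to_numpy(),
            "start": meta["start"].to_numpy(),
            "end": meta["end"].to_numpy(),
            "strand": meta["strand"].to_numpy(),
            "feature_class": meta["info"].to_numpy(),
        },
        index=pd.Index(meta["id"], name="feature_id"),
    )
    values = df.drop(columns=["#chr", "start", "end", "id", "info", "strand"]).T
    values.columns = features.index
    values.index.name = "sample_id"
    return PhenotypeTable(features, values, stage=stage)


def write_dosage_tsv(variants: VariantSet, path) -> None:
    """Variants x patients dosage matrix prefixed by chrom/pos/maf columns."""
    meta = variants.variants.copy()
    out = pd.concat([meta, variants.dosages.T], axis=1)
    out.index.name = "variant_id"
    out.to_csv(path, sep="\t")


def read_dosage_tsv(path) -> VariantSet:
    df = pd.read_csv(path, sep="\t", index_col="variant_id", dtype={"chrom": str})
    meta = df[["chrom", "pos", "maf"]]
    dosages = df.drop(columns=["chrom", "pos", "maf"]).T
    dosages.index.name = "patient_id"
    dosages.columns = dosages.columns.rename(None)  # plain ids, as constructed
    return VariantSet(meta, dosages)


def write_vcf(variants: VariantSet, path) -> None:
    """Minimal unphased VCF 4.2 with GT calls derived from integer dosages."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    patients = list(variants.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(patients) + "\n")
        for vid, row in variants.variants.iterrows():
            dos = variants.dosages[vid].round().astype(int).clip(0, 2)
            calls = "\t".join(gt_map[int(d)] for d in dos)
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path) -> VariantSet:
    """Read a VCF into a VariantSet (dosage = alternate-allele count)."""
    from cyvcf2 import VCF  # heavier import, only needed for VCF input

    vcf = VCF(str(path))
    patients = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    for rec in vcf:
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        gts = np.array(rec.genotypes)[:, :2]
        rows.append(np.where(gts < 0, np.nan, gts).sum(axis=1))
    dosage = np.array(rows).T
    f = np.nanmean(dosage, axis=0) / 2.0
    meta = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "maf": np.minimum(f, 1 - f)},
        index=pd.Index(ids, name="variant_id"),
    )
    dosages = pd.DataFrame(dosage, index=pd.Index(patients, name="patient_id"), columns=ids)
    return VariantSet(meta, dosages)


def read_peaks_bed(path) -> pd.DataFrame:
    """Plain BED3(+) peak file -> frame with chrom/start/end (half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    return df[["chrom", "start", "end"]]


def write_design(design: CohortDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_design(path) -> CohortDesign:
    return CohortDesign(pd.read_csv(path, sep="\t"))


def write_truth(truth: TruthTable, path_effects, path_triplets) -> None:
    truth.effects.to_csv(path_effects, sep="\t", index=False)
    truth.triplets.to_csv(path_triplets, sep="\t", index=False)


def read_truth(path_effects, path_triplets) -> TruthTable:
    return TruthTable(
        effects=pd.read_csv(path_effects, sep="\t"),
        triplets=pd.read_csv(path_triplets, sep="\t"),
    )
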