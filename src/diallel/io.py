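"""Reading and writing founder panels and phenotype tables.

Founder genotypes round-trip through VCF (one sample per founder, GT fields
0/0, 1/1, 0/1 or ./.) and through PLINK PED/MAP in the "recode12" dialect
(alleles written as 1 = reference, 2 = alternate, 0 = missing).  Replicate
and phenotype tables are plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .design import HET, HOM_ALT, HOM_REF, MISSING, FounderPanel

_GT_TO_CODE = {"0/0": HOM_REF, "1/1": HOM_ALT, "0/1": HET, "1/0": HET, "./.": MISSING}
_CODE_TO_GT = {HOM_REF: "0/0", HOM_ALT: "1/1", HET: "0/1", MISSING: "./."}


def write_vcf(panel: FounderPanel, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if "maf_source" in panel.sites.columns:
            fh.write(
                '##INFO=<ID=SMAF,Number=1,Type=Float,'
                'Description="Minor allele frequency in source population">\n'
            )
        for chrom in pd.unique(panel.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.parent_ids)
            + "\n"
        )
        has_smaf = "maf_source" in panel.sites.columns
        for j, site in panel.sites.iterrows():
            info = f"SMAF={site['maf_source']:.6g}" if has_smaf else "."
            gts = "\t".join(_CODE_TO_GT[int(c)] for c in panel.genotypes[:, j])
            fh.write(
                f"{site['chrom']}\t{site['pos']}\t{site['chrom']}:{site['pos']}\t"
                f"{site['ref']}\t{site['alt']}\t.\t.\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path) -> FounderPanel:
    """Read a founder VCF via cyvcf2 (biallelic SNPs, GT only)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    parent_ids = list(vcf.samples)
    rows, columns = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        smaf = variant.INFO.get("SMAF")
        rows.append((variant.CHROM, variant.POS, variant.REF, variant.ALT[0], smaf))
        # gt_types: 0=hom_ref, 1=het, 2=unknown, 3=hom_alt
        codes = np.array(
            [
                {0: HOM_REF, 1: HET, 3: HOM_ALT}.get(t, MISSING)
                for t in variant.gt_types
            ],
            dtype=np.int8,
        )
        columns.append(codes)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "maf_source"])
    if sites["maf_source"].isna().all():
        sites = sites.drop(columns=["maf_source"])
    genotypes = np.column_stack(columns) if columns else np.empty((len(parent_ids), 0), np.int8)
    return FounderPanel(parent_ids, sites, genotypes)


def write_ped_map(panel: FounderPanel, prefix) -> None:
    """Write PLINK PED/MAP with alleles recoded 1 (ref) / 2 (alt)."""
    prefix = Path(prefix)
    allele_pairs = {HOM_REF: "1 1", HOM_ALT: "2 2", HET: "1 2", MISSING: "0 0"}
    with prefix.with_suffix(".ped").open("w") as fh:
        for i, pid in enumerate(panel.parent_ids):
            geno = " ".join(allele_pairs[int(c)] for c in panel.genotypes[i])
            fh.write(f"{pid} {pid} 0 0 0 -9 {geno}\n")
    with prefix.with_suffix(".map").open("w") as fh:
        for _, site in panel.sites.iterrows():
            fh.write(f"{site['chrom']}\t{site['chrom']}:{site['pos']}\t0\t{site['pos']}\n")


def read_ped_map(prefix) -> FounderPanel:
    """Read a recode12 PED/MAP pair back into a founder panel.

    Allele symbols 1/2 map to ref/alt; chromosome and position come from
    the MAP file, ref/alt bases are not recoverable and are written as the
    placeholder alleles A/C.
    """
    prefix = Path(prefix)
    map_rows = []
    with prefix.with_suffix(".map").open() as fh:
        for line in fh:
            chrom, _sid, _cm, pos = line.split()
            map_rows.append((chrom, int(pos), "A", "C"))
    sites = pd.DataFrame(map_rows, columns=["chrom", "pos", "ref", "alt"])
    parent_ids, rows = [], []
    pair_to_code = {("1", "1"): HOM_REF, ("2", "2"): HOM_ALT, ("1", "2"): HET,
                    ("2", "1"): HET, ("0", "0"): MISSING}
    with prefix.with_suffix(".ped").open() as fh:
        for line in fh:
            fields = line.split()
            parent_ids.append(fields[1])
            alleles = fields[6:]
            if len(alleles) != 2 * len(sites):
                raise ValueError("PED genotype count does not match MAP sites")
            codes = [
                pair_to_code[(alleles[2 * j], alleles[2 * j + 1])]
                for j in range(len(sites))
            ]
            rows.append(codes)
    return FounderPanel(parent_ids, sites, np.array(rows, dtype=np.int8))


def write_replicates_tsv(replicates: pd.DataFrame, path) -> None:
    replicates.to_csv(path, sep="\t", index=False)


def read_replicates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
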