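"""File interchange: VCF v4.2 (haploid GT:DP:GQ:AD), annotation/sample TSVs, BED.

The writer emits deterministic text so identical inputs give byte-identical
files; reading goes through cyvcf2 for the VCF and pandas for the tables.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .cohort import GenotypeMatrix
from .errors import SchemaError, StructuralError

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "pop_maf", "male_maf",
    "pop_call_rate", "pass_flag", "n_alleles", "span_nt",
]
SAMPLE_COLUMNS = ["sample_id", "phenotype", "age", "stratum"]

_VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=chrX,length=156040895>
##FILTER=<ID=FAIL,Description="Non-PASS in the reference annotation">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
"""


def write_vcf(path, sites: pd.DataFrame, gm: GenotypeMatrix) -> None:
    if gm.n_sites != len(sites):
        raise StructuralError("site table and genotype matrix disagree on site count")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        if gm.sample_ids:
            fh.write("\tFORMAT")
            for s in gm.sample_ids:
                fh.write("\t" + s)
        fh.write("\n")
        ac, dp, gq, rr, ar = gm.allele_count, gm.depth, gm.gq, gm.ref_reads, gm.alt_reads
        for i, (_, row) in enumerate(sites.iterrows()):
            cells = [
                str(row["chrom"]), str(int(row["pos"])), ".", str(row["ref"]), str(row["alt"]),
                ".", "PASS" if row.get("pass_flag", True) else "FAIL", ".",
            ]
            if gm.sample_ids:
                cells.append("GT:DP:GQ:AD")
            for j in range(gm.n_samples):
                a = ac[i, j]
                gt = "." if a < 0 else str(int(a))
                cells.append(f"{gt}:{dp[i, j]}:{gq[i, j]}:{rr[i, j]},{ar[i, j]}")
            fh.write("\t".join(cells) + "\n")


def read_vcf(path) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Read a haploid VCF into a minimal site frame and a GenotypeMatrix."""
    v = VCF(str(path))
    sample_ids = list(v.samples)
    recs, ac_rows, dp_rows, gq_rows, rr_rows, ar_rows = [], [], [], [], [], []
    for var in v:
        if not var.ALT:
            raise SchemaError(f"{path}: record at {var.CHROM}:{var.POS} has no ALT allele")
        recs.append({"chrom": var.CHROM, "pos": var.POS, "ref": var.REF, "alt": var.ALT[0]})
        gts = np.array([g[0] for g in var.genotypes], dtype=np.int8)
        ac_rows.append(gts)
        if sample_ids:
            dp = np.asarray(var.format("DP")).reshape(-1)
            gq = np.asarray(var.format("GQ")).reshape(-1)
            ad = np.asarray(var.format("AD")).reshape(len(sample_ids), -1)
        else:
            dp = gq = np.zeros(0)
            ad = np.zeros((0, 2))
        dp_rows.append(np.where(dp < 0, 0, dp))
        gq_rows.append(np.where(gq < 0, 0, gq))
        rr_rows.append(np.where(ad[:, 0] < 0, 0, ad[:, 0]))
        ar_rows.append(np.where(ad[:, 1] < 0, 0, ad[:, 1]))
    sites = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt"])
    n = len(recs)
    shape = (n, len(sample_ids))
    gm = GenotypeMatrix(
        sample_ids,
        pd.Index(range(n)),
        np.array(ac_rows, dtype=np.int8).reshape(shape),
        np.array(dp_rows, dtype=np.int32).reshape(shape),
        np.array(gq_rows, dtype=np.int16).reshape(shape),
        np.array(rr_rows, dtype=np.int32).reshape(shape),
        np.array(ar_rows, dtype=np.int32).reshape(shape),
    )
    return sites, gm


def write_annotation(path, sites: pd.DataFrame) -> None:
    df = sites.copy()
    df["pass_flag"] = df["pass_flag"].astype(bool)
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: annotation is missing columns {missing}")
    df["pass_flag"] = df["pass_flag"].astype(bool)
    return df


def write_sample_sheet(path, samples: pd.DataFrame) -> None:
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: sample sheet is missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate sample_id {dup!r}")
    return df


def write_bed(path, intervals: pd.DataFrame) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end"], usecols=[0, 1, 2])
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    if (df["end"] < df["start"]).any():
        raise SchemaError(f"{path}: BED interval with end < start")
    return df


def decoy_bed_from_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """One 1-bp interval per in_decoy site (0-based half-open)."""
    dec = sites.loc[sites["in_decoy"].astype(bool)]
    return pd.DataFrame(
        {"chrom": dec["chrom"], "start": dec["pos"] - 1, "end": dec["pos"]}
    ).reset_index(drop=True)


def write_cohort(out_dir, samples: pd.DataFrame, sites: pd.DataFrame, gm: GenotypeMatrix) -> dict:
    """Emit the four pipeline inputs; returns the path set."""
    if list(gm.sample_ids) != list(samples["sample_id"]):
        raise StructuralError("genotype matrix samples do not match the sample sheet")
    out = Path(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "annotation": out / "annotation.tsv",
        "samples": out / "samples.tsv",
        "decoy_bed": out / "decoy.bed",
    }
    write_vcf(paths["vcf"], sites, gm)
    write_annotation(paths["annotation"], sites)
    write_sample_sheet(paths["samples"], samples)
    write_bed(paths["decoy_bed"], decoy_bed_from_sites(sites))
    return {k: str(v) for k, v in paths.items()}


def read_cohort(paths: dict) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeMatrix, pd.DataFrame]:
    """Read the file set back; annotation and VCF are joined positionally.

    Returns (samples, sites-with-annotation, genotypes, decoy_bed).  The
    in_decoy flag is recomputed from the BED.
    """
    samples = read_sample_sheet(paths["samples"])
    ann = read_annotation(paths["annotation"])
    vcf_sites, gm = read_vcf(paths["vcf"])
    if len(ann) != len(vcf_sites):
        raise StructuralError("annotation and VCF record counts differ")
    key_a = ann[["chrom", "pos", "ref", "alt"]].astype({"pos": int})
    key_v = vcf_sites.astype({"pos": int})
    if not key_a.reset_index(drop=True).equals(key_v.reset_index(drop=True)):
        raise StructuralError("annotation rows do not match VCF records")
    if list(gm.sample_ids) != list(samples["sample_id"]):
        raise StructuralError("VCF samples do not match the sample sheet")
    bed = read_bed(paths["decoy_bed"]) if paths.get("decoy_bed") else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    from .qc import mark_in_decoy

    sites = ann.copy()
    sites["in_decoy"] = False
    sites = mark_in_decoy(sites, bed)
    gm.site_index = pd.Index(sites.index)
    return samples, sites, gm, bed
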