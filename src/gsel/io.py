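"""Readers and writers for the standard interchange formats.

VCF reading goes through :mod:`cyvcf2`; the VCF writer emits plain-text
v4.2 with GT-only records (``./.`` for missing) and no date stamp so that
identical runs produce identical bytes. PLINK .bed/.bim/.fam uses the
SNP-major .bed dialect (no maintained pure-Python writer is available in
the target environment, so the 2-bit codec is implemented here).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, PhenotypeTable

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_plink",
    "read_plink",
    "write_phenotypes",
    "read_phenotypes",
    "write_grm_csv",
    "write_grm_gcta",
    "write_toy_gff3",
]

_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit PLINK codes indexed by alt dosage; 0b01 is the missing code
_DOSAGE_TO_CODE = {0.0: 0b11, 1.0: 0b10, 2.0: 0b00}
_CODE_TO_DOSAGE = {0b11: 0.0, 0b10: 1.0, 0b00: 2.0, 0b01: np.nan}


def write_vcf(genotypes: GenotypeMatrix, path) -> Path:
    """Write a minimal VCF v4.2 with GT fields (``./.`` for missing).

    Fractional (imputed) dosages cannot be represented; round-trips are
    exact only for integer dosage matrices.
    """
    path = Path(path)
    dos = genotypes.dosages
    if np.nanmax(np.abs(dos - np.round(dos)), initial=0.0) > 0:
        raise ValueError("VCF GT output requires integer dosages")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(genotypes.snp_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        cols = "\t".join(str(i) for i in genotypes.ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j, row in genotypes.snp_map.iterrows():
            gts = [
                "./." if np.isnan(d) else gt_map[int(d)] for d in dos[:, j]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.chrom}_{row.pos}\t{row.ref}\t"
                f"{row.alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into alt-allele dosages."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples)
    rows, dosages = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types.astype(np.float64)
        d = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        dosages.append(d)
    vcf.close()
    snp_map = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(
        dosages=np.array(dosages).T if dosages else np.empty((len(ids), 0)),
        snp_map=snp_map,
        ids=ids,
    )


def write_plink(genotypes: GenotypeMatrix, prefix) -> tuple[Path, Path, Path]:
    """Write SNP-major .bed plus .bim/.fam. A1 is the alt allele, so the
    stored genotype code counts alt copies."""
    prefix = Path(prefix)
    dos = genotypes.dosages
    n, m = dos.shape
    if np.nanmax(np.abs(dos - np.round(dos)), initial=0.0) > 0:
        raise ValueError("PLINK output requires integer dosages")

    bed_path = prefix.with_suffix(".bed")
    n_bytes = (n + 3) // 4
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = bytearray(n_bytes)
        for j in range(m):
            for b in range(n_bytes):
                buf[b] = 0
            for i in range(n):
                d = dos[i, j]
                code = 0b01 if np.isnan(d) else _DOSAGE_TO_CODE[float(d)]
                buf[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(buf))

    bim_path = prefix.with_suffix(".bim")
    bim = pd.DataFrame(
        {
            "chrom": genotypes.snp_map["chrom"].str.replace("chr", "", regex=False),
            "id": [
                f"{c}_{p}"
                for c, p in zip(genotypes.snp_map["chrom"], genotypes.snp_map["pos"])
            ],
            "cm": 0,
            "pos": genotypes.snp_map["pos"],
            "a1": genotypes.snp_map["alt"],
            "a2": genotypes.snp_map["ref"],
        }
    )
    bim.to_csv(bim_path, sep="\t", header=False, index=False)

    fam_path = prefix.with_suffix(".fam")
    fam = pd.DataFrame(
        {
            "fid": genotypes.ids,
            "iid": genotypes.ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(fam_path, sep=" ", header=False, index=False)
    return bed_path, bim_path, fam_path


def read_plink(prefix) -> GenotypeMatrix:
    """Read a SNP-major PLINK .bed/.bim/.fam triplet."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK .bed file")
    n_bytes = (n + 3) // 4
    dos = np.empty((n, m), dtype=np.float64)
    body = raw[3:]
    for j in range(m):
        chunk = body[j * n_bytes : (j + 1) * n_bytes]
        for i in range(n):
            code = (chunk[i // 4] >> (2 * (i % 4))) & 0b11
            dos[i, j] = _CODE_TO_DOSAGE[code]
    chrom = [c if c.startswith("chr") else f"chr{c}" for c in bim["chrom"]]
    snp_map = pd.DataFrame(
        {"chrom": chrom, "pos": bim["pos"], "ref": bim["a2"], "alt": bim["a1"]}
    )
    return GenotypeMatrix(dosages=dos, snp_map=snp_map, ids=fam["iid"].to_numpy())


def write_phenotypes(pheno: PhenotypeTable, path) -> Path:
    path = Path(path)
    pheno.to_frame().to_csv(path, index=False)
    return path


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable.from_frame(pd.read_csv(path))


def write_grm_csv(grm, path) -> Path:
    path = Path(path)
    grm.to_frame().to_csv(path)
    return path


def write_grm_gcta(grm, prefix) -> tuple[Path, Path]:
    """GCTA-style text pair: ``.grm.id`` (ids) and ``.grm`` rows
    ``i j n_snps value`` over the lower triangle (1-based)."""
    prefix = Path(prefix)
    ids = grm.ids if grm.ids is not None else np.arange(grm.n)
    id_path = prefix.with_suffix(".grm.id")
    with open(id_path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\t{i}\n")
    grm_path = prefix.with_suffix(".grm")
    m = len(grm.allele_freqs)
    with open(grm_path, "w") as fh:
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{m}\t{grm.matrix[i, j]:.10g}\n")
    return grm_path, id_path


def write_toy_gff3(
    genes: pd.DataFrame, path, source: str = "gsel"
) -> Path:
    """Write gene features (1-based inclusive) from a frame with columns
    ``chrom, start, end, gene``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for k, row in genes.reset_index(drop=True).iterrows():
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{int(row.start)}\t{int(row.end)}\t.\t+\t.\t"
                f"ID=gene{k};Name={row.gene}\n"
            )
    return path
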