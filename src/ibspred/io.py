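"""Readers and writers for the package's external formats.

Phased genotypes go out as VCF (GT with '|' phase separators) and PLINK
PED/MAP text; pedigrees as CSV; run configurations as YAML; observed /
unobserved splits as two-column TSV of SNP ids; matrices as square or
long-format TSV; ROH segments in a PLINK .hom-like TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .markers import MarkerMap
from .simulate import PhasedPopulation

# synthetic biallelic loci use fixed REF/ALT nucleotides
REF_ALLELE, ALT_ALLELE = "A", "C"


def snp_names(marker_map: MarkerMap) -> list[str]:
    return [f"snp{c}_{p}" for c, p in zip(marker_map.chrom, marker_map.pos_bp)]


# -- VCF -------------------------------------------------------------------

def write_vcf(pop: PhasedPopulation, path) -> None:
    """Minimal phased VCF 4.2 for a simulated cohort."""
    m = pop.map
    names = snp_names(m)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in m.chromosomes:
            last = m.pos_bp[m.chrom == c].max()
            fh.write(f"##contig=<ID={c},length={last + 1}>\n")
        samples = "\t".join(f"ind{i}" for i in pop.ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        h0 = pop.haps[:, 0, :]
        h1 = pop.haps[:, 1, :]
        for j in range(m.n_loci):
            gts = "\t".join(f"{a}|{b}" for a, b in zip(h0[:, j], h1[:, j]))
            fh.write(f"{m.chrom[j]}\t{m.pos_bp[j]}\t{names[j]}\t"
                     f"{REF_ALLELE}\t{ALT_ALLELE}\t.\t.\t.\tGT\t{gts}\n")


def read_vcf(path):
    """Read a VCF into (genotypes, haplotypes-or-None, missing mask,
    MarkerMap, sample names). Haplotypes are returned only when every
    genotype is phased; missing calls are masked and coded 0."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos = [], []
    genos, phased_rows = [], []
    for var in vcf:
        chrom.append(int(var.CHROM))
        pos.append(var.POS)
        gt = np.array(var.genotype.array())  # (n, 3): allele0, allele1, phased
        genos.append(gt[:, :2])
        phased_rows.append(gt[:, 2].astype(bool))
    gt3 = np.stack(genos, axis=2)  # (n, 2, m) with -1 for missing
    missing = (gt3 < 0).any(axis=1)  # (n, m)
    haps = np.clip(gt3, 0, 1).astype(np.uint8)
    genotypes = haps.sum(axis=1).astype(np.uint8)
    genotypes[missing] = 0
    all_phased = bool(np.all(np.stack(phased_rows)))
    m = len(chrom)
    marker_map = MarkerMap(np.array(chrom), np.array(pos),
                           np.array(pos, dtype=float) / 1e8,
                           np.zeros(m, dtype=bool))
    return genotypes, (haps if all_phased else None), missing, marker_map, samples


# -- PLINK PED/MAP ---------------------------------------------------------

def write_ped_map(pop: PhasedPopulation, prefix) -> None:
    """PLINK text PED/MAP; alleles coded 1 (ref) / 2 (alt), phase kept by
    writing haplotype 0 then haplotype 1 per locus."""
    m = pop.map
    with open(f"{prefix}.map", "w") as fh:
        for c, name, g, p in zip(m.chrom, snp_names(m), m.gen_pos * 100, m.pos_bp):
            fh.write(f"{c}\t{name}\t{g:.6f}\t{p}\n")
    with open(f"{prefix}.ped", "w") as fh:
        for i in range(pop.n):
            sex_code = 1 if pop.sex[i] == 0 else 2
            fields = [str(pop.ids[i]), str(pop.ids[i]), str(pop.sire[i]),
                      str(pop.dam[i]), str(sex_code), "-9"]
            alleles = np.empty(2 * pop.map.n_loci, dtype=np.int64)
            alleles[0::2] = pop.haps[i, 0] + 1
            alleles[1::2] = pop.haps[i, 1] + 1
            fh.write(" ".join(fields) + " " + " ".join(map(str, alleles)) + "\n")


def read_ped_map(prefix):
    """Read PLINK text files back into (genotypes, haplotypes, MarkerMap,
    ids). Allele 1 maps to code 0, allele 2 to code 1."""
    mp = pd.read_csv(f"{prefix}.map", sep="\t", header=None,
                     names=["chrom", "name", "cm", "bp"])
    marker_map = MarkerMap(mp["chrom"].to_numpy(), mp["bp"].to_numpy(),
                           mp["cm"].to_numpy() / 100.0,
                           np.zeros(len(mp), dtype=bool))
    ids, haps = [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            ids.append(int(parts[1]))
            alleles = np.array(parts[6:], dtype=np.int64) - 1
            haps.append(np.stack([alleles[0::2], alleles[1::2]]))
    haps = np.array(haps, dtype=np.uint8)
    return haps.sum(axis=1).astype(np.uint8), haps, marker_map, np.array(ids)


# -- tables ----------------------------------------------------------------

def write_pedigree_csv(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, index=False)


def read_pedigree_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_split_tsv(split, marker_map: MarkerMap, path) -> None:
    """Two-column TSV (snp_id, set) over the SNP-only map."""
    snp_only = marker_map.subset(~marker_map.is_qtl)
    names = np.array(snp_names(snp_only))
    rows = pd.concat([
        pd.DataFrame({"snp_id": names[split.observed], "set": "observed"}),
        pd.DataFrame({"snp_id": names[split.unobserved], "set": "unobserved"}),
    ])
    rows.to_csv(path, sep="\t", index=False)


def write_square_tsv(ids, M: np.ndarray, path) -> None:
    pd.DataFrame(M, index=ids, columns=ids).to_csv(path, sep="\t")


def write_long_tsv(ids, M: np.ndarray, path) -> None:
    iu, ju = np.triu_indices(len(ids), k=0)
    pd.DataFrame({"id1": np.asarray(ids)[iu], "id2": np.asarray(ids)[ju],
                  "value": M[iu, ju]}).to_csv(path, sep="\t", index=False)


def write_roh_tsv(segs, ids, path) -> None:
    """PLINK .hom-like table: IID, CHR, POS1, POS2, KB, NSNP."""
    df = segs.segments.copy()
    df["IID"] = np.asarray(ids)[df["indiv"].to_numpy()]
    df["KB"] = (df["end_bp"] - df["start_bp"]) / 1000.0
    df = df.rename(columns={"chrom": "CHR", "start_bp": "POS1",
                            "end_bp": "POS2", "n_snp": "NSNP"})
    df[["IID", "CHR", "POS1", "POS2", "KB", "NSNP"]].to_csv(
        path, sep="\t", index=False)
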