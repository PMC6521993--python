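"""Readers and writers for the pipeline's file formats.

Phased VCF 4.2 is the interchange format for haplotypes, tab-separated
tables for phenotypes and variant genotype matrices, JSON for simulation
truth. VCF parsing uses cyvcf2; writing emits minimal spec-conformant text.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import COMPONENTS, GenotypePanel, HaplotypePanel


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a phased VCF 4.2 with '|'-separated GT and contig headers."""
    path = Path(path)
    chrom_lengths = panel.markers.groupby("chrom", sort=False)["pos"].max()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=uasmap\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples)
            + "\n"
        )
        alleles = panel.alleles
        for j, row in panel.markers.iterrows():
            gts = "\t".join(
                f"{alleles[i, 0, j]}|{alleles[i, 1, j]}" for i in range(panel.n_samples)
            )
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path: str | Path) -> HaplotypePanel:
    """Read a phased VCF into a HaplotypePanel (multi-allelic sites rejected)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    hap_cols = []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ValueError(f"multi-allelic record at {rec.CHROM}:{rec.POS}; split first")
        gts = np.array(rec.genotypes)  # (n, 3): a0, a1, phased flag
        if not gts[:, 2].all():
            raise ValueError(f"unphased genotype at {rec.CHROM}:{rec.POS}")
        if (gts[:, :2] < 0).any():
            raise ValueError(f"missing genotype in phased VCF at {rec.CHROM}:{rec.POS}")
        hap_cols.append(gts[:, :2])
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}_{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
    markers = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    alleles = np.stack(hap_cols, axis=2)  # (n, 2, m)
    return HaplotypePanel(alleles, markers, samples)


def read_vcf_genotypes(path: str | Path) -> GenotypePanel:
    """Read a VCF (phased or not) into dosages; multi-allelic sites are split."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    for rec in vcf:
        gts = np.array(rec.genotypes)[:, :2]
        for k, alt in enumerate(rec.ALT, start=1):
            dos = np.where((gts < 0).any(axis=1), np.nan, (gts == k).sum(axis=1))
            rid = rec.ID if rec.ID else f"{rec.CHROM}_{rec.POS}"
            if len(rec.ALT) > 1:
                rid = f"{rid}_{alt}"
            rows.append((rid, rec.CHROM, rec.POS, rec.REF, alt))
            dosage_cols.append(dos.astype(float))
    markers = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    return GenotypePanel(np.column_stack(dosage_cols), markers, samples)


PHENOTYPE_COLUMNS = ["dog_id", "sex", "age_months", "weight_kg"] + COMPONENTS


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=PHENOTYPE_COLUMNS)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    return table


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def interval_to_bed(chrom: str, start_1based: int, end_1based: int) -> str:
    """1-based inclusive interval -> one BED line (0-based half-open)."""
    return f"{chrom}\t{start_1based - 1}\t{end_1based}\n"
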