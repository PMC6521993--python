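"""Shared fixtures: small programmatically generated panels, phenotype
tables and gene-model files."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from uasmap.containers import COMPONENTS, GenotypePanel, HaplotypePanel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def marker_table(n: int, chrom: str = "chr13", start: int = 1000, step: int = 100) -> pd.DataFrame:
    pos = start + step * np.arange(n)
    return pd.DataFrame(
        {
            "id": [f"m{i}" for i in range(n)],
            "chrom": chrom,
            "pos": pos,
            "ref": ["A"] * n,
            "alt": ["G"] * n,
        }
    )


def hap_panel(alleles: np.ndarray, **kwargs) -> HaplotypePanel:
    """HaplotypePanel from an (n_dogs, 2, m) array with generated metadata."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n, _, m = alleles.shape
    return HaplotypePanel(
        alleles, marker_table(m, **kwargs), [f"dog{i:03d}" for i in range(n)]
    )


def geno_panel(dosages: np.ndarray, **kwargs) -> GenotypePanel:
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypePanel(dosages, marker_table(m, **kwargs), [f"dog{i:03d}" for i in range(n)])


def pheno_table(grades: dict[str, list[int]] | np.ndarray, **extra) -> pd.DataFrame:
    """Phenotype table from per-component grade lists or an (n, 10) array."""
    if isinstance(grades, np.ndarray):
        grades = {c: grades[:, k].tolist() for k, c in enumerate(COMPONENTS)}
    n = len(next(iter(grades.values())))
    base = {
        "dog_id": [f"dog{i:03d}" for i in range(n)],
        "sex": ["F"] * n,
        "age_months": [24] * n,
        "weight_kg": [5.0] * n,
    }
    base.update({c: grades.get(c, [1] * n) for c in COMPONENTS})
    base.update(extra)
    return pd.DataFrame(base)


@pytest.fixture(scope="session")
def small_cohort():
    """One 150-dog simulated cohort shared by read-only tests."""
    from uasmap.synth import simulate_cohort

    return simulate_cohort(n_dogs=150, n_markers=400, seed=7)


TOY_GFF = """\
##gff-version 3
{chrom}\ttoy\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\tID={gene_id}
{features}
"""


def write_gene_files(tmp_path, cds_seq: str, exon_specs, chrom="chr13", strand="+",
                     gene_id="toygene", utr_exons=()):
    """Write a toy GFF3 + CDS FASTA. ``exon_specs`` are genomic (start, end)
    CDS intervals in 5'->3' order; ``utr_exons`` extra non-coding exons."""
    all_exons = sorted(list(exon_specs) + list(utr_exons))
    gene_start = min(s for s, _ in all_exons)
    gene_end = max(e for _, e in all_exons)
    lines = []
    for s, e in all_exons:
        lines.append(f"{chrom}\ttoy\texon\t{s}\t{e}\t.\t{strand}\t.\tParent={gene_id}")
    for s, e in sorted(exon_specs):
        lines.append(f"{chrom}\ttoy\tCDS\t{s}\t{e}\t.\t{strand}\t0\tParent={gene_id}")
    gff = tmp_path / "toy.gff3"
    gff.write_text(
        TOY_GFF.format(
            chrom=chrom,
            gene_start=gene_start,
            gene_end=gene_end,
            strand=strand,
            gene_id=gene_id,
            features="\n".join(lines),
        )
    )
    fasta = tmp_path / "toy_cds.fasta"
    fasta.write_text(f">{gene_id}_cds\n{cds_seq}\n")
    return gff, fasta
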