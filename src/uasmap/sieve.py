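"""Candidate-variant filtering and coding-consequence annotation.

Variants called inside the critical interval are sieved by allelic
segregation against the risk-haplotype carrier status of the resequenced
dogs, grouped by complete LD, classified against a gene model, and — for
the resulting protein change — checked for residue invariance across a
cross-species protein alignment (the in-repo stand-in for external
pathogenicity predictors).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .containers import CriticalInterval

# genotype codes in a VariantTable
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1


@dataclass
class VariantTable:
    """Bi-allelic variant calls: metadata plus per-sample genotype codes
    (0 hom-ref, 1 het, 2 hom-alt, -1 missing)."""

    variants: pd.DataFrame  # columns: id, chrom, pos, ref, alt
    genotypes: np.ndarray  # (n_variants, n_samples)
    samples: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        if self.genotypes.shape != (len(self.variants), len(self.samples)):
            raise ValueError("genotype matrix shape mismatch")
        if not np.isin(self.genotypes, [HOM_REF, HET, HOM_ALT, MISSING]).all():
            raise ValueError("genotype codes must be 0/1/2/-1")
        if (self.variants["ref"] == self.variants["alt"]).any():
            raise ValueError("ref and alt alleles must differ")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, mask: np.ndarray) -> "VariantTable":
        mask = np.asarray(mask)
        return VariantTable(
            self.variants[mask].reset_index(drop=True),
            self.genotypes[mask],
            list(self.samples),
        )


@dataclass
class CarrierStatus:
    """Risk-haplotype carrier and affection flags for the resequenced dogs."""

    table: pd.DataFrame  # columns: sample, carrier (bool), affected (bool)

    def __post_init__(self) -> None:
        need = {"sample", "carrier", "affected"}
        if not need <= set(self.table.columns):
            raise ValueError(f"carrier table needs columns {sorted(need)}")

    def carriers(self) -> list[str]:
        return self.table.loc[self.table["carrier"], "sample"].tolist()

    def non_carriers(self) -> list[str]:
        return self.table.loc[~self.table["carrier"], "sample"].tolist()

    def affected(self) -> list[str]:
        return self.table.loc[self.table["affected"], "sample"].tolist()


def restrict_to_interval(
    table: VariantTable, interval: CriticalInterval | tuple[str, int, int]
) -> VariantTable:
    """Keep variants with 1-based position inside [start, end] inclusive."""
    if isinstance(interval, CriticalInterval):
        chrom, lo, hi = interval.chrom, interval.left, interval.right
    else:
        chrom, lo, hi = interval
    v = table.variants
    mask = ((v["chrom"] == chrom) & (v["pos"] >= lo) & (v["pos"] <= hi)).to_numpy()
    return table.subset(mask)


def segregation_filter(
    table: VariantTable, carriers: CarrierStatus, scheme: str
) -> tuple[VariantTable, int]:
    """Filter by allelic segregation with the risk haplotype.

    Sites with any missing call are dropped first (only positions called in
    every dog are considered). Scheme ``exclusive-to-affected`` keeps
    variants homozygous-alternate in the affected carrier(s) and not
    homozygous-alternate in every other dog; scheme ``haplotype-concordant``
    keeps variants homozygous-alternate in all risk-haplotype carriers and
    homozygous-reference in all non-carriers. Returns the filtered table and
    the number of sites dropped for missingness.
    """
    if not carriers.carriers():
        raise ValueError("carrier set is empty")
    sample_idx = {s: i for i, s in enumerate(table.samples)}
    unknown = [s for s in carriers.table["sample"] if s not in sample_idx]
    if unknown:
        raise ValueError(f"carrier-status samples not in variant table: {unknown}")
    complete = (table.genotypes != MISSING).all(axis=1)
    n_dropped = int((~complete).sum())
    work = table.subset(complete)
    g = work.genotypes

    if scheme == "exclusive-to-affected":
        aff = [sample_idx[s] for s in carriers.affected()]
        if not aff:
            raise ValueError("scheme exclusive-to-affected needs >=1 affected dog")
        others = [i for i in range(len(table.samples)) if i not in aff]
        keep = (g[:, aff] == HOM_ALT).all(axis=1)
        if others:
            keep &= (g[:, others] != HOM_ALT).all(axis=1)
    elif scheme == "haplotype-concordant":
        car = [sample_idx[s] for s in carriers.carriers()]
        non = [sample_idx[s] for s in carriers.non_carriers()]
        keep = (g[:, car] == HOM_ALT).all(axis=1)
        if non:
            keep &= (g[:, non] == HOM_REF).all(axis=1)
    else:
        raise ValueError(
            "scheme must be 'exclusive-to-affected' or 'haplotype-concordant'"
        )
    return work.subset(keep), n_dropped


COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class GeneModel:
    """One gene's exon structure and CDS for consequence calls.

    Exons and CDS intervals are 1-based inclusive genomic coordinates,
    ordered 5'->3' (descending genomic position on the minus strand).
    ``cds_seq`` is the spliced coding sequence on the coding strand.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_intervals: list[tuple[int, int]]
    cds_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if len(self.cds_seq) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        total = sum(e - s + 1 for s, e in self.cds_intervals)
        if total != len(self.cds_seq):
            raise ValueError(
                f"CDS intervals span {total} bp but sequence is {len(self.cds_seq)} bp"
            )
        genomic_sorted = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 <= e1:
                raise ValueError("exons must not overlap")

    @property
    def span(self) -> tuple[int, int]:
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    def genomic_to_cds(self, pos: int) -> int | None:
        """1-based CDS coordinate of a genomic position, None if non-coding."""
        offset = 0
        for s, e in self.cds_intervals:
            if s <= pos <= e:
                if self.strand == "+":
                    return offset + (pos - s) + 1
                return offset + (e - pos) + 1
            offset += e - s + 1
        return None

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)


def gene_model_from_gff3(
    gff_path: str, cds_fasta_path: str, gene_id: str | None = None
) -> GeneModel:
    """Build a GeneModel from a GFF3 gene annotation and its CDS FASTA."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = list(db.features_of_type("gene"))
    if gene_id is not None:
        genes = [g for g in genes if g.id == gene_id]
    if len(genes) != 1:
        raise ValueError(f"expected exactly one gene, found {len(genes)}")
    gene = genes[0]
    exons = [(f.start, f.end) for f in db.children(gene, featuretype="exon")]
    cds = [(f.start, f.end) for f in db.children(gene, featuretype="CDS")]
    reverse = gene.strand == "-"
    exons = sorted(exons, reverse=reverse)
    cds = sorted(cds, reverse=reverse)
    records = list(SeqIO.parse(str(cds_fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError("CDS FASTA must contain exactly one record")
    return GeneModel(
        gene_id=gene.id,
        chrom=gene.seqid,
        strand=gene.strand,
        exons=exons,
        cds_intervals=cds,
        cds_seq=str(records[0].seq).upper(),
    )


@dataclass
class Consequence:
    category: str  # intergenic/intronic/exonic-noncoding/synonymous/missense/
    #                nonsense/exonic-indel/intronic-indel/intergenic-indel
    cds_pos: int | None = None
    codon_number: int | None = None
    cds_notation: str | None = None
    protein_notation: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None


def classify_consequence(
    chrom: str, pos: int, ref: str, alt: str, model: GeneModel
) -> Consequence:
    """Locate a variant against the gene model and, for coding SNVs, derive
    the codon change with c./p. notation (three-letter amino acid codes)."""
    if chrom != model.chrom:
        return Consequence("intergenic")
    lo, hi = model.span
    is_snv = len(ref) == 1 and len(alt) == 1
    if not lo <= pos <= hi:
        return Consequence("intergenic" if is_snv else "intergenic-indel")
    in_exon = model.in_exon(pos)
    if not is_snv:
        return Consequence("exonic-indel" if in_exon else "intronic-indel")
    if not in_exon:
        return Consequence("intronic")
    cds_pos = model.genomic_to_cds(pos)
    if cds_pos is None:
        return Consequence("exonic-noncoding")

    # orient alleles to the coding strand
    ref_c = ref if model.strand == "+" else ref.translate(COMPLEMENT)
    alt_c = alt if model.strand == "+" else alt.translate(COMPLEMENT)
    if model.cds_seq[cds_pos - 1] != ref_c:
        raise ValueError(
            f"reference allele {ref!r} at {chrom}:{pos} disagrees with CDS base "
            f"{model.cds_seq[cds_pos - 1]!r} at c.{cds_pos}"
        )
    codon_number = math.ceil(cds_pos / 3)
    codon_start = (codon_number - 1) * 3
    ref_codon = model.cds_seq[codon_start : codon_start + 3]
    within = (cds_pos - 1) % 3
    alt_codon = ref_codon[:within] + alt_c + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        category = "synonymous"  # includes stop-retained changes
    elif alt_aa == "*":
        category = "nonsense"
    else:
        category = "missense"
    ref3 = "Ter" if ref_aa == "*" else seq3(ref_aa)
    alt3 = "Ter" if alt_aa == "*" else seq3(alt_aa)
    return Consequence(
        category=category,
        cds_pos=cds_pos,
        codon_number=codon_number,
        cds_notation=f"c.{cds_pos}{ref_c}>{alt_c}",
        protein_notation=f"p.({ref3}{codon_number}{alt3})",
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


def annotate_variants(table: VariantTable, model: GeneModel) -> pd.DataFrame:
    """Consequence annotation for every variant in the table."""
    rows = []
    for v in table.variants.itertuples():
        c = classify_consequence(v.chrom, int(v.pos), v.ref, v.alt, model)
        rows.append(
            (
                v.id,
                v.chrom,
                int(v.pos),
                v.ref,
                v.alt,
                c.category,
                c.cds_notation,
                c.protein_notation,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "pos", "ref", "alt", "consequence", "cds", "protein"],
    )


def complete_ld_groups(table: VariantTable) -> list[list[int]]:
    """Partition variants into maximal groups in complete LD (pairwise
    r^2 = 1): dosage vectors identical or exact affine flips of each other.
    Variants with missing calls or zero variance form singleton groups."""
    g = table.genotypes.astype(float)
    g[g == MISSING] = np.nan
    m = table.n_variants
    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    ok = ~np.isnan(g).any(axis=1)
    sd = np.nanstd(g, axis=1)
    for i in range(m):
        if not ok[i] or sd[i] == 0:
            continue
        for j in range(i + 1, m):
            if not ok[j] or sd[j] == 0:
                continue
            r = np.corrcoef(g[i], g[j])[0, 1]
            if abs(abs(r) - 1.0) < 1e-12:
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda grp: grp[0])


@dataclass
class InvarianceResult:
    is_invariant: bool
    residues: set[str]
    per_sequence: dict[str, str]
    n_gaps: int
    all_gap: bool = False


def residue_invariance(msa, column: int) -> InvarianceResult:
    """Check cross-species invariance of one alignment column (1-based).

    ``msa`` is a Bio.Align.MultipleSeqAlignment or a path to an aligned
    FASTA. Invariant means exactly one distinct non-gap residue; an all-gap
    column is flagged rather than reported invariant.
    """
    if isinstance(msa, (str,)) or hasattr(msa, "__fspath__"):
        msa = AlignIO.read(str(msa), "fasta")
    length = msa.get_alignment_length()
    if not 1 <= column <= length:
        raise ValueError(f"column {column} outside alignment length {length}")
    per_seq = {rec.id: str(rec.seq[column - 1]).upper() for rec in msa}
    residues = {r for r in per_seq.values() if r not in "-."}
    n_gaps = sum(1 for r in per_seq.values() if r in "-.")
    all_gap = len(residues) == 0
    return InvarianceResult(
        is_invariant=(len(residues) == 1),
        residues=residues,
        per_sequence=per_seq,
        n_gaps=n_gaps,
        all_gap=all_gap,
    )


def variant_table_from_genotypes(
    dosages: np.ndarray, markers: pd.DataFrame, samples: list[str]
) -> VariantTable:
    """Recast a dosage matrix (samples x markers) as a VariantTable
    (variants x samples) for segregation filtering."""
    g = dosages.T.copy()
    g = np.where(np.isnan(g), MISSING, g).astype(int)
    return VariantTable(markers[["id", "chrom", "pos", "ref", "alt"]].copy(), g, list(samples))
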