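"""Variant sieving: interval restriction, the two segregation schemes,
consequence classification against a toy gene model, complete-LD grouping
and alignment-column invariance."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uasmap.sieve import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    CarrierStatus,
    VariantTable,
    classify_consequence,
    complete_ld_groups,
    gene_model_from_gff3,
    residue_invariance,
    restrict_to_interval,
    segregation_filter,
)

from conftest import write_gene_files


def make_table(genos: np.ndarray, positions=None, chrom="chr13") -> VariantTable:
    genos = np.asarray(genos, dtype=int)
    n_var, n_samp = genos.shape
    positions = positions if positions is not None else 100 + 10 * np.arange(n_var)
    variants = pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(n_var)],
            "chrom": chrom,
            "pos": positions,
            "ref": "G",
            "alt": "A",
        }
    )
    return VariantTable(variants, genos, [f"s{i}" for i in range(n_samp)])


QUARTET = CarrierStatus(
    pd.DataFrame(
        {
            "sample": ["s0", "s1", "s2", "s3"],
            "carrier": [True, True, False, False],
            "affected": [True, False, False, False],
        }
    )
)


class TestRestrict:
    def test_inclusive_boundaries_and_count(self):
        pos = [50, 100, 150, 200, 250, 300, 350]
        table = make_table(np.zeros((7, 2)), positions=pos)
        kept = restrict_to_interval(table, ("chr13", 100, 300))
        assert kept.n_variants == 5
        assert kept.variants["pos"].min() == 100
        one_left = restrict_to_interval(table, ("chr13", 101, 300))
        assert 100 not in one_left.variants["pos"].tolist()

    def test_hand_counted_subset(self):
        pos = [10, 20, 30, 40, 50, 60, 70]
        table = make_table(np.zeros((7, 3)), positions=pos)
        kept = restrict_to_interval(table, ("chr13", 25, 55))
        assert kept.n_variants == 3  # 30, 40, 50

    def test_idempotent_and_contractive(self):
        pos = [10, 20, 30, 40]
        table = make_table(np.zeros((4, 2)), positions=pos)
        once = restrict_to_interval(table, ("chr13", 15, 35))
        twice = restrict_to_interval(once, ("chr13", 15, 35))
        assert once.variants.equals(twice.variants)
        assert set(once.variants["id"]) <= set(table.variants["id"])


class TestSegregation:
    def test_truth_table_of_the_two_schemes(self):
        # hom-alt in both carriers, hom-ref in both non-carriers:
        # retained by the haplotype-concordant scheme, dropped by the
        # exclusive-to-affected scheme (the unaffected carrier shares it)
        table = make_table([[HOM_ALT, HOM_ALT, HOM_REF, HOM_REF]])
        b, _ = segregation_filter(table, QUARTET, "haplotype-concordant")
        a, _ = segregation_filter(table, QUARTET, "exclusive-to-affected")
        assert b.n_variants == 1
        assert a.n_variants == 0

    def test_exclusive_scheme_dead_end_when_variant_shared(self):
        # every causal-candidate variant shared by the unaffected carrier:
        # scheme A returns nothing, as in the original filtering attempt
        genos = np.array(
            [
                [HOM_ALT, HOM_ALT, HOM_REF, HOM_REF],
                [HOM_ALT, HOM_ALT, HET, HOM_REF],
            ]
        )
        a, _ = segregation_filter(make_table(genos), QUARTET, "exclusive-to-affected")
        assert a.n_variants == 0

    def test_exclusive_scheme_keeps_private_homozygote(self):
        table = make_table([[HOM_ALT, HET, HOM_REF, HOM_REF]])
        a, _ = segregation_filter(table, QUARTET, "exclusive-to-affected")
        b, _ = segregation_filter(table, QUARTET, "haplotype-concordant")
        assert a.n_variants == 1  # hom-alt only in the affected dog
        assert b.n_variants == 0  # not hom-alt in ALL carriers

    def test_het_in_one_carrier_dropped_by_both(self):
        table = make_table([[HOM_ALT, HET, HOM_REF, HOM_REF]])
        for scheme in ("haplotype-concordant",):
            kept, _ = segregation_filter(table, QUARTET, scheme)
            assert kept.n_variants == 0
        # and a het in the affected dog fails the exclusive scheme too
        table2 = make_table([[HET, HOM_ALT, HOM_REF, HOM_REF]])
        a, _ = segregation_filter(table2, QUARTET, "exclusive-to-affected")
        assert a.n_variants == 0

    def test_sites_with_missing_calls_dropped_first(self):
        genos = np.array(
            [
                [HOM_ALT, HOM_ALT, MISSING, HOM_REF],
                [HOM_ALT, HOM_ALT, HOM_REF, HOM_REF],
            ]
        )
        kept, n_dropped = segregation_filter(
            make_table(genos), QUARTET, "haplotype-concordant"
        )
        assert n_dropped == 1
        assert kept.variants["id"].tolist() == ["v1"]

    def test_empty_carrier_set_rejected(self):
        status = CarrierStatus(
            pd.DataFrame(
                {"sample": ["s0", "s1"], "carrier": [False, False], "affected": [False, False]}
            )
        )
        with pytest.raises(ValueError, match="empty"):
            segregation_filter(make_table(np.zeros((1, 2))), status, "haplotype-concordant")

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_filters_contractive_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        genos = rng.choice([HOM_REF, HET, HOM_ALT, MISSING], size=(12, 4))
        table = make_table(genos)
        for scheme in ("haplotype-concordant", "exclusive-to-affected"):
            once, _ = segregation_filter(table, QUARTET, scheme)
            twice, _ = segregation_filter(once, QUARTET, scheme)
            assert set(once.variants["id"]) <= set(table.variants["id"])
            assert once.variants["id"].tolist() == twice.variants["id"].tolist()


def _codon_929_gene(tmp_path):
    """Single-exon toy gene whose CDS has codon 929 = CGC so the G at
    c.2786 sits at the codon's second position."""
    rng = np.random.default_rng(99)
    codons = ["CTT"] * 930  # Leu codons, no internal stops
    codons[928] = "CGC"  # codon 929 (1-based) = Arg
    codons[929] = "TAA"  # terminal stop
    cds = "".join(codons)
    start = 5000
    gff, fasta = write_gene_files(tmp_path, cds, [(start, start + len(cds) - 1)])
    return gene_model_from_gff3(gff, fasta), start


class TestConsequence:
    def test_published_missense_notation(self, tmp_path):
        model, start = _codon_929_gene(tmp_path)
        pos = start + 2786 - 1  # genomic position of c.2786 on a + strand gene
        c = classify_consequence("chr13", pos, "G", "A", model)
        assert c.category == "missense"
        assert c.codon_number == 929
        assert c.cds_notation == "c.2786G>A"
        assert c.protein_notation == "p.(Arg929His)"

    def test_third_position_synonymous(self, tmp_path):
        model, start = _codon_929_gene(tmp_path)
        pos = start + 2  # third base of codon 1 = CTT -> CTC, still Leu
        c = classify_consequence("chr13", pos, "T", "C", model)
        assert c.category == "synonymous"
        assert c.protein_notation == "p.(Leu1Leu)"

    def test_intronic_and_intergenic(self, tmp_path):
        cds = "ATGCGCTAA"
        gff, fasta = write_gene_files(tmp_path, cds, [(100, 105), (200, 202)])
        model = gene_model_from_gff3(gff, fasta)
        assert classify_consequence("chr13", 150, "G", "A", model).category == "intronic"
        assert classify_consequence("chr13", 50, "G", "A", model).category == "intergenic"
        assert classify_consequence("chr1", 101, "G", "A", model).category == "intergenic"

    def test_indels_classified_without_protein_notation(self, tmp_path):
        cds = "ATGCGCTAA"
        gff, fasta = write_gene_files(tmp_path, cds, [(100, 105), (200, 202)])
        model = gene_model_from_gff3(gff, fasta)
        c = classify_consequence("chr13", 102, "GA", "G", model)
        assert c.category == "exonic-indel"
        assert c.protein_notation is None
        assert classify_consequence("chr13", 150, "G", "GT", model).category == "intronic-indel"

    def test_reference_mismatch_is_error(self, tmp_path):
        model, start = _codon_929_gene(tmp_path)
        with pytest.raises(ValueError, match="disagrees"):
            classify_consequence("chr13", start + 2786 - 1, "T", "A", model)

    def test_minus_strand_mapping(self, tmp_path):
        # CDS ATG GCA TAA on the minus strand: genomic segment is the
        # reverse complement, so genomic end maps to c.1
        cds = "ATGGCATAA"
        from Bio.Seq import Seq

        genomic = str(Seq(cds).reverse_complement())
        gff, fasta = write_gene_files(
            tmp_path, cds, [(300, 300 + 8)], strand="-"
        )
        model = gene_model_from_gff3(gff, fasta)
        assert model.genomic_to_cds(308) == 1
        # c.5 (codon 2 pos 2: GCA -> GAA, Ala -> Glu): genomic base is the
        # complement of C, at genomic position 308 - 4
        c = classify_consequence("chr13", 304, "G", "T", model)
        assert c.cds_notation == "c.5C>A"
        assert c.category == "missense"
        assert c.protein_notation == "p.(Ala2Glu)"

    def test_nonsense(self, tmp_path):
        # Trp codon TGG at codon 6 (c.16-18): G>A at c.17 gives the TAG stop
        cds = "ATGCGTTTACCAGGTTGGAGCAAGCTTCACTAA"
        start = 1000
        gff, fasta = write_gene_files(tmp_path, cds, [(start, start + len(cds) - 1)])
        model = gene_model_from_gff3(gff, fasta)
        c = classify_consequence("chr13", start + 16, "G", "A", model)
        assert c.category == "nonsense"
        assert c.protein_notation == "p.(Trp6Ter)"

    def test_round_trip_against_full_translation_oracle(self, tmp_path):
        # every possible CDS SNV in a short gene: mutate the CDS string,
        # translate both proteins with Biopython and compare categories
        from Bio.Seq import Seq

        cds = "ATGCGTTTACCAGGTTGGAGCAAGCTTCAC" + "TAA"
        start = 1000
        gff, fasta = write_gene_files(tmp_path, cds, [(start, start + len(cds) - 1)])
        model = gene_model_from_gff3(gff, fasta)
        prot_ref = str(Seq(cds).translate())
        for cds_pos in range(1, len(cds) + 1):
            ref = cds[cds_pos - 1]
            for alt in "ACGT".replace(ref, ""):
                mutated = cds[: cds_pos - 1] + alt + cds[cds_pos:]
                prot_alt = str(Seq(mutated).translate())
                codon_i = (cds_pos - 1) // 3
                expected = (
                    "synonymous"
                    if prot_alt == prot_ref
                    else ("nonsense" if prot_alt[codon_i] == "*" else "missense")
                )
                c = classify_consequence("chr13", start + cds_pos - 1, ref, alt, model)
                assert c.category == expected, (cds_pos, ref, alt)
                assert c.codon_number == codon_i + 1


class TestCompleteLD:
    def test_identical_flipped_and_hand_grouping(self):
        base = np.array([HOM_REF, HET, HOM_ALT, HOM_REF, HET])
        genos = np.array(
            [
                base,
                base,  # identical -> same group
                2 - base,  # allele-flipped -> same group
                [HOM_REF, HOM_REF, HOM_ALT, HET, HOM_ALT],
                [HOM_ALT, HOM_ALT, HOM_ALT, HOM_REF, HOM_REF],
            ]
        )
        groups = complete_ld_groups(make_table(genos))
        sizes = sorted(len(g) for g in groups)
        assert sizes == [1, 1, 3]
        assert [0, 1, 2] in groups

    def test_zero_variance_isolated(self):
        genos = np.array([[HET, HET, HET, HET], [HOM_REF, HET, HOM_ALT, HET]])
        groups = complete_ld_groups(make_table(genos))
        assert sorted(len(g) for g in groups) == [1, 1]


class TestResidueInvariance:
    def _write_msa(self, tmp_path, rows):
        path = tmp_path / "msa.fasta"
        path.write_text("".join(f">seq{i}\n{s}\n" for i, s in enumerate(rows)))
        return path

    def test_invariant_column(self, tmp_path):
        msa = self._write_msa(tmp_path, ["ARND"] * 10)
        res = residue_invariance(msa, 2)
        assert res.is_invariant and res.residues == {"R"}

    def test_substituted_column_not_invariant(self, tmp_path):
        msa = self._write_msa(tmp_path, ["ARND"] * 9 + ["AHND"])
        res = residue_invariance(msa, 2)
        assert not res.is_invariant
        assert res.residues == {"R", "H"}

    def test_gaps_tolerated_and_counted(self, tmp_path):
        msa = self._write_msa(tmp_path, ["ARND"] * 4 + ["A-ND", "A-ND"])
        res = residue_invariance(msa, 2)
        assert res.is_invariant and res.n_gaps == 2

    def test_all_gap_column_flagged(self, tmp_path):
        msa = self._write_msa(tmp_path, ["A-ND"] * 3)
        res = residue_invariance(msa, 2)
        assert res.all_gap and not res.is_invariant

    def test_out_of_bounds_column(self, tmp_path):
        msa = self._write_msa(tmp_path, ["ARND"] * 3)
        with pytest.raises(ValueError, match="outside"):
            residue_invariance(msa, 9)
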