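"""End-to-end pipeline driver: simulate -> score -> GWAS -> fine-map ->
sieve -> report, with every intermediate parameter and artefact logged in a
single structured report."""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import finemap, gwas, io, phenotypes, report, sieve, synth


@dataclass
class PipelineConfig:
    """Study conditions for a synthetic end-to-end run.

    Defaults mirror the cohort structure the analysis assumes: ~300 dogs,
    one chromosome of 1000 markers, one crossover per chromosome copy per
    meiosis of founder mosaic, risk-allele frequency 0.57, causal effect
    2.0 liability SD per allele copy and a 0.3 polygenic share.
    """

    n_dogs: int = 300
    n_markers: int = 1000
    n_founders: int = 30
    recomb_rate: float = 1.0
    target_risk_af: float = 0.57
    beta: float = 2.0
    h2_polygenic: float = 0.3
    maf_min: float = 0.05
    sample_missing_max: float = 0.1
    min_recomb: int = 3
    severe_component: str = "laryngeal_saccule"
    severe_grade: int = 4
    alpha: float = 0.05
    weights: dict | None = None  # total-score weights; None = unit

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def select_resequencing_panel(
    cohort: synth.SimulatedCohort,
    consensus: finemap.ConsensusHaplotype,
    rank: list[str],
    classes: dict[str, str],
    severe: list[str],
    index_marker: str,
) -> tuple[list[str], sieve.CarrierStatus]:
    """Pick the whole-genome-resequencing quartet the study design calls for.

    Two risk-haplotype homozygotes — the most severely ranked one (the
    affected carrier) and the least severely ranked one (standing in for the
    seemingly unaffected carrier) — plus the two least severe dogs carrying
    no copy of the risk haplotype. Non-carriers are additionally required to
    lack the consensus allele on both chromosomes at the index marker, so
    the quartet cleanly separates the two haplotype backgrounds.
    """
    hap = cohort.haplotypes
    ids = hap.markers["id"].tolist()
    index_idx = ids.index(index_marker)
    cons_at_index = consensus.alleles[
        int(np.searchsorted(consensus.marker_idx, index_idx))
    ]
    hom_risk = [d for d in rank if classes[d] == "homozygous-risk"]
    if not hom_risk:
        raise ValueError("no risk-haplotype homozygote available for resequencing")
    carriers = [hom_risk[0]]
    if len(hom_risk) > 1:
        carriers.append(hom_risk[-1])

    def clean_non_carrier(dog: str) -> bool:
        i = hap.samples.index(dog)
        return classes[dog] == "non-carrier" and all(
            hap.alleles[i, c, index_idx] != cons_at_index for c in (0, 1)
        )

    non_carriers = [d for d in reversed(rank) if clean_non_carrier(d)][:2]
    if not non_carriers:
        raise ValueError("no non-carrier dog available for resequencing")
    reseq = carriers + non_carriers
    severe_set = set(severe)
    status = sieve.CarrierStatus(
        pd.DataFrame(
            {
                "sample": reseq,
                "carrier": [d in set(carriers) for d in reseq],
                "affected": [d in severe_set for d in reseq],
            }
        )
    )
    return reseq, status


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_all(
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the whole analysis on one simulated cohort; returns the report.

    With ``out_dir`` set, writes the phased VCF, phenotype TSV, truth JSON,
    association TSV, interval BED, consensus TSV and the report JSON.
    """
    config = config or PipelineConfig()
    rpt: dict = {"seed": int(seed), "config": asdict(config), "stages": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - aborting with stage context
                raise StageError(name, exc) from exc

        return deco

    cohort = stage("simulate")(
        lambda: synth.simulate_cohort(
            n_dogs=config.n_dogs,
            n_markers=config.n_markers,
            n_founders=config.n_founders,
            recomb_rate=config.recomb_rate,
            target_risk_af=config.target_risk_af,
            model=None
            if (config.beta, config.h2_polygenic) == (2.0, 0.3)
            else synth.DiseaseModel(
                causal_marker_index=config.n_markers // 2,
                beta=config.beta,
                h2_polygenic=config.h2_polygenic,
                causal_allele_freq=config.target_risk_af,
            ),
            seed=seed,
        )
    )
    rpt["stages"]["simulate"] = {
        "n_dogs": cohort.genotypes.n_samples,
        "n_markers": cohort.genotypes.n_markers,
        "realised_causal_af": float(
            cohort.genotypes.allele_freq()[cohort.truth["causal_marker_index"]]
        ),
        "truth_causal_marker": cohort.truth["causal_marker_id"],
    }

    def _score():
        total = phenotypes.total_airway_score(cohort.phenotypes, config.weights)
        order = phenotypes.severity_rank(cohort.phenotypes, weights=config.weights)
        severe = phenotypes.severe_dogs(
            cohort.phenotypes, config.severe_component, config.severe_grade
        )
        severe = [d for d in order.rank if d in set(severe)]  # severity-ordered
        return total, order, severe

    total_score, order, severe = stage("score")(_score)
    rpt["stages"]["score"] = {
        "n_severe": len(severe),
        "mean_total_score": float(total_score.mean()),
    }

    def _gwas():
        panel, qc = gwas.qc_filter(
            cohort.genotypes, config.maf_min, config.sample_missing_max
        )
        kin = gwas.kinship(panel)
        covs = np.column_stack(
            [
                cohort.phenotypes["age_months"].to_numpy(float),
                (cohort.phenotypes["sex"] == "M").to_numpy(float),
            ]
        )
        res = gwas.lmm_scan(panel, total_score.to_numpy(), covs, kin)
        p_thr, mlog_thr = gwas.bonferroni_threshold(panel.n_markers, config.alpha)
        return panel, qc, res, p_thr, mlog_thr

    panel, qc, assoc, p_thr, mlog_thr = stage("gwas")(_gwas)
    top = assoc.top_marker()
    rpt["stages"]["gwas"] = {
        "n_markers_tested": panel.n_markers,
        "qc": qc.summary(),
        "bonferroni_minus_log10": mlog_thr,
        "index_marker": str(top["id"]),
        "index_minus_log10_p": float(top["minus_log10_p"]),
        "n_significant": int(len(assoc.significant(mlog_thr))),
    }

    def _finemap():
        interval, consensus = finemap.critical_interval(
            cohort.haplotypes, severe, str(top["id"]), min_recomb=config.min_recomb
        )
        return interval, consensus

    interval, consensus = stage("finemap")(_finemap)
    rpt["stages"]["finemap"] = {
        "chrom": interval.chrom,
        "left": interval.left,
        "right": interval.right,
        "length_bp": interval.length,
        "bounded": bool(interval.left_bounded and interval.right_bounded),
        "consensus_support": f"{consensus.support}/{consensus.total}",
        "contains_truth_causal": bool(interval.contains(cohort.truth["causal_pos"])),
    }

    def _sieve():
        classes = {
            d: finemap.diplotype_class(cohort.haplotypes, consensus, d)
            for d in cohort.genotypes.samples
        }
        reseq, carriers = select_resequencing_panel(
            cohort, consensus, order.rank, classes, severe, str(top["id"])
        )
        sub = cohort.genotypes.subset(
            sample_idx=[cohort.genotypes.samples.index(d) for d in reseq]
        )
        vt = sieve.variant_table_from_genotypes(sub.dosages, sub.markers, sub.samples)
        inside = sieve.restrict_to_interval(vt, interval)
        kept, n_dropped = sieve.segregation_filter(
            inside, carriers, "haplotype-concordant"
        )
        return reseq, inside, kept, n_dropped, classes

    reseq, inside, kept, n_dropped, classes = stage("sieve")(_sieve)
    rpt["stages"]["sieve"] = {
        "resequenced_dogs": reseq,
        "n_in_interval": inside.n_variants,
        "n_dropped_missing": n_dropped,
        "n_pass_scheme_b": kept.n_variants,
        "causal_retained": cohort.truth["causal_marker_id"]
        in set(kept.variants["id"]),
    }

    def _report():
        geno = [classes[d] for d in cohort.genotypes.samples]
        counts = report.GenotypeCounts(
            geno.count("homozygous-risk"),
            geno.count("heterozygous"),
            geno.count("non-carrier"),
        )
        scores = total_score.to_numpy()
        by = {
            g: scores[[x == g for x in geno]]
            for g in ("homozygous-risk", "heterozygous", "non-carrier")
        }
        tests = {}
        for a, b in (
            ("homozygous-risk", "heterozygous"),
            ("homozygous-risk", "non-carrier"),
            ("heterozygous", "non-carrier"),
        ):
            if len(by[a]) and len(by[b]):
                tests[f"{a}_vs_{b}"] = report.genotype_score_test(by[a], by[b])
        overall = [
            phenotypes.overall_grade(s) for s in scores
        ]
        decisions = [report.breeding_classifier(o) for o in overall]
        table = report.genotype_by_decision_table(geno, decisions)
        return counts, tests, table

    counts, tests, decision_table = stage("report")(_report)
    rpt["stages"]["report"] = {
        "risk_allele_freq": report.allele_frequency(counts),
        "genotype_percent": report.genotype_percentages(counts),
        "score_tests_p": tests,
        "decision_table": decision_table.to_dict(orient="records"),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_phased_vcf(cohort.haplotypes, out / "cohort.vcf")
        io.write_phenotypes(cohort.phenotypes, out / "phenotypes.tsv")
        io.write_truth(cohort.truth, out / "truth.json")
        assoc.table.to_csv(out / "association.tsv", sep="\t", index=False)
        with open(out / "critical_interval.bed", "w") as fh:
            fh.write(io.interval_to_bed(interval.chrom, interval.left, interval.right))
        pd.DataFrame(
            {
                "marker_id": cohort.genotypes.markers.loc[
                    consensus.marker_idx, "id"
                ].to_numpy(),
                "allele": consensus.alleles,
            }
        ).to_csv(out / "consensus_haplotype.tsv", sep="\t", index=False)
        rpt["artefacts"] = sorted(p.name for p in out.iterdir())
        with open(out / "report.json", "w") as fh:
            json.dump(rpt, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return rpt
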