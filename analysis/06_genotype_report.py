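#!/usr/bin/env python
"""Genotype-phenotype report: diplotype frequencies, rank-sum comparisons
of the total airway score between genotype classes, and the breeding-
guideline decision table. Writes results/report/."""
import json
from pathlib import Path

import pandas as pd

from uasmap import io, plots
from uasmap.finemap import critical_interval, diplotype_class
from uasmap.phenotypes import overall_grade, severe_dogs, severity_rank, total_airway_score
from uasmap.report import (
    GenotypeCounts,
    allele_frequency,
    breeding_classifier,
    genotype_by_decision_table,
    genotype_percentages,
    genotype_score_test,
)

COHORT = Path("results/cohort")
GWAS = Path("results/gwas")
OUT = Path("results/report")


def main() -> None:
    panel = io.read_phased_vcf(COHORT / "cohort.vcf")
    table = io.read_phenotypes(COHORT / "phenotypes.tsv")
    assoc = pd.read_csv(GWAS / "association.tsv", sep="\t")
    index_marker = str(assoc.loc[assoc["minus_log10_p"].idxmax(), "id"])
    OUT.mkdir(parents=True, exist_ok=True)

    order = severity_rank(table)
    severe_ordered = [d for d in order.rank if d in set(severe_dogs(table))]
    _, consensus = critical_interval(panel, severe_ordered, index_marker)
    classes = [diplotype_class(panel, consensus, d) for d in panel.samples]

    counts = GenotypeCounts(
        classes.count("homozygous-risk"),
        classes.count("heterozygous"),
        classes.count("non-carrier"),
    )
    scores = total_airway_score(table).to_numpy()
    by = {g: scores[[c == g for c in classes]] for g in set(classes)}
    tests = {}
    for a, b in (
        ("homozygous-risk", "heterozygous"),
        ("homozygous-risk", "non-carrier"),
        ("heterozygous", "non-carrier"),
    ):
        if len(by.get(a, [])) and len(by.get(b, [])):
            tests[f"{a}_vs_{b}"] = genotype_score_test(by[a], by[b])

    decisions = [breeding_classifier(overall_grade(s)) for s in scores]
    decision_table = genotype_by_decision_table(classes, decisions)
    decision_table.to_csv(OUT / "decision_table.tsv", sep="\t", index=False)
    plots.score_by_genotype(scores, classes, OUT / "score_by_genotype.png")

    report = {
        "risk_haplotype_frequency": allele_frequency(counts),
        "genotype_percent": genotype_percentages(counts),
        "rank_sum_p": tests,
        "n_prohibited": decisions.count("prohibited"),
    }
    (OUT / "report.json").write_text(json.dumps(report, indent=2) + "\n")

    print(f"risk haplotype frequency {report['risk_haplotype_frequency']} "
          f"(genotype % {report['genotype_percent']})")
    for k, v in tests.items():
        print(f"rank-sum {k}: p = {v:.3g}")
    print(f"{decisions.count('prohibited')} of {len(decisions)} dogs prohibited from breeding")


if __name__ == "__main__":
    main()
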