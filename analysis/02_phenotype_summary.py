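#!/usr/bin/env python
"""Summarise the ten ordinal airway components: grade distributions, total
airway scores, the component correlation matrix with its dendrogram order,
and the severity ranking used downstream by the fine-mapper."""
from pathlib import Path

import pandas as pd

from uasmap import io
from uasmap.containers import COMPONENTS
from uasmap.phenotypes import (
    grade_distribution,
    overall_grade,
    phenotype_correlations,
    severity_rank,
    total_airway_score,
)

IN = Path("results/cohort/phenotypes.tsv")
OUT = Path("results/phenotypes")


def main() -> None:
    table = io.read_phenotypes(IN)
    OUT.mkdir(parents=True, exist_ok=True)

    total = total_airway_score(table)
    pd.DataFrame(
        {
            "dog_id": table["dog_id"],
            "total_airway_score": total,
            "overall_grade": [overall_grade(s) for s in total],
        }
    ).to_csv(OUT / "total_scores.tsv", sep="\t", index=False)

    dists = pd.concat(
        [grade_distribution(table, c).assign(component=c) for c in COMPONENTS]
    )
    dists.to_csv(OUT / "grade_distributions.tsv", sep="\t", index=False)

    corr, order = phenotype_correlations(table)
    corr.loc[order, order].to_csv(OUT / "correlations.tsv", sep="\t")

    rank = severity_rank(table)
    pd.DataFrame({"dog_id": rank.rank}).to_csv(OUT / "severity_rank.tsv", sep="\t", index=False)

    import numpy as np

    m = corr.to_numpy()
    off_diag = m[~np.eye(len(m), dtype=bool)]
    print(f"{len(table)} dogs; mean total score {total.mean():.1f}")
    print(f"median off-diagonal component correlation r = {np.nanmedian(off_diag):.3f}")
    print(f"most severe dog: {rank.rank[0]}")


if __name__ == "__main__":
    main()
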