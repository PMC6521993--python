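#!/usr/bin/env python
"""Mixed-model association scan of the total airway score: QC filters,
standardised kinship, per-marker REML, the Bonferroni threshold and
windowed LD around the index marker. Writes the association table, LD
table and Manhattan/QQ figures under results/gwas/."""
from pathlib import Path

import numpy as np

from uasmap import gwas, io, plots
from uasmap.phenotypes import total_airway_score

COHORT = Path("results/cohort")
OUT = Path("results/gwas")


def main() -> None:
    panel = io.read_vcf_genotypes(COHORT / "cohort.vcf")
    table = io.read_phenotypes(COHORT / "phenotypes.tsv")
    truth = io.read_truth(COHORT / "truth.json")
    OUT.mkdir(parents=True, exist_ok=True)

    filtered, qc = gwas.qc_filter(panel)
    kin = gwas.kinship(filtered)
    y = total_airway_score(table).to_numpy()
    covs = np.column_stack(
        [table["age_months"].to_numpy(float), (table["sex"] == "M").to_numpy(float)]
    )
    result = gwas.lmm_scan(filtered, y, covs, kin)
    result.table.to_csv(OUT / "association.tsv", sep="\t", index=False)

    p_thr, mlog = gwas.bonferroni_threshold(filtered.n_markers)
    top = result.top_marker()
    ld = gwas.ld_r2(filtered, [str(top["id"])], window=50)
    ld.to_csv(OUT / "ld_window.tsv", sep="\t", index=False)

    plots.manhattan(result, mlog, OUT / "manhattan.png")
    plots.qq(result, OUT / "qq.png")

    n_sig = len(result.significant(mlog))
    print(qc.summary())
    print(f"Bonferroni -log10 threshold over {filtered.n_markers} markers: {mlog}")
    print(
        f"index marker {top['id']} at -log10 p = {top['minus_log10_p']:.2f} "
        f"({n_sig} markers genome-wide significant)"
    )
    print(f"planted causal marker was {truth['causal_marker_id']}")
    print(f"genomic inflation lambda = {gwas.genomic_inflation(result.table['p']):.3f}")


if __name__ == "__main__":
    main()
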