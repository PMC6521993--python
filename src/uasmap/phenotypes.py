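"""Summaries and orderings of the ten ordinal airway grades.

Each dog carries ten laryngoscopic component grades (1 = normal to
4 = severe). This module computes the weighted total airway score, per
component grade distributions, the component correlation structure, an
overall categorical grade, and the severity ranking that orders dogs for
haplotype fine-mapping.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .containers import COMPONENTS, PRIORITY_COMPONENTS

#: Component weights for the total airway score. The weighting used
#: clinically is not published; unit weights preserve the ordinal
#: monotonicity that everything downstream relies on. Override via config.
DEFAULT_WEIGHTS = {c: 1.0 for c in COMPONENTS}

#: Total-score cutpoints for the overall grade (clear <= 14 < mild <= 22 <
#: moderate <= 30 < severe). Conventions of this package, not published
#: values; boundaries belong to the lower grade.
DEFAULT_OVERALL_CUTPOINTS = (14.0, 22.0, 30.0)


def _check_grades(table: pd.DataFrame) -> None:
    missing = [c for c in COMPONENTS if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table lacks components {missing}")
    for comp in COMPONENTS:
        col = table[comp]
        if col.isna().any():
            dog = table.loc[col.isna(), "dog_id"].iloc[0] if "dog_id" in table else "?"
            raise ValueError(f"missing grade for component {comp!r} (dog {dog})")
        bad = ~col.isin([1, 2, 3, 4])
        if bad.any():
            dog = table.loc[bad, "dog_id"].iloc[0] if "dog_id" in table else "?"
            raise ValueError(f"grade outside 1-4 for component {comp!r} (dog {dog})")


def total_airway_score(
    table: pd.DataFrame, weights: dict[str, float] | None = None
) -> pd.Series:
    """Weighted sum of the ten component grades per dog."""
    _check_grades(table)
    weights = DEFAULT_WEIGHTS if weights is None else weights
    missing = [c for c in COMPONENTS if c not in weights]
    if missing:
        raise ValueError(f"weights missing for components {missing}")
    if any(weights[c] < 0 for c in COMPONENTS):
        raise ValueError("component weights must be non-negative")
    score = sum(weights[c] * table[c].astype(float) for c in COMPONENTS)
    score.name = "total_airway_score"
    return score


def grade_distribution(table: pd.DataFrame, component: str) -> pd.DataFrame:
    """Counts and percentages of grades 1-4 for one component.

    Percentages are 100*count/n rounded to one decimal, the precision used
    in published grade tables.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    if len(table) == 0:
        raise ValueError("empty phenotype table")
    _check_grades(table)
    counts = table[component].value_counts().reindex([1, 2, 3, 4], fill_value=0)
    n = len(table)
    return pd.DataFrame(
        {
            "grade": [1, 2, 3, 4],
            "label": ["normal", "mild", "moderate", "severe"],
            "count": counts.to_numpy(),
            "percent": np.round(100.0 * counts.to_numpy() / n, 1),
        }
    )


def phenotype_correlations(table: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation matrix of the ten components plus a dendrogram order.

    Zero-variance components yield NaN rows/columns (flagged, never silently
    zero) and are placed last in the dendrogram order. Ordering uses
    average-linkage hierarchical clustering on 1 - r distance.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 dogs for correlations")
    _check_grades(table)
    grades = table[COMPONENTS].astype(float)
    corr = grades.corr()  # pandas leaves zero-variance columns as NaN
    np.fill_diagonal(corr.values, 1.0)
    defined = [c for c in COMPONENTS if not corr[c].drop(index=c).isna().all()]
    undefined = [c for c in COMPONENTS if c not in defined]
    for c in undefined:
        corr.loc[c, c] = np.nan
    if len(defined) > 2:
        sub = corr.loc[defined, defined].to_numpy()
        dist = squareform(np.clip(1.0 - sub, 0.0, 2.0), checks=False)
        order_idx = leaves_list(linkage(dist, method="average"))
        order = [defined[i] for i in order_idx] + undefined
    else:
        order = defined + undefined
    return corr, order


def overall_grade(
    score: float, cutpoints: tuple[float, float, float] = DEFAULT_OVERALL_CUTPOINTS
) -> str:
    """Categorical overall grade from the total score.

    Boundary scores take the lower grade: score <= cutpoints[0] is clear.
    """
    c1, c2, c3 = cutpoints
    if not c1 < c2 < c3:
        raise ValueError("cutpoints must be strictly increasing")
    if score <= c1:
        return "clear"
    if score <= c2:
        return "mild"
    if score <= c3:
        return "moderate"
    return "severe"


@dataclass
class SeverityOrder:
    """Dogs ranked most severe first on the priority components."""

    priority_components: list[str]
    rank: list[str]  # dog ids, most severe first

    def position(self, dog_id: str) -> int:
        return self.rank.index(dog_id)


def severity_rank(
    table: pd.DataFrame,
    priority_components: list[str] | None = None,
    weights: dict[str, float] | None = None,
) -> SeverityOrder:
    """Order dogs by severity for the haplotype ribbon and fine-mapper.

    Descending lexicographic sort on the priority-component grade tuple
    (most severe of all four first), ties broken by descending total airway
    score, then by stable input order.
    """
    priority = priority_components or PRIORITY_COMPONENTS
    missing = [c for c in priority if c not in table.columns]
    if missing:
        raise ValueError(f"priority components missing from table: {missing}")
    _check_grades(table)
    work = table.reset_index(drop=True).copy()
    work["_total"] = total_airway_score(work, weights).to_numpy()
    work["_input_order"] = np.arange(len(work))
    work = work.sort_values(
        by=list(priority) + ["_total", "_input_order"],
        ascending=[False] * len(priority) + [False, True],
        kind="stable",
    )
    return SeverityOrder(list(priority), work["dog_id"].tolist())


def severe_dogs(
    table: pd.DataFrame, component: str = "laryngeal_saccule", grade: int = 4
) -> list[str]:
    """The 'severe' stratum used for consensus-haplotype construction:
    dogs at the given grade (default 4) on the top-priority component."""
    _check_grades(table)
    return table.loc[table[component] >= grade, "dog_id"].tolist()
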