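"""Genotype-phenotype reporting.

Allele and genotype frequencies from counts, rank-sum comparisons of the
total airway score between genotype classes (exact enumeration for small
samples, tie- and continuity-corrected normal approximation otherwise),
and the breeding-guideline classification with its genotype-by-decision
table.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OVERALL_GRADES

#: Combined sample size at or below which the exact enumeration is used.
EXACT_LIMIT = 12


@dataclass
class GenotypeCounts:
    """Counts of the three genotype classes at a bi-allelic risk variant."""

    n_hom_risk: int
    n_het: int
    n_hom_ref: int

    def __post_init__(self) -> None:
        if min(self.n_hom_risk, self.n_het, self.n_hom_ref) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom_risk + self.n_het + self.n_hom_ref


def allele_frequency(counts: GenotypeCounts, decimals: int = 2) -> float:
    """Risk-allele frequency (2*hom + het)/(2n), reported to 2 decimals."""
    if counts.n == 0:
        raise ValueError("cannot compute allele frequency from zero dogs")
    af = (2 * counts.n_hom_risk + counts.n_het) / (2 * counts.n)
    return round(af, decimals)


def genotype_percentages(counts: GenotypeCounts, decimals: int = 1) -> dict[str, float]:
    if counts.n == 0:
        raise ValueError("empty genotype counts")
    return {
        "hom_risk": round(100.0 * counts.n_hom_risk / counts.n, decimals),
        "het": round(100.0 * counts.n_het / counts.n, decimals),
        "hom_ref": round(100.0 * counts.n_hom_ref / counts.n, decimals),
    }


def _u_statistic(ranks_x: np.ndarray, nx: int, ny: int) -> float:
    return float(ranks_x.sum() - nx * (nx + 1) / 2.0)


def mann_whitney_exact(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration with midranks.

    The p-value is the fraction of the C(nx+ny, nx) equally likely group
    assignments whose U statistic is at least as far from its null mean
    nx*ny/2 as the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks[:nx], nx, ny)
    mu = nx * ny / 2.0
    dev = abs(u_obs - mu)
    n = nx + ny
    count = 0
    total = 0
    for idx in combinations(range(n), nx):
        u = float(ranks[list(idx)].sum() - nx * (nx + 1) / 2.0)
        if abs(u - mu) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def mann_whitney_normal(x, y) -> float:
    """Two-sided normal-approximation p with tie and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = _u_statistic(ranks[:nx], nx, ny)
    n = nx + ny
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def genotype_score_test(x, y, method: str = "auto") -> float:
    """Two-sided Mann-Whitney p comparing scores between two genotype groups.

    ``auto`` enumerates exactly when the combined sample size is at most
    12 and falls back to the corrected normal approximation above that.
    """
    nx, ny = len(x), len(y)
    if method == "auto":
        method = "exact" if nx + ny <= EXACT_LIMIT else "normal"
    if method == "exact":
        return mann_whitney_exact(x, y)
    if method == "normal":
        return mann_whitney_normal(x, y)
    raise ValueError("method must be 'auto', 'exact' or 'normal'")


@dataclass
class BreedingPolicy:
    """Breeding-guideline rule: prohibit dogs whose overall grade exceeds
    ``max_permitted_grade`` (strictly — a 'moderate' dog is still permitted
    under the default rule)."""

    max_permitted_grade: str = "moderate"

    def __post_init__(self) -> None:
        if self.max_permitted_grade not in OVERALL_GRADES:
            raise ValueError(f"unknown grade {self.max_permitted_grade!r}")


def breeding_classifier(overall: str, policy: BreedingPolicy | None = None) -> str:
    """'permitted' or 'prohibited' for one dog's overall grade."""
    policy = policy or BreedingPolicy()
    if overall not in OVERALL_GRADES:
        raise ValueError(f"unknown overall grade {overall!r}")
    limit = OVERALL_GRADES.index(policy.max_permitted_grade)
    return "prohibited" if OVERALL_GRADES.index(overall) > limit else "permitted"


def genotype_by_decision_table(
    genotype_class: pd.Series | list[str],
    decision: pd.Series | list[str],
    decimals: int = 1,
) -> pd.DataFrame:
    """Within-stratum genotype percentages for permitted/prohibited dogs.

    Empty strata are flagged with NaN percentages rather than dropped.
    """
    df = pd.DataFrame({"genotype": list(genotype_class), "decision": list(decision)})
    rows = []
    for stratum in ("permitted", "prohibited"):
        sub = df[df["decision"] == stratum]
        n = len(sub)
        for geno in ("homozygous-risk", "heterozygous", "non-carrier"):
            cnt = int((sub["genotype"] == geno).sum())
            pct = round(100.0 * cnt / n, decimals) if n else float("nan")
            rows.append((stratum, geno, cnt, n, pct))
    return pd.DataFrame(
        rows, columns=["decision", "genotype", "count", "stratum_n", "percent"]
    )


def breed_table(rows: list[tuple[str, GenotypeCounts]]) -> pd.DataFrame:
    """Per-breed genotype counts and risk-allele frequency."""
    out = []
    for breed, counts in rows:
        out.append(
            (
                breed,
                counts.n_hom_risk,
                counts.n_het,
                counts.n_hom_ref,
                counts.n,
                allele_frequency(counts),
            )
        )
    return pd.DataFrame(
        out, columns=["breed", "n_hom_risk", "n_het", "n_hom_ref", "n", "allele_freq"]
    )
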