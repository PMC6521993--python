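"""Synthetic cohort generator.

Emulates the statistical structure of a single-breed mapping cohort:
a small pool of founder haplotypes recombined into sample chromosomes
(founder-mosaic LD and kinship), one causal variant born on a single
founder background (the risk haplotype), and ten correlated ordinal
airway grades produced by a liability-threshold model in which severity
depends on causal dosage plus a polygenic term drawn against the realised
kinship matrix.

The crossover model is deliberately minimal: a Poisson crossover count
per chromosome copy with uniform breakpoint positions and no
interference. That is enough to create the recombination-breakpoint
diversity the haplotype fine-mapper consumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import COMPONENTS, PRIORITY_COMPONENTS, GenotypePanel, HaplotypePanel


@dataclass
class FounderPool:
    """Founder haplotypes from which sample chromosomes are mosaicked."""

    haplotypes: np.ndarray  # (n_founders, n_markers) of 0/1
    markers: pd.DataFrame
    allele_freq_spectrum: np.ndarray
    causal_index: int
    risk_founder: int = 0

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape[0] < 2:
            raise ValueError("at least two founder haplotypes required")
        freqs = np.asarray(self.allele_freq_spectrum, dtype=float)
        if np.any(freqs <= 0) or np.any(freqs >= 1):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        for _, sub in self.markers.groupby("chrom", sort=False):
            if np.any(np.diff(sub["pos"].to_numpy()) <= 0):
                raise ValueError("marker positions must be strictly increasing")

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class DiseaseModel:
    """Liability-threshold model for the ten ordinal airway grades.

    Shared liability L = beta * causal dosage + g + e, with the polygenic
    term g ~ N(0, h2_polygenic * K) and e independent normal chosen so the
    residual (non-causal) liability variance is 1. Each component's latent
    score is loading * L plus component noise, cut at three thresholds
    into grades 1-4.
    """

    causal_marker_index: int
    beta: float = 2.0
    h2_polygenic: float = 0.3
    component_loadings: np.ndarray = field(
        default_factory=lambda: np.array(
            [1.0 if c in PRIORITY_COMPONENTS else 0.6 for c in COMPONENTS]
        )
    )
    component_noise_sd: float = 1.0
    grade_thresholds: np.ndarray | None = None  # (10, 3), built lazily
    causal_allele_freq: float = 0.57
    age_effect: float = 0.0  # liability units per month, off by default
    sex_effect: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not 0 <= self.h2_polygenic < 1:
            raise ValueError("h2_polygenic must lie in [0, 1)")
        self.component_loadings = np.asarray(self.component_loadings, dtype=float)
        if self.component_loadings.shape != (len(COMPONENTS),):
            raise ValueError(f"need {len(COMPONENTS)} component loadings")
        if self.grade_thresholds is None:
            self.grade_thresholds = self._default_thresholds()
        self.grade_thresholds = np.asarray(self.grade_thresholds, dtype=float)
        if self.grade_thresholds.shape != (len(COMPONENTS), 3):
            raise ValueError("grade_thresholds must be (n_components, 3)")
        if np.any(np.diff(self.grade_thresholds, axis=1) <= 0):
            raise ValueError("grade thresholds must be strictly increasing per component")

    def _default_thresholds(self) -> np.ndarray:
        # Cutpoints placed at fixed z-offsets of each component's
        # theoretical latent distribution so default grade frequencies are
        # stable across beta/loading choices.
        p = self.causal_allele_freq
        mean_l = self.beta * 2 * p
        var_l = self.beta**2 * 2 * p * (1 - p) + 1.0
        mean_c = self.component_loadings * mean_l
        sd_c = np.sqrt(self.component_loadings**2 * var_l + self.component_noise_sd**2)
        offsets = np.array([-1.0, 0.2, 1.2])
        return mean_c[:, None] + sd_c[:, None] * offsets[None, :]


@dataclass
class SimulatedCohort:
    haplotypes: HaplotypePanel
    genotypes: GenotypePanel
    phenotypes: pd.DataFrame
    truth: dict

    def __post_init__(self) -> None:
        dos = self.haplotypes.alleles.sum(axis=1)
        if not np.array_equal(dos, self.genotypes.dosages):
            raise ValueError("genotype dosages must equal the sum of phased alleles")


def default_marker_table(
    n_markers: int = 1000,
    n_chromosomes: int = 1,
    span: tuple[int, int] = (60_000_000, 62_000_000),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Evenly spread marker positions with small random jitter.

    A single chromosome is named chr13 (the locus under study); a
    multi-chromosome panel — used for genome-wide null calibration — is
    named chr1..chrN with the same per-chromosome span.
    """
    rng = rng or np.random.default_rng(0)
    lo, hi = span
    names = (
        ["chr13"]
        if n_chromosomes == 1
        else [f"chr{c + 1}" for c in range(n_chromosomes)]
    )
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    frames = []
    for chrom, m in zip(names, per):
        base = np.linspace(lo, hi, m).astype(np.int64)
        jitter = rng.integers(0, max((hi - lo) // (4 * m), 1), size=m)
        pos = np.sort(base + jitter)
        pos = np.maximum.accumulate(pos) + np.arange(m)  # force strict increase
        bases = np.array(list("ACGT"))
        ref = rng.choice(bases, size=m)
        alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{chrom}_{p}" for p in pos],
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_founders(
    n_haplotypes: int,
    marker_spec: pd.DataFrame | int = 1000,
    seed: int = 0,
    allele_freq_spectrum: np.ndarray | None = None,
    causal_index: int | None = None,
    n_chromosomes: int = 1,
) -> FounderPool:
    """Draw founder haplotypes; exactly one founder carries the causal allele.

    ``marker_spec`` is either a marker metadata table or a marker count (a
    default single-chromosome map is then generated). Founder alleles at
    each marker are Bernoulli draws from the allele-frequency spectrum
    (default Uniform(0.1, 0.9) per marker); the causal column is overwritten
    so the alternate allele is private to the designated risk founder,
    founder 0 — the variant is born on a single haplotype background.
    """
    if n_haplotypes < 2:
        raise ValueError("at least two founder haplotypes required")
    rng = np.random.default_rng(seed)
    if isinstance(marker_spec, int):
        markers = default_marker_table(marker_spec, n_chromosomes, rng=rng)
    else:
        markers = marker_spec.reset_index(drop=True)
    m = len(markers)
    if causal_index is None:
        causal_index = m // 2
    if not 0 <= causal_index < m:
        raise ValueError("causal_index out of range")
    if allele_freq_spectrum is None:
        freqs = rng.uniform(0.1, 0.9, size=m)
    else:
        freqs = np.asarray(allele_freq_spectrum, dtype=float)
        if freqs.shape != (m,):
            raise ValueError("allele_freq_spectrum length must match marker count")
    haps = (rng.random((n_haplotypes, m)) < freqs[None, :]).astype(np.int8)
    haps[:, causal_index] = 0
    haps[0, causal_index] = 1
    return FounderPool(haps, markers, freqs, causal_index=causal_index, risk_founder=0)


def _mosaic_block(
    haplotypes: np.ndarray,
    pos: np.ndarray,
    weights: np.ndarray,
    recomb_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mosaic one chromosome: Poisson crossover count, uniform breakpoints,
    independent founder donor per segment."""
    n_cross = rng.poisson(recomb_rate)
    if n_cross == 0:
        donor = rng.choice(haplotypes.shape[0], p=weights)
        return haplotypes[donor].copy()
    breakpoints = np.sort(rng.uniform(pos[0], pos[-1], size=n_cross))
    donors = rng.choice(haplotypes.shape[0], size=n_cross + 1, p=weights)
    segment = np.searchsorted(breakpoints, pos, side="right")
    return haplotypes[donors[segment], np.arange(len(pos))].copy()


def simulate_population(
    founders: FounderPool,
    n_dogs: int,
    recomb_rate: float = 1.0,
    target_risk_af: float = 0.57,
    seed: int = 0,
    max_tries: int = 100,
) -> tuple[HaplotypePanel, GenotypePanel]:
    """Mosaic sample chromosomes from the founder pool.

    Each chromosome copy receives a Poisson(recomb_rate) crossover count
    with uniform breakpoint positions; segment donors are drawn with the
    risk founder weighted at target_risk_af so the realised causal allele
    frequency lands near the target. On a multi-chromosome panel only the
    chromosome carrying the causal marker is risk-weighted; the others use
    uniform founder weights and recombine independently. Populations whose
    realised frequency misses the target by more than 0.05 are redrawn
    (deterministically under the seed).
    """
    if not 0 < target_risk_af < 1:
        raise ValueError("target_risk_af must lie strictly in (0, 1)")
    if recomb_rate < 0:
        raise ValueError("recomb_rate must be non-negative")
    causal_col = founders.haplotypes[:, founders.causal_index]
    if causal_col.sum() == 0 or causal_col.sum() == founders.n_founders:
        raise ValueError("causal allele fixed or absent in founders; target unattainable")
    risk_weights = np.full(
        founders.n_founders, (1 - target_risk_af) / (founders.n_founders - 1)
    )
    risk_weights[founders.risk_founder] = target_risk_af
    uniform = np.full(founders.n_founders, 1.0 / founders.n_founders)

    markers = founders.markers
    causal_chrom = markers.loc[founders.causal_index, "chrom"]
    blocks = []  # (marker index array, positions, weights) per chromosome
    for chrom, sub in markers.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        w = risk_weights if chrom == causal_chrom else uniform
        blocks.append((idx, sub["pos"].to_numpy().astype(float), w))

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        alleles = np.empty((n_dogs, 2, founders.n_markers), dtype=np.int8)
        for i in range(n_dogs):
            for c in range(2):
                for idx, pos, w in blocks:
                    alleles[i, c, idx] = _mosaic_block(
                        founders.haplotypes[:, idx], pos, w, recomb_rate, rng
                    )
        realised = alleles[:, :, founders.causal_index].mean()
        if abs(realised - target_risk_af) <= 0.05:
            break
    else:
        raise RuntimeError(
            f"could not realise causal AF within 0.05 of {target_risk_af} "
            f"in {max_tries} draws"
        )
    samples = [f"dog{i:04d}" for i in range(n_dogs)]
    hap = HaplotypePanel(alleles, founders.markers.copy(), samples)
    return hap, hap.to_genotypes()


def simulate_phenotypes(
    genotypes: GenotypePanel,
    kinship: np.ndarray,
    model: DiseaseModel,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Liability-threshold draw of the ten ordinal grades plus covariates.

    Returns the phenotype table and the per-dog shared liability L.
    Age and sex are emitted as covariates with no liability effect unless
    the model sets age_effect / sex_effect.
    """
    kinship = np.asarray(kinship, dtype=float)
    n = genotypes.n_samples
    if kinship.shape != (n, n):
        raise ValueError("kinship dimensions must match the cohort")
    if not np.allclose(kinship, kinship.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    rng = np.random.default_rng(seed)
    dosage = genotypes.dosages[:, model.causal_marker_index]
    if np.isnan(dosage).any():
        raise ValueError("causal marker has missing dosages")

    h2 = model.h2_polygenic
    if h2 > 0:
        # small jitter keeps Cholesky stable for near-singular realised kinship
        chol = np.linalg.cholesky(kinship + 1e-8 * np.eye(n))
        g = np.sqrt(h2) * (chol @ rng.standard_normal(n))
    else:
        g = np.zeros(n)
    e = np.sqrt(1.0 - h2) * rng.standard_normal(n)

    age = rng.integers(6, 121, size=n).astype(float)
    sex = rng.integers(0, 2, size=n)  # 0 = F, 1 = M
    weight = np.clip(rng.normal(5.5, 0.8, size=n), 3.5, None).round(1)

    liability = (
        model.beta * dosage + g + e + model.age_effect * age + model.sex_effect * sex
    )

    table = {"dog_id": genotypes.samples.copy()}
    table["sex"] = np.where(sex == 1, "M", "F")
    table["age_months"] = age.astype(int)
    table["weight_kg"] = weight
    for k, comp in enumerate(COMPONENTS):
        latent = model.component_loadings[k] * liability + rng.normal(
            0.0, model.component_noise_sd, size=n
        )
        grades = np.digitize(latent, model.grade_thresholds[k]) + 1
        table[comp] = grades.astype(int)
    return pd.DataFrame(table), liability


def simulate_cohort(
    n_dogs: int = 300,
    n_markers: int = 1000,
    n_founders: int = 30,
    recomb_rate: float = 1.0,
    target_risk_af: float = 0.57,
    model: DiseaseModel | None = None,
    seed: int = 0,
    n_chromosomes: int = 1,
) -> SimulatedCohort:
    """One-call cohort simulation chaining founders -> population -> phenotypes.

    The kinship handed to the phenotype model is the realised standardised
    kinship of the simulated markers, so the association scan's estimated
    kinship can recover the structure it needs to correct for.
    """
    from .gwas import kinship as estimate_kinship

    rng = np.random.default_rng(seed)
    s_founders, s_pop, s_pheno = rng.integers(0, 2**31 - 1, size=3)
    founders = simulate_founders(
        n_founders, n_markers, seed=int(s_founders), n_chromosomes=n_chromosomes
    )
    haps, genos = simulate_population(
        founders, n_dogs, recomb_rate, target_risk_af, seed=int(s_pop)
    )
    if model is None:
        model = DiseaseModel(causal_marker_index=founders.causal_index)
    elif model.causal_marker_index != founders.causal_index:
        raise ValueError("disease model causal index must match the founder pool")
    kin = estimate_kinship(genos)
    phenos, liability = simulate_phenotypes(genos, kin.matrix, model, seed=int(s_pheno))
    truth = {
        "causal_marker_id": str(genos.markers.loc[founders.causal_index, "id"]),
        "causal_marker_index": int(founders.causal_index),
        "causal_pos": int(genos.markers.loc[founders.causal_index, "pos"]),
        "risk_founder": int(founders.risk_founder),
        "beta": float(model.beta),
        "h2_polygenic": float(model.h2_polygenic),
        "seed": int(seed),
        "liability": [float(x) for x in liability],
    }
    return SimulatedCohort(haps, genos, phenos, truth)
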