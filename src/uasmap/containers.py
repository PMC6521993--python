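"""In-memory containers shared across the pipeline.

Genotypes are dosages of the alternate allele (0/1/2, NaN = missing) in a
samples x markers matrix; phased haplotypes are a (samples, 2, markers)
array of 0/1 alleles. Marker metadata travels alongside as a DataFrame with
columns ``id, chrom, pos, ref, alt`` (``pos`` is 1-based, as in VCF).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]

#: The ten laryngoscopically graded airway components (grades 1-4 =
#: normal / mild / moderate / severe).
COMPONENTS = [
    "laryngeal_saccule",
    "soft_palate_length",
    "oedema_cricoid",
    "oedema_pharynx",
    "oedema_oropharynx",
    "trachea_shape",
    "cartilage_position",
    "cartilage_stability",
    "soft_palate_thickness",
    "cartilage_shape",
]

#: Components ranked by GWAS significance; drives the severity ordering
#: used by the fine-mapper.
PRIORITY_COMPONENTS = [
    "laryngeal_saccule",
    "cartilage_position",
    "oedema_cricoid",
    "oedema_oropharynx",
]

GRADE_LABELS = {1: "normal", 2: "mild", 3: "moderate", 4: "severe"}
OVERALL_GRADES = ["clear", "mild", "moderate", "severe"]


def _check_markers(markers: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise ValueError(f"marker table lacks columns {missing}")
    if markers["id"].duplicated().any():
        raise ValueError("marker ids must be unique")
    for _, sub in markers.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError("marker positions must be strictly increasing per chromosome")
    return markers.reset_index(drop=True)


@dataclass
class GenotypePanel:
    """Dosage matrix (samples x markers) with marker and sample metadata."""

    dosages: np.ndarray  # float array, values 0/1/2 or NaN
    markers: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.markers = _check_markers(self.markers)
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        valid = np.isnan(self.dosages) | np.isin(self.dosages, [0.0, 1.0, 2.0])
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker, ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypePanel":
        d = self.dosages
        samples = self.samples
        markers = self.markers
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx, :]
            samples = [self.samples[i] for i in sample_idx]
        if marker_idx is not None:
            marker_idx = np.asarray(marker_idx)
            d = d[:, marker_idx]
            markers = markers.iloc[marker_idx]
        return GenotypePanel(d.copy(), markers.reset_index(drop=True), list(samples))


@dataclass
class HaplotypePanel:
    """Phased alleles, two chromosomes per sample, sharing the marker index."""

    alleles: np.ndarray  # (n_samples, 2, n_markers) of 0/1
    markers: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.markers = _check_markers(self.markers)
        n, two, m = self.alleles.shape
        if two != 2:
            raise ValueError("exactly two chromosomes per sample required")
        if (n, m) != (len(self.samples), len(self.markers)):
            raise ValueError("haplotype array does not match sample/marker counts")
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("phased alleles must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def to_genotypes(self) -> GenotypePanel:
        return GenotypePanel(
            self.alleles.sum(axis=1).astype(float), self.markers.copy(), list(self.samples)
        )

    def chromosomes(self) -> np.ndarray:
        """Flatten to a (2*n_samples, n_markers) chromosome matrix."""
        return self.alleles.reshape(-1, self.n_markers)


@dataclass
class AssociationResult:
    """Per-marker mixed-model association statistics."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: id, chrom, pos, beta, se, wald, p, minus_log10_p, var_ratio

    def top_marker(self) -> pd.Series:
        return self.table.loc[self.table["minus_log10_p"].idxmax()]

    def significant(self, minus_log10_threshold: float) -> pd.DataFrame:
        return self.table[self.table["minus_log10_p"] >= minus_log10_threshold]


@dataclass
class CriticalInterval:
    """Haplotype-sharing critical interval around an index marker."""

    chrom: str
    left: int
    right: int
    index_pos: int
    left_events: list[tuple[int, int]]  # (chromosome row, first mismatching marker idx)
    right_events: list[tuple[int, int]]
    min_recomb: int
    left_bounded: bool = True
    right_bounded: bool = True

    @property
    def length(self) -> int:
        # end - start, matching the published interval arithmetic
        # (61,166,179-61,579,985 is printed as 413,806 bp)
        return self.right - self.left

    def contains(self, pos: int) -> bool:
        return self.left <= pos <= self.right
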