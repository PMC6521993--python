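"""Haplotype-sharing refinement of the critical interval.

Severely affected dogs are expected to share the ancestral risk haplotype
around the index marker. The modal phased haplotype among their
chromosomes is the consensus; walking outward from the index marker, each
consensus-carrying chromosome "departs" at its first mismatching marker,
and a departure is read as one meiotic recombination event. The critical
interval ends just inside the marker at which the cumulative event count
on that side reaches ``min_recomb`` (default 3).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CriticalInterval, HaplotypePanel


@dataclass
class ConsensusHaplotype:
    """Modal risk haplotype among severe dogs' chromosomes over a region."""

    alleles: np.ndarray  # 0/1 over the region's markers
    marker_idx: np.ndarray  # panel marker indices the alleles refer to
    support: int  # chromosomes exactly matching over the region
    total: int  # severe chromosomes considered

    def __post_init__(self) -> None:
        if self.support > self.total:
            raise ValueError("support cannot exceed total chromosome count")


def _region_indices(panel: HaplotypePanel, region: tuple[int, int] | None) -> np.ndarray:
    if region is None:
        return np.arange(panel.n_markers)
    lo, hi = region
    pos = panel.markers["pos"].to_numpy()
    idx = np.where((pos >= lo) & (pos <= hi))[0]
    if len(idx) == 0:
        raise ValueError(f"no panel markers inside region {region}")
    return idx


def _severe_chromosomes(
    panel: HaplotypePanel, severe_ids: list[str]
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Chromosome rows of the severe dogs, in the given severity order."""
    if not severe_ids:
        raise ValueError("empty severe-dog set")
    id_to_idx = {s: i for i, s in enumerate(panel.samples)}
    missing = [s for s in severe_ids if s not in id_to_idx]
    if missing:
        raise ValueError(f"severe dogs not in panel: {missing}")
    rows = []
    owners = []
    for dog in severe_ids:
        i = id_to_idx[dog]
        for c in (0, 1):
            rows.append(panel.alleles[i, c])
            owners.append((i, dog))
    return np.array(rows), owners


def consensus_risk_haplotype(
    panel: HaplotypePanel,
    severe_ids: list[str],
    region: tuple[int, int] | None = None,
) -> ConsensusHaplotype:
    """The most frequent full-region haplotype among severe dogs.

    ``severe_ids`` must be ordered most severe first; frequency ties are
    broken in favour of the haplotype carried by the highest-ranked dog
    (then lowest dog id), which makes the choice deterministic.
    """
    idx = _region_indices(panel, region)
    chroms, owners = _severe_chromosomes(panel, severe_ids)
    sub = chroms[:, idx]
    counts = Counter(map(tuple, sub))
    top = max(counts.values())
    winners = {h for h, c in counts.items() if c == top}
    if len(winners) == 1:
        chosen = next(iter(winners))
    else:
        chosen = None
        # owners are already in severity order; first carrier wins, with the
        # lowest dog id as a final deterministic tie-break within a dog rank
        for rank, (row, (_, dog)) in enumerate(zip(sub, owners)):
            h = tuple(row)
            if h in winners:
                chosen = h
                break
    return ConsensusHaplotype(
        np.array(chosen, dtype=np.int8), idx, support=top, total=len(sub)
    )


def departure_scan(
    panel: HaplotypePanel,
    consensus: ConsensusHaplotype,
    severe_ids: list[str],
    index_marker: str,
) -> pd.DataFrame:
    """First departure from consensus per chromosome, left and right.

    Only chromosomes matching the consensus allele at the index marker are
    scanned; each contributes at most one departure per side (a chromosome
    that departs and later re-matches still counts once). Departure columns
    hold panel marker indices, or -1 for no departure on that side.
    """
    ids = panel.markers["id"].tolist()
    if index_marker not in ids:
        raise ValueError(f"index marker {index_marker!r} not in panel")
    index_idx = ids.index(index_marker)
    region_pos = {int(g): k for k, g in enumerate(consensus.marker_idx)}
    if index_idx not in region_pos:
        raise ValueError("index marker lies outside the consensus region")
    chroms, owners = _severe_chromosomes(panel, severe_ids)
    sub = chroms[:, consensus.marker_idx]
    i0 = region_pos[index_idx]
    cons = consensus.alleles
    rows = []
    for c, (row, (sample_i, dog)) in enumerate(zip(sub, owners)):
        if row[i0] != cons[i0]:
            continue  # not a risk chromosome at the anchor: excluded
        mism = row != cons
        left = np.where(mism[:i0])[0]
        right = np.where(mism[i0 + 1 :])[0]
        left_dep = int(consensus.marker_idx[left[-1]]) if len(left) else -1
        right_dep = int(consensus.marker_idx[i0 + 1 + right[0]]) if len(right) else -1
        rows.append((c, dog, left_dep, right_dep))
    return pd.DataFrame(rows, columns=["chromosome", "dog_id", "left_departure", "right_departure"])


def _boundary(
    departures: np.ndarray,
    index_idx: int,
    min_recomb: int,
    side: str,
    n_markers: int,
    boundary_inclusive: bool,
) -> tuple[int, bool, list[int]]:
    """Walk outward accumulating departures; boundary is the last marker
    strictly inside the marker where the count reaches min_recomb."""
    order = (
        range(index_idx - 1, -1, -1) if side == "left" else range(index_idx + 1, n_markers)
    )
    count = 0
    events = []
    for j in order:
        hits = int((departures == j).sum())
        if hits:
            count += hits
            events.extend([j] * hits)
        if count >= min_recomb:
            if boundary_inclusive:
                return j, True, events
            inner = j + 1 if side == "left" else j - 1
            return inner, True, events
    edge = 0 if side == "left" else n_markers - 1
    return edge, False, events


def critical_interval(
    panel: HaplotypePanel,
    severe_ids: list[str],
    index_marker: str,
    min_recomb: int = 3,
    region: tuple[int, int] | None = None,
    boundary_inclusive: bool = False,
    count_mode: str = "per_side",
) -> tuple[CriticalInterval, ConsensusHaplotype]:
    """Define the critical interval by accumulated recombination events.

    ``count_mode='per_side'`` requires min_recomb events independently on
    each side (default); ``'total'`` stops both walks once the combined
    count reaches min_recomb, taking the side boundaries reached at that
    point. If a side never accumulates enough events its boundary falls on
    the outermost panel marker and the interval is flagged unbounded there.
    """
    if min_recomb < 1:
        raise ValueError("min_recomb must be >= 1")
    consensus = consensus_risk_haplotype(panel, severe_ids, region)
    scan = departure_scan(panel, consensus, severe_ids, index_marker)
    if len(scan) == 0:
        raise ValueError("no severe chromosome carries the consensus at the index marker")
    ids = panel.markers["id"].tolist()
    index_idx = ids.index(index_marker)
    pos = panel.markers["pos"].to_numpy()
    n = panel.n_markers

    if count_mode == "per_side":
        need_left = need_right = min_recomb
    elif count_mode == "total":
        # split the walk: each side runs until the combined tally reaches
        # min_recomb, nearest departures (either side) counted first
        need_left = need_right = min_recomb  # refined below
    else:
        raise ValueError("count_mode must be 'per_side' or 'total'")

    left_dep = scan["left_departure"].to_numpy()
    right_dep = scan["right_departure"].to_numpy()

    if count_mode == "total":
        dists = []
        for j in left_dep[left_dep >= 0]:
            dists.append((index_idx - j, "L", int(j)))
        for j in right_dep[right_dep >= 0]:
            dists.append((j - index_idx, "R", int(j)))
        dists.sort()
        cutoff = dists[: min_recomb]
        if len(cutoff) < min_recomb:
            lj, lb = 0, False
            rj, rb = n - 1, False
            levents = [int(j) for j in left_dep if j >= 0]
            revents = [int(j) for j in right_dep if j >= 0]
        else:
            lhits = [j for _, s, j in cutoff if s == "L"]
            rhits = [j for _, s, j in cutoff if s == "R"]
            lj = (min(lhits) + (0 if boundary_inclusive else 1)) if lhits else 0
            rj = (max(rhits) - (0 if boundary_inclusive else 1)) if rhits else n - 1
            lb, rb = bool(lhits), bool(rhits)
            levents, revents = lhits, rhits
    else:
        lj, lb, levents = _boundary(left_dep, index_idx, need_left, "left", n, boundary_inclusive)
        rj, rb, revents = _boundary(right_dep, index_idx, need_right, "right", n, boundary_inclusive)

    lj = min(lj, index_idx)
    rj = max(rj, index_idx)
    interval = CriticalInterval(
        chrom=str(panel.markers.loc[index_idx, "chrom"]),
        left=int(pos[lj]),
        right=int(pos[rj]),
        index_pos=int(pos[index_idx]),
        left_events=[(int(r.chromosome), int(r.left_departure)) for r in scan.itertuples() if r.left_departure >= 0],
        right_events=[(int(r.chromosome), int(r.right_departure)) for r in scan.itertuples() if r.right_departure >= 0],
        min_recomb=min_recomb,
        left_bounded=lb,
        right_bounded=rb,
    )
    return interval, consensus


def diplotype_class(
    panel: HaplotypePanel,
    consensus: ConsensusHaplotype,
    dog_id: str,
    region_idx: np.ndarray | None = None,
) -> str:
    """Classify one dog by how many chromosomes match the consensus across
    the interval: 2 -> homozygous-risk, 1 -> heterozygous, 0 -> non-carrier."""
    idx = consensus.marker_idx if region_idx is None else region_idx
    i = panel.samples.index(dog_id)
    cons = consensus.alleles if region_idx is None else consensus.alleles[
        np.searchsorted(consensus.marker_idx, idx)
    ]
    n_match = sum(
        int(np.array_equal(panel.alleles[i, c, idx], cons)) for c in (0, 1)
    )
    return {2: "homozygous-risk", 1: "heterozygous", 0: "non-carrier"}[n_match]


def diplotype_percentages(
    panel: HaplotypePanel,
    consensus: ConsensusHaplotype,
    strata: dict[str, list[str]],
) -> pd.DataFrame:
    """Homozygous-risk / heterozygous / non-carrier percentages (1 dp) per
    named stratum of dogs, e.g. severe vs moderately-to-unaffected."""
    rows = []
    for name, dogs in strata.items():
        classes = Counter(diplotype_class(panel, consensus, d) for d in dogs)
        n = len(dogs)
        for cls in ("homozygous-risk", "heterozygous", "non-carrier"):
            cnt = classes.get(cls, 0)
            pct = round(100.0 * cnt / n, 1) if n else float("nan")
            rows.append((name, cls, cnt, n, pct))
    return pd.DataFrame(rows, columns=["stratum", "diplotype", "count", "n", "percent"])
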