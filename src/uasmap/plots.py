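"""Diagnostic figures: Manhattan and QQ plots for the scan, the
severity-ordered haplotype ribbon, and score-by-genotype distributions."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .containers import AssociationResult, HaplotypePanel
from .finemap import ConsensusHaplotype


def manhattan(result: AssociationResult, threshold: float, path: str | Path) -> None:
    """-log10 p by position, one panel per chromosome, with the
    significance threshold drawn."""
    table = result.table
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for chrom, sub in table.groupby("chrom", sort=False):
        x = sub["pos"] - sub["pos"].min() + offset
        ax.scatter(x, sub["minus_log10_p"], s=6)
        ticks.append(x.mean())
        labels.append(str(chrom))
        offset = x.max() + (sub["pos"].max() - sub["pos"].min()) * 0.02
    ax.axhline(threshold, color="red", linestyle="--", linewidth=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq(result: AssociationResult, path: str | Path) -> None:
    """Observed vs expected -log10 p under the uniform null."""
    obs = np.sort(result.table["minus_log10_p"].to_numpy())[::-1]
    n = len(obs)
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    ax.scatter(exp, obs, s=6)
    lim = max(exp.max(), obs.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", linewidth=0.8)
    ax.set_xlabel("expected " + r"$-\log_{10} p$")
    ax.set_ylabel("observed " + r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def haplotype_ribbon(
    panel: HaplotypePanel,
    consensus: ConsensusHaplotype,
    ordered_dogs: list[str],
    index_pos: int,
    path: str | Path,
) -> None:
    """Dogs ordered by severity (top first); each row coloured white/orange/
    red for homozygous-consensus, heterozygous and homozygous-alternate
    genotypes relative to the consensus haplotype."""
    idx = consensus.marker_idx
    cons = consensus.alleles
    rows = []
    for dog in ordered_dogs:
        i = panel.samples.index(dog)
        match = (panel.alleles[i, :, :][:, idx] == cons[None, :]).sum(axis=0)
        rows.append(2 - match)  # 0 hom-consensus, 1 het, 2 hom-alternate
    img = np.array(rows)
    fig, ax = plt.subplots(figsize=(9, max(2.0, 0.06 * len(rows))))
    cmap = matplotlib.colors.ListedColormap(["white", "orange", "red"])
    ax.imshow(img, aspect="auto", cmap=cmap, vmin=0, vmax=2, interpolation="nearest")
    pos = panel.markers.loc[idx, "pos"].to_numpy()
    j = int(np.argmin(np.abs(pos - index_pos)))
    ax.axvline(j, color="black", linewidth=0.8)
    ax.set_xlabel("marker")
    ax.set_ylabel("dogs (most severe at top)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def score_by_genotype(
    scores: np.ndarray, genotype_class: list[str], path: str | Path
) -> None:
    """Total airway score distributions stratified by diplotype class."""
    order = ["non-carrier", "heterozygous", "homozygous-risk"]
    data = [
        [s for s, g in zip(scores, genotype_class) if g == cls] for cls in order
    ]
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.boxplot([d if d else [np.nan] for d in data], tick_labels=order)
    for k, d in enumerate(data, start=1):
        if d:
            jitter = np.random.default_rng(0).uniform(-0.12, 0.12, len(d))
            ax.scatter(np.full(len(d), k) + jitter, d, s=8, alpha=0.5)
    ax.set_ylabel("total airway score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
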