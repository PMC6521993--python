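"""Linear mixed-model association scan.

The model for each marker is

    y = W a + x b + u + e,   u ~ N(0, sg2 K),  e ~ N(0, se2 I)

with W the fixed covariates (intercept, age, sex), x the marker dosage and
K a genomic kinship matrix. Writing the variance ratio lam = sg2/se2, the
covariance is se2 (lam K + I); after a one-off eigendecomposition
K = U S U', the rotated model has a diagonal covariance with weights
1/(lam s_i + 1), and the restricted likelihood is maximised over lam per
marker by a log-grid search with local parabolic refinement — the
EMMA-style computation. Wald t statistics use the GLS estimate at the
optimum with n - p degrees of freedom (p = all fixed-effect columns), so
with K = I the scan collapses exactly to ordinary least squares.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AssociationResult, GenotypePanel

LOG10 = np.log(10.0)


@dataclass
class KinshipMatrix:
    """Genomic relationship matrix; sample order matches the source panel."""

    matrix: np.ndarray
    samples: list[str]
    n_markers_used: int
    dropped_markers: list[str]

    def __post_init__(self) -> None:
        k = np.asarray(self.matrix, dtype=float)
        if not np.allclose(k, k.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        w = np.linalg.eigvalsh(k)
        if w[0] < -1e-8 * max(w[-1], 1.0):
            raise ValueError("kinship matrix must be positive semi-definite")
        self.matrix = (k + k.T) / 2.0


@dataclass
class QCReport:
    removed_samples: pd.DataFrame  # sample, missing_fraction
    removed_markers: pd.DataFrame  # id, maf, reason

    def summary(self) -> str:
        return (
            f"{len(self.removed_samples)} samples removed (missingness), "
            f"{len(self.removed_markers)} markers removed (MAF)"
        )


def qc_filter(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    sample_missing_max: float = 0.1,
) -> tuple[GenotypePanel, QCReport]:
    """Remove high-missingness samples, then low-MAF markers.

    Samples with missing fraction strictly above ``sample_missing_max`` go
    first; marker MAF is then computed on the retained samples and markers
    with MAF strictly below ``maf_min`` are dropped. Both cutoffs are
    strict, so MAF exactly 0.05 and missingness exactly 0.1 survive.
    """
    if panel.n_samples == 0 or panel.n_markers == 0:
        raise ValueError("empty genotype panel")
    miss_frac = np.isnan(panel.dosages).mean(axis=1)
    keep_samples = miss_frac <= sample_missing_max
    if not keep_samples.any():
        raise ValueError("QC removed every sample")
    removed_samples = pd.DataFrame(
        {
            "sample": [s for s, k in zip(panel.samples, keep_samples) if not k],
            "missing_fraction": miss_frac[~keep_samples],
        }
    )
    retained = panel.subset(sample_idx=np.where(keep_samples)[0])
    af = retained.allele_freq()
    maf = np.minimum(af, 1 - af)
    keep_markers = ~(maf < maf_min)  # NaN AF (all-missing marker) also dropped
    keep_markers &= ~np.isnan(maf)
    removed_markers = pd.DataFrame(
        {
            "id": retained.markers.loc[~keep_markers, "id"].to_numpy(),
            "maf": maf[~keep_markers],
            "reason": [
                "all_missing" if np.isnan(x) else "maf_below_min"
                for x in maf[~keep_markers]
            ],
        }
    )
    filtered = retained.subset(marker_idx=np.where(keep_markers)[0])
    return filtered, QCReport(removed_samples, removed_markers)


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-marker mean."""
    out = dosages.astype(float).copy()
    col_mean = np.nanmean(out, axis=0)
    idx = np.where(np.isnan(out))
    out[idx] = col_mean[idx[1]]
    return out


def kinship(panel: GenotypePanel, standardised: bool = True) -> KinshipMatrix:
    """Genomic kinship K = Z Z' / m from centred (and by default scaled)
    dosage columns. Zero-variance markers carry no relatedness information
    and are excluded with a note in the result."""
    x = mean_impute(panel.dosages)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    dropped = panel.markers.loc[~keep, "id"].tolist()
    z = x[:, keep] - mu[keep]
    if standardised:
        z = z / sd[keep]
    m = keep.sum()
    if m == 0:
        raise ValueError("no polymorphic markers for kinship")
    k = z @ z.T / m
    return KinshipMatrix(k, list(panel.samples), int(m), dropped)


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """Bonferroni-corrected p cutoff and its -log10, the latter to 2 dp."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    p_thr = alpha / n_tests
    return p_thr, round(-np.log10(p_thr), 2)


def _scan_at_lambda(w, ut_w, ut_x, ut_y, f0_logdet_xtx, criterion="reml"):
    """GLS fits for all markers at one weight vector w (length n).

    Returns beta, the marker's Schur complement (its GLS precision), the
    residual sum of squares and the restricted (or full, profile-beta)
    log-likelihood used to pick the variance ratio.
    """
    n = ut_y.shape[0]
    p = ut_w.shape[1] + 1
    ww = ut_w * w[:, None]
    a = ut_w.T @ ww  # (q, q)
    b = ww.T @ ut_y  # (q,)
    f = float(ut_y @ (w * ut_y))
    a_inv = np.linalg.inv(a)
    ab = a_inv @ b
    wx = ut_x * w[:, None]  # (n, m)
    c = ut_w.T @ wx  # (q, m)
    d = np.einsum("nm,nm->m", ut_x, wx)  # x' W x
    e = wx.T @ ut_y  # (m,)
    g = a_inv @ c  # (q, m)
    schur = d - np.einsum("qm,qm->m", c, g)
    schur = np.maximum(schur, 1e-300)
    t_num = e - c.T @ ab  # (m,)
    beta = t_num / schur
    rss0 = f - b @ ab
    rss = np.maximum(rss0 - t_num**2 / schur, 1e-300)
    sum_log_w = float(np.log(w).sum())
    if criterion == "reml":
        sign, logdet_a = np.linalg.slogdet(a)
        logdet_xtwx = logdet_a + np.log(schur)
        df = n - p
        ll = 0.5 * (
            df * (np.log(df / (2 * np.pi)) - 1)
            - df * np.log(rss)
            + sum_log_w
            - logdet_xtwx
            + f0_logdet_xtx
        )
    else:  # ML with beta profiled out
        ll = 0.5 * (n * (np.log(n / (2 * np.pi)) - 1) - n * np.log(rss) + sum_log_w)
    return beta, schur, rss, ll


def lmm_scan(
    panel: GenotypePanel,
    phenotype: np.ndarray | pd.Series,
    covariates: np.ndarray | pd.DataFrame | None,
    kin: KinshipMatrix | np.ndarray,
    grid_size: int = 41,
    lambda_bounds: tuple[float, float] = (1e-5, 1e5),
    criterion: str = "reml",
) -> AssociationResult:
    """Per-marker univariate LMM association with Wald t tests.

    ``covariates`` excludes the intercept (added here); ordinal phenotype
    grades are treated as numeric. The genetic/residual variance ratio is
    optimised per marker on a log grid over ``lambda_bounds`` with
    parabolic refinement; flat stretches resolve toward the smaller ratio.
    ``criterion`` selects the restricted ("reml", default) or full profile
    ("ml") likelihood for that search.
    """
    if criterion not in ("reml", "ml"):
        raise ValueError("criterion must be 'reml' or 'ml'")
    y = np.asarray(phenotype, dtype=float)
    n = panel.n_samples
    if y.shape != (n,):
        raise ValueError("phenotype length must match sample count")
    k = kin.matrix if isinstance(kin, KinshipMatrix) else np.asarray(kin, dtype=float)
    if k.shape != (n, n):
        raise ValueError("kinship dimensions must match the panel")
    if not np.allclose(k, k.T, atol=1e-8):
        raise ValueError("kinship must be symmetric")
    if covariates is None:
        w_mat = np.ones((n, 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        w_mat = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(w_mat) < w_mat.shape[1]:
        raise ValueError("singular covariate design")

    s, u = np.linalg.eigh(k)
    if s[0] < -1e-8 * max(s[-1], 1.0):
        raise ValueError("kinship must be positive semi-definite")
    s = np.clip(s, 0.0, None)

    x = mean_impute(panel.dosages)
    ut_w = u.T @ w_mat
    ut_x = u.T @ x
    ut_y = u.T @ y

    p = w_mat.shape[1] + 1
    # log|X'X| per marker, lambda-independent (enters REML as a constant
    # in lambda but kept so likelihood values are comparable across markers)
    a0 = w_mat.T @ w_mat
    sign0, logdet_a0 = np.linalg.slogdet(a0)
    a0_inv = np.linalg.inv(a0)
    c0 = w_mat.T @ x
    d0 = np.einsum("nm,nm->m", x, x)
    schur0 = np.maximum(d0 - np.einsum("qm,qm->m", c0, a0_inv @ c0), 1e-300)
    f0_logdet_xtx = logdet_a0 + np.log(schur0)

    lo, hi = lambda_bounds
    grid = np.logspace(np.log10(lo), np.log10(hi), grid_size)
    m = panel.n_markers
    reml_grid = np.empty((grid_size, m))
    for gi, lam in enumerate(grid):
        w = 1.0 / (lam * s + 1.0)
        _, _, _, ll = _scan_at_lambda(w, ut_w, ut_x, ut_y, f0_logdet_xtx, criterion)
        reml_grid[gi] = ll

    # ties/flat likelihood -> smallest ratio: argmax takes the first maximum
    best = np.argmax(reml_grid, axis=0)

    # parabolic refinement in log-lambda where the optimum is interior
    log_grid = np.log10(grid)
    lam_hat = grid[best]
    interior = (best > 0) & (best < grid_size - 1)
    if interior.any():
        i = best[interior]
        y0 = reml_grid[i - 1, np.where(interior)[0]]
        y1 = reml_grid[i, np.where(interior)[0]]
        y2 = reml_grid[i + 1, np.where(interior)[0]]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        step = log_grid[1] - log_grid[0]
        lam_ref = 10 ** (log_grid[i] + shift * step)
        lam_hat = lam_hat.copy()
        lam_hat[interior] = lam_ref

    beta = np.empty(m)
    se = np.empty(m)
    tstat = np.empty(m)
    log_p = np.empty(m)
    df = n - p
    if df <= 0:
        raise ValueError("not enough samples for the fixed-effect design")
    # final per-marker fit at the refined ratio
    for j in range(m):
        w = 1.0 / (lam_hat[j] * s + 1.0)
        b_j, schur_j, rss_j, _ = _scan_at_lambda(
            w, ut_w, ut_x[:, [j]], ut_y, f0_logdet_xtx[[j]]
        )
        sigma_e2 = rss_j[0] / df
        beta[j] = b_j[0]
        se[j] = np.sqrt(sigma_e2 / schur_j[0])
        tstat[j] = beta[j] / se[j]
        # log-space survival keeps extreme signals finite
        log_p[j] = stats.t.logsf(abs(tstat[j]), df) + np.log(2.0)

    minus_log10_p = -log_p / LOG10
    pvals = np.exp(log_p)
    table = panel.markers[["id", "chrom", "pos"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["wald"] = tstat
    table["p"] = np.clip(pvals, None, 1.0)
    table["minus_log10_p"] = np.maximum(minus_log10_p, 0.0)
    table["var_ratio"] = lam_hat
    return AssociationResult(table)


def ld_r2(
    panel: GenotypePanel, index_markers: list[str], window: int = 50
) -> pd.DataFrame:
    """Composite LD: squared Pearson correlation of dosage vectors between
    each index marker and every marker within ``window`` markers either side.

    Zero-variance pairs are flagged with NaN rather than 0.
    """
    x = mean_impute(panel.dosages)
    ids = panel.markers["id"].tolist()
    id_to_idx = {mid: j for j, mid in enumerate(ids)}
    rows = []
    sd = x.std(axis=0)
    for mid in index_markers:
        if mid not in id_to_idx:
            raise ValueError(f"index marker {mid!r} not in panel")
        j = id_to_idx[mid]
        lo, hi = max(0, j - window), min(panel.n_markers, j + window + 1)
        xi = x[:, j]
        for k in range(lo, hi):
            if sd[j] == 0 or sd[k] == 0:
                r2 = np.nan
            else:
                r = np.corrcoef(xi, x[:, k])[0, 1]
                r2 = r * r
            rows.append((mid, ids[k], int(panel.markers.loc[k, "pos"]), r2))
    return pd.DataFrame(rows, columns=["index_id", "marker_id", "pos", "r2"])


def genotype_pca(panel: GenotypePanel, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the centred dosage matrix: (scores, explained variance)."""
    if panel.n_samples < 2:
        raise ValueError("need at least two samples for PCA")
    x = mean_impute(panel.dosages)
    x = x - x.mean(axis=0)
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    n_components = min(n_components, len(sv))
    scores = u[:, :n_components] * sv[:n_components]
    explained = sv[:n_components] ** 2 / (panel.n_samples - 1)
    return scores, explained


def genomic_inflation(pvals: np.ndarray) -> float:
    """Genomic control lambda: median association chi-square over its null
    median (0.4549). Values near 1 indicate calibrated tests."""
    chi2 = stats.chi2.isf(np.asarray(pvals, dtype=float), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def ols_scan(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
) -> AssociationResult:
    """Naive fixed-effects-only scan (no kinship); the baseline the mixed
    model is judged against under confounded nulls."""
    n = panel.n_samples
    return lmm_scan(panel, phenotype, covariates, np.eye(n), grid_size=2)
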