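"""Kinship-corrected case/control association scan.

The phenotype (0/1) is analysed on the linear scale under the polygenic
model  y ~ N(X beta, sigma^2 (h^2 * 2K + (1 - h^2) I)), fitted by maximum
likelihood with h^2 on a grid refined by golden-section search.  Each
marker is then tested with a 1-df score statistic on the GLS residuals,

    chi^2 = (g' P y)^2 / (g' P g),
    P = S^-1 - S^-1 X (X' S^-1 X)^-1 X' S^-1,   S = fitted covariance,

which reduces exactly to the Armitage trend test when the kinship is zero.
Genome-wide calibration is summarised by the genomic inflation factor
lambda (median chi-square over its null median) and empirical significance
by phenotype-permutation minima plus a Beta order-statistic QQ band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AssociationResult, GenotypeMatrix

_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


@dataclass
class PolygenicFit:
    """Variance-component fit of the polygenic null model."""

    samples: list[str]
    y: np.ndarray
    h2: float
    sigma2: float
    beta: np.ndarray
    covariates: np.ndarray  # design matrix X including intercept
    inverse_covariance: np.ndarray
    residuals: np.ndarray
    fitted_mean: np.ndarray
    loglik: float
    # eigenbasis of 2K, kept for fast rescans/permutations
    _U: np.ndarray = field(repr=False, default=None)
    _D: np.ndarray = field(repr=False, default=None)


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.hstack([X, C])
    return X


def _profile_loglik(
    h2: float, D: np.ndarray, yt: np.ndarray, Xt: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Profile log-likelihood over (beta, sigma^2) at fixed h^2."""
    d = h2 * D + (1.0 - h2)
    if d.min() <= 1e-10:
        return -np.inf, np.zeros(Xt.shape[1]), np.nan
    w = 1.0 / d
    XtW = Xt * w[:, None]
    beta = np.linalg.solve(XtW.T @ Xt, XtW.T @ yt)
    resid = yt - Xt @ beta
    n = yt.size
    sigma2 = float(np.sum(w * resid**2) / n)
    if sigma2 <= 0:
        return -np.inf, beta, np.nan
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + np.sum(np.log(d)) + n)
    return float(ll), beta, sigma2


def fit_polygenic(
    y: np.ndarray,
    K: pd.DataFrame,
    covariates: np.ndarray | None = None,
    grid_step: float = 0.01,
) -> PolygenicFit:
    """Fit the polygenic null model by ML over (beta, sigma^2, h^2).

    h^2 is scanned on [0, 0.99] at ``grid_step`` then refined by
    golden-section search around the best grid point.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    if K.shape != (n, n):
        raise ValueError("kinship does not match phenotype length")

    A = 2.0 * K.to_numpy()
    A = (A + A.T) / 2.0
    D, U = np.linalg.eigh(A)
    yt = U.T @ y
    X = _design(n, covariates)
    Xt = U.T @ X

    grid = np.arange(0.0, 0.99 + 1e-9, grid_step)
    lls = np.array([_profile_loglik(h, D, yt, Xt)[0] for h in grid])
    if not np.isfinite(lls).any():
        raise ValueError("covariance not positive definite anywhere on the grid")
    i = int(np.argmax(lls))
    lo = grid[max(0, i - 1)]
    hi = grid[min(grid.size - 1, i + 1)]

    # golden-section refinement
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - gr * (b - a)
    dd = a + gr * (b - a)
    fc = _profile_loglik(c, D, yt, Xt)[0]
    fd = _profile_loglik(dd, D, yt, Xt)[0]
    for _ in range(60):
        if b - a < 1e-6:
            break
        if fc > fd:
            b, dd, fd = dd, c, fc
            c = b - gr * (b - a)
            fc = _profile_loglik(c, D, yt, Xt)[0]
        else:
            a, c, fc = c, dd, fd
            dd = a + gr * (b - a)
            fd = _profile_loglik(dd, D, yt, Xt)[0]
    h2 = float((a + b) / 2.0)
    ll, beta, sigma2 = _profile_loglik(h2, D, yt, Xt)
    if not np.isfinite(ll):
        h2, (ll, beta, sigma2) = grid[i], _profile_loglik(grid[i], D, yt, Xt)

    d = h2 * D + (1.0 - h2)
    inv_cov = (U / (sigma2 * d)) @ U.T
    fitted = X @ beta
    return PolygenicFit(
        samples=list(K.index),
        y=y,
        h2=h2,
        sigma2=sigma2,
        beta=beta,
        covariates=X,
        inverse_covariance=inv_cov,
        residuals=y - fitted,
        fitted_mean=fitted,
        loglik=ll,
        _U=U,
        _D=D,
    )


def _projection(fit: PolygenicFit) -> np.ndarray:
    """P = S^-1 - S^-1 X (X'S^-1X)^-1 X'S^-1 for the fitted covariance."""
    Vi = fit.inverse_covariance
    X = fit.covariates
    ViX = Vi @ X
    return Vi - ViX @ np.linalg.solve(X.T @ ViX, ViX.T)


def _impute_mean(dosage: np.ndarray) -> np.ndarray:
    d = dosage.copy()
    miss = np.isnan(d)
    if miss.any():
        col_mean = np.nanmean(np.where(miss, np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
    return d


def _scan_statistics(
    Gm: np.ndarray, P: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Score statistics and numerators for all markers (columns of Gm)."""
    Py = P @ y
    num = Gm.T @ Py
    GP = Gm.T @ P
    den = np.einsum("ij,ji->i", GP, Gm)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(den > 1e-12, num**2 / den, 0.0)
    return stat, num


def mm_score_test(G: GenotypeMatrix, fit: PolygenicFit) -> AssociationResult:
    """Score-test every marker against the fitted polygenic null.

    Monomorphic markers get p = 1 with flag "monomorphic"; missing dosages
    are mean-imputed for the test (frequencies are computed on observed
    calls only).
    """
    if list(G.samples) != list(fit.samples):
        raise ValueError("genotype matrix and fit cover different samples")
    Gm = _impute_mean(G.dosage)
    P = _projection(fit)
    stat, num = _scan_statistics(Gm, P, fit.y)

    p_all = G.allele_freq()
    mono = (np.nanstd(G.dosage, axis=0) == 0) | ~np.isfinite(p_all)
    stat = np.where(mono, 0.0, stat)
    pvals = stats.chi2.sf(stat, df=1)
    pvals = np.where(mono, 1.0, pvals)

    case_mask = fit.y == 1
    with np.errstate(invalid="ignore"):
        af_case = np.nanmean(G.dosage[case_mask], axis=0) / 2.0
        af_ctrl = np.nanmean(G.dosage[~case_mask], axis=0) / 2.0
    table = pd.DataFrame(
        {
            "chrom": G.marker_map["chrom"].to_numpy(),
            "pos": G.marker_map["pos"].to_numpy(),
            "stat": stat,
            "p": pvals,
            "direction": np.sign(num).astype(int),
            "maf_all": np.minimum(p_all, 1 - p_all),
            "maf_case": np.minimum(af_case, 1 - af_case),
            "maf_control": np.minimum(af_ctrl, 1 - af_ctrl),
            "flag": np.where(mono, "monomorphic", ""),
        },
        index=G.marker_map.index,
    )
    return AssociationResult(table, extras={"h2": fit.h2, "sigma2": fit.sigma2})


def genomic_lambda(statistics: np.ndarray) -> float:
    """Genomic inflation factor: median chi-square / 0.4549 (1-df null)."""
    s = np.asarray(statistics, dtype=float)
    s = s[np.isfinite(s)]
    if s.size == 0:
        raise ValueError("no finite statistics")
    return float(np.median(s) / _CHI2_MEDIAN_1DF)


@dataclass
class ScanSummary:
    """Genome-wide calibration and significance summary."""

    lambda_gc: float
    empirical_threshold: float
    ci95_band: pd.DataFrame  # per rank: expected, lower, upper
    perm_min_p: np.ndarray


def qq_band(n_markers: int) -> pd.DataFrame:
    """Beta order-statistic 95% band for ranked null p-values."""
    i = np.arange(1, n_markers + 1)
    return pd.DataFrame(
        {
            "rank": i,
            "expected": i / (n_markers + 1.0),
            "lower": stats.beta.ppf(0.025, i, n_markers - i + 1),
            "upper": stats.beta.ppf(0.975, i, n_markers - i + 1),
        }
    )


def empirical_significance(
    G: GenotypeMatrix,
    y: np.ndarray,
    fit: PolygenicFit,
    n_perm: int = 1000,
    seed: int = 0,
) -> ScanSummary:
    """Permutation-based genome-wide threshold plus the QQ confidence band.

    Phenotype labels are permuted ``n_perm`` times; for each permutation the
    score scan is re-run (GLS mean and residual variance refit in the
    eigenbasis at the h^2 fitted on the observed phenotype) and the minimum
    p recorded.  The threshold is the 5th percentile of those minima, i.e.
    the genome-wide alpha = 0.05 level.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")

    Gm = _impute_mean(G.dosage)
    U, D, h2 = fit._U, fit._D, fit.h2
    d = h2 * D + (1.0 - h2)
    X = fit.covariates
    Xt = U.T @ X
    Gt = U.T @ Gm  # n x m in eigenbasis
    w = 1.0 / d
    XtW = Xt * w[:, None]
    XtWX_inv = np.linalg.inv(XtW.T @ Xt)
    GtW = Gt * w[:, None]
    # per-marker denominators g'Pg are permutation-invariant
    gPg = np.einsum("ij,ij->j", GtW, Gt) - np.einsum(
        "ij,ij->j", (XtW @ (XtWX_inv @ (XtW.T @ Gt))), Gt
    )
    gPg = np.maximum(gPg, 1e-12)

    rng = np.random.default_rng(seed)
    n = y.size
    minima = np.empty(n_perm)
    for b in range(n_perm):
        yp = y[rng.permutation(n)]
        ypt = U.T @ yp
        beta = XtWX_inv @ (XtW.T @ ypt)
        resid = ypt - Xt @ beta
        sigma2 = float(np.sum(w * resid**2) / n)
        num = GtW.T @ resid - (GtW.T @ Xt) @ (XtWX_inv @ (XtW.T @ resid))
        stat = num**2 / (gPg * sigma2)
        minima[b] = stats.chi2.sf(stat.max(), df=1)

    observed = mm_score_test(G, fit)
    lam = genomic_lambda(observed.table["stat"].to_numpy())
    threshold = float(np.quantile(minima, 0.05))
    return ScanSummary(
        lambda_gc=lam,
        empirical_threshold=threshold,
        ci95_band=qq_band(G.n_markers),
        perm_min_p=minima,
    )


def conditional_scan(
    G: GenotypeMatrix,
    y: np.ndarray,
    K: pd.DataFrame,
    conditioning_marker: str,
    covariates: np.ndarray | None = None,
) -> AssociationResult:
    """Re-scan with the top marker's dosage as a fixed covariate.

    Tests whether the rest of the locus carries signal independent of the
    conditioning marker; the marker itself is reported with p = 1 and flag
    "self-conditioning".
    """
    if conditioning_marker not in G.marker_map.index:
        raise ValueError(f"conditioning marker {conditioning_marker!r} not found")
    g_cond = _impute_mean(G.dosage_of(conditioning_marker)[:, None]).ravel()
    if np.ptp(g_cond) == 0:
        raise ValueError("conditioning marker is monomorphic")
    C = (
        g_cond[:, None]
        if covariates is None
        else np.hstack([np.atleast_2d(covariates).reshape(len(y), -1), g_cond[:, None]])
    )
    fit = fit_polygenic(y, K, covariates=C)
    res = mm_score_test(G, fit)
    res.table.loc[conditioning_marker, ["stat", "p", "flag"]] = [
        0.0,
        1.0,
        "self-conditioning",
    ]
    return res
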