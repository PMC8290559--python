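"""Core two-sample MR estimators and heterogeneity diagnostics.

All estimators consume a :class:`~mrexposome.harmonize.HarmonizedSet` whose
per-SNP records (beta_x, se_x, beta_y, se_y) are aligned to the exposure's
effect allele, and return :class:`MREstimate` objects on the log-OR (or
outcome-unit) scale with 95% CIs exponentiated to odds ratios.

Methods
-------
ivw
    Inverse-variance-weighted estimate: weighted regression of beta_y on
    beta_x through the origin with weights 1/se_y^2.  Reported under a
    multiplicative random-effects model: SE = fixed-effect SE scaled by
    sqrt(Q/(J-1)) when Cochran's Q exceeds its degrees of freedom (never
    deflated below the fixed-effect SE); normal p-value.
egger
    Weighted regression with an intercept after orienting all beta_x >= 0;
    the slope is the causal estimate, the intercept estimates average
    directional pleiotropy.  SEs scaled by max(1, residual SD); t p-values
    with J-2 df.
weighted_median
    Weighted median of the per-SNP Wald ratios; consistent when up to half
    of the instrument weight is invalid.  SE by parametric bootstrap.
mvmr
    Multivariable MR: joint weighted regression of beta_y on K exposures'
    betas (no intercept), giving direct (conditional) effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import CollinearityError, DomainError, InsufficientInstrumentsError
from .harmonize import HarmonizedSet

Z95 = 1.96


@dataclass
class MREstimate:
    """One method's causal estimate on the log-OR scale."""

    method: str
    beta_hat: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity test for the Wald ratios."""

    q_stat: float
    df: int
    pval: float


def _estimate(method: str, beta: float, se: float, n_snps: int,
              t_df: int | None = None) -> MREstimate:
    beta, se = float(beta), float(se)
    if t_df is not None:
        p = 2.0 * sps.t.sf(abs(beta) / se, t_df) if se > 0 else 0.0
    else:
        p = 2.0 * sps.norm.sf(abs(beta) / se) if se > 0 else 0.0
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return MREstimate(
        method=method,
        beta_hat=beta,
        se=se,
        or_point=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        pval=float(p),
        n_snps=n_snps,
    )


def _arrays(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    r = h.records
    return (
        r["beta_x"].to_numpy(float),
        r["se_x"].to_numpy(float),
        r["beta_y"].to_numpy(float),
        r["se_y"].to_numpy(float),
    )


def wald_ratios(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratios theta_j = beta_y/beta_x with first-order delta
    SE se_y/|beta_x| and inverse-variance weights."""
    bx, _, by, sy = _arrays(h)
    if (bx == 0).any():
        bad = h.records.loc[bx == 0, "snp_id"].iloc[0]
        raise DomainError(f"wald_ratios: beta_x is zero for {bad!r}")
    theta = by / bx
    se = sy / np.abs(bx)
    return pd.DataFrame(
        {
            "snp_id": h.records["snp_id"],
            "theta": theta,
            "se": se,
            "w": 1.0 / se**2,
        }
    )


def cochran_q(ratios: pd.DataFrame, theta_hat: float) -> HeterogeneityResult:
    """Cochran's Q = sum w_j (theta_j - theta_hat)^2, chi-square on J-1 df."""
    if len(ratios) < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs at least 2 SNPs")
    q = float(np.sum(ratios["w"] * (ratios["theta"] - theta_hat) ** 2))
    df = len(ratios) - 1
    return HeterogeneityResult(q_stat=q, df=df, pval=float(sps.chi2.sf(q, df)))


def ivw(h: HarmonizedSet) -> tuple[MREstimate, HeterogeneityResult]:
    """Inverse-variance-weighted estimate with multiplicative random effects.

    theta_hat = sum(bx by / sy^2) / sum(bx^2 / sy^2); the fixed-effect SE
    (sum bx^2/sy^2)^{-1/2} is scaled by sqrt(Q/(J-1)) when Q/(J-1) > 1.
    """
    bx, _, by, sy = _arrays(h)
    j = len(bx)
    if j < 2:
        raise InsufficientInstrumentsError(f"IVW needs >= 2 SNPs, got {j}")
    w = 1.0 / sy**2
    sxx = float(np.sum(bx**2 * w))
    theta_hat = float(np.sum(bx * by * w)) / sxx
    se_fixed = sxx**-0.5
    ratios = wald_ratios(h)
    het = cochran_q(ratios, theta_hat)
    scale = max(1.0, np.sqrt(het.q_stat / het.df))
    return _estimate("ivw", theta_hat, se_fixed * scale, j), het


def egger(h: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: returns (slope estimate, intercept estimate).

    SNPs are oriented so beta_x >= 0; betas regressed with weights 1/se_y^2.
    """
    bx, _, by, sy = _arrays(h)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 SNPs, got {j}")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise CollinearityError("all beta_x identical after orientation")
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(j), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (j - 2)
    scale = max(1.0, np.sqrt(sigma2))
    cov_unit = np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov_unit)) * scale
    slope = _estimate("egger_slope", coef[1], se[1], j, t_df=j - 2)
    intercept = _estimate("egger_intercept", coef[0], se[0], j, t_df=j - 2)
    return slope, intercept


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: cumulative-weight midpoints vs theta."""
    order = np.argsort(theta, kind="stable")
    t, ww = theta[order], w[order]
    ww = ww / ww.sum()
    p = np.cumsum(ww) - ww / 2.0
    return float(np.interp(0.5, p, t))


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MREstimate:
    """Weighted-median estimate; SE from a parametric bootstrap drawing
    beta_x* ~ N(beta_x, se_x), beta_y* ~ N(beta_y, se_y)."""
    bx, sx, by, sy = _arrays(h)
    j = len(bx)
    if j < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 SNPs, got {j}")
    if seed is None:
        raise DomainError("weighted_median requires an explicit seed")
    theta = by / bx
    w = bx**2 / sy**2
    point = _weighted_median_point(theta, w)

    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, j))
    bys = rng.normal(by, sy, size=(n_boot, j))
    bxs[bxs == 0] = np.finfo(float).tiny
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = _weighted_median_point(bys[i] / bxs[i], bxs[i] ** 2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _estimate("weighted_median", point, se, j)


def mvmr(
    beta_x: np.ndarray | pd.DataFrame,
    beta_y: np.ndarray,
    se_y: np.ndarray,
    exposure_ids: list[str] | None = None,
) -> list[MREstimate]:
    """Multivariable MR: weighted no-intercept regression of beta_y on a
    J x K matrix of exposure betas; per-exposure conditional estimates with
    t p-values on J-K df and SEs scaled by max(1, residual SD)."""
    if isinstance(beta_x, pd.DataFrame):
        if exposure_ids is None:
            exposure_ids = [str(c) for c in beta_x.columns]
        beta_x = beta_x.to_numpy(float)
    X = np.atleast_2d(np.asarray(beta_x, float))
    y = np.asarray(beta_y, float)
    sy = np.asarray(se_y, float)
    j, k = X.shape
    if k < 1:
        raise DomainError("mvmr needs at least one exposure column")
    if j <= k:
        raise InsufficientInstrumentsError(f"mvmr needs J > K (J={j}, K={k})")
    if exposure_ids is None:
        exposure_ids = [f"exposure_{i}" for i in range(k)]
    if np.linalg.matrix_rank(X) < k:
        raise CollinearityError(
            f"exposure beta matrix is rank deficient (rank < {k}); "
            "some exposures are linearly dependent"
        )
    w = 1.0 / sy**2
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (j - k)
    scale = max(1.0, np.sqrt(sigma2))
    se = np.sqrt(np.diag(np.linalg.inv(xtwx))) * scale
    return [
        _estimate(f"mvmr:{exposure_ids[i]}", coef[i], se[i], j, t_df=j - k)
        for i in range(k)
    ]
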