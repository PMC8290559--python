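"""MR-PRESSO: pleiotropy residual sum and outlier test.

The global test compares the observed residual sum of squares (RSS) of the
harmonized instruments against its parametric-simulation distribution under
the no-pleiotropy model.  Residuals are computed against leave-one-out IVW
fits so an outlying SNP cannot mask itself, and standardized by se_y for
scale invariance across SNPs.  Per-SNP empirical p-values are Bonferroni
adjusted by the number of instruments; SNPs with adjusted p < 0.05 are
outliers, and an outlier-corrected IVW estimate is reported on the retained
set.  Empirical p-values use the add-one rule, so they are never below
1/(n_sim + 1).

Each SNP draws its simulation noise from a private random substream keyed by
its identifier, which makes the test reproducible and invariant to SNP
order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .estimators import MREstimate, ivw
from .exceptions import ConfigurationError, InsufficientInstrumentsError
from .harmonize import HarmonizedSet

OUTLIER_ALPHA = 0.05


@dataclass
class PressoResult:
    """MR-PRESSO global test, per-SNP outlier tests, corrected estimate."""

    rss_obs: float
    global_p: float
    n_sim: int
    per_snp: pd.DataFrame  # snp_id, p_raw, p_adj
    outliers: list[str]
    corrected: MREstimate | None


def _loo_thetas(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorized over the left-out SNP."""
    w = 1.0 / sy**2
    sxy = np.sum(bx * by * w)
    sxx = np.sum(bx**2 * w)
    return (sxy - bx * by * w) / (sxx - bx**2 * w)


def _snp_rng(seed: int, snp_id: str) -> np.random.Generator:
    key = zlib.crc32(str(snp_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def presso_test(
    h: HarmonizedSet, n_sim: int = 1000, seed: int | None = None
) -> PressoResult:
    """Run the MR-PRESSO global and outlier tests.

    For each SNP j: r_j = (beta_y_j - theta_loo_j * beta_x_j) / se_y_j with
    theta_loo_j the IVW estimate excluding j; RSS_obs = sum r_j^2.  Each of
    n_sim replicates redraws beta_x* ~ N(beta_x, se_x) and
    beta_y* ~ N(theta_loo * beta_x, se_y) and recomputes RSS* the same way.
    """
    if seed is None:
        raise ConfigurationError("presso_test requires an explicit seed")
    if n_sim < 100:
        raise ConfigurationError(f"n_sim must be >= 100, got {n_sim}")
    bx, sx, by, sy = (
        h.records["beta_x"].to_numpy(float),
        h.records["se_x"].to_numpy(float),
        h.records["beta_y"].to_numpy(float),
        h.records["se_y"].to_numpy(float),
    )
    j = len(bx)
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO needs >= 4 SNPs, got {j}")

    theta_loo = _loo_thetas(bx, by, sy)
    r_obs = (by - theta_loo * bx) / sy
    rss_obs = float(np.sum(r_obs**2))

    # per-SNP substreams keyed by snp_id: reproducible and order-invariant
    bxs = np.empty((n_sim, j))
    bys = np.empty((n_sim, j))
    for col, snp in enumerate(h.records["snp_id"]):
        rng = _snp_rng(seed, snp)
        bxs[:, col] = rng.normal(bx[col], sx[col], n_sim)
        bys[:, col] = rng.normal(theta_loo[col] * bx[col], sy[col], n_sim)

    w = 1.0 / sy**2
    sxy_s = (bxs * bys * w).sum(axis=1, keepdims=True)
    sxx_s = (bxs**2 * w).sum(axis=1, keepdims=True)
    theta_loo_s = (sxy_s - bxs * bys * w) / (sxx_s - bxs**2 * w)
    r_sim = (bys - theta_loo_s * bxs) / sy
    rss_sim = (r_sim**2).sum(axis=1)

    global_p = (np.sum(rss_sim >= rss_obs) + 1.0) / (n_sim + 1.0)
    p_raw = (np.sum(r_sim**2 >= r_obs**2, axis=0) + 1.0) / (n_sim + 1.0)
    p_adj = np.minimum(1.0, p_raw * j)
    per_snp = pd.DataFrame(
        {"snp_id": h.records["snp_id"], "p_raw": p_raw, "p_adj": p_adj}
    )
    outliers = per_snp.loc[per_snp["p_adj"] < OUTLIER_ALPHA, "snp_id"].tolist()

    corrected = None
    if outliers and j - len(outliers) >= 2:
        corrected = presso_corrected(h, outliers)

    return PressoResult(
        rss_obs=rss_obs,
        global_p=float(global_p),
        n_sim=n_sim,
        per_snp=per_snp,
        outliers=outliers,
        corrected=corrected,
    )


def presso_corrected(h: HarmonizedSet, outliers) -> MREstimate:
    """IVW on the instruments that remain after removing ``outliers``."""
    outliers = set(outliers)
    unknown = outliers - set(h.records["snp_id"])
    if unknown:
        raise ConfigurationError(f"outliers not in harmonized set: {sorted(unknown)}")
    keep = ~h.records["snp_id"].isin(outliers)
    if int(keep.sum()) < 2:
        raise InsufficientInstrumentsError(
            "fewer than 2 instruments remain after outlier removal"
        )
    trimmed = replace(h, records=h.records.loc[keep].reset_index(drop=True))
    est, _ = ivw(trimmed)
    return replace(est, method="presso_corrected")
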