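"""Synthetic GWAS summary statistics with known causal ground truth.

The generator makes the standard two-sample MR data-generating model
generative.  For each SNP j an instrument effect gamma_j ~ N(0, sigma_gamma^2)
(truncated away from zero so selected instruments clear genome-wide
significance in desk-scale runs), an observed exposure effect
beta_x_j ~ N(gamma_j, se_x^2), a pleiotropic effect alpha_j per regime, and
an observed outcome effect beta_y_j ~ N(theta * gamma_j + alpha_j, se_y^2).
Pleiotropy regimes cover balanced (mean-zero alpha), directional (nonzero
mean), InSIDE-violating (alpha correlated with gamma), and planted per-SNP
outliers.

The exposome generator scales this to many independent exposures, a small
causal fraction, and two binary longevity-like outcomes (a primary one and a
secondary one with fewer cases and hence larger standard errors), emitting a
truth table for scoring.  A master seed spawns one substream per exposure so
any single exposure is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, DomainError
from .instruments import LDMatrix
from .sumstats import PVAL_FLOOR, VARIANT_COLUMNS, SummaryStats

#: Non-palindromic ordered allele pairs; default SNPs avoid strand ambiguity
#: so harmonization keeps every instrument (palindrome handling is exercised
#: with explicitly constructed variants).
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]

# emulated sample sizes: exposure GWAS cohort and the two longevity outcomes
# (cases surviving past the 90th / 99th percentile age plus shared controls)
N_EXPOSURE = 361_194
N_CONTROLS = 25_483
N_CASES_P90 = 11_262
N_CASES_P99 = 3_484


@dataclass
class SimTruth:
    """Ground-truth parameters of one simulated exposure-outcome pair."""

    theta: float
    sigma_gamma: float
    seed: int
    sigma_alpha: float = 0.0
    mu_alpha: float = 0.0
    inside_violation: bool = False
    outlier_ids: dict = field(default_factory=dict)
    case_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_gamma <= 0:
            raise DomainError(f"sigma_gamma must be > 0, got {self.sigma_gamma}")
        if self.sigma_alpha == 0.0 and self.mu_alpha != 0.0:
            raise ConfigurationError(
                "directional pleiotropy (mu_alpha != 0) requires a pleiotropy "
                "regime (sigma_alpha > 0)"
            )
        if self.sigma_alpha < 0:
            raise DomainError(f"sigma_alpha must be >= 0, got {self.sigma_alpha}")


class PairSim(NamedTuple):
    exposure: SummaryStats
    outcome: SummaryStats
    ld: LDMatrix


class LinearBinarySim(NamedTuple):
    linear: SummaryStats  # stored on the raw linear scale (binary_linear)
    logodds: SummaryStats  # the underlying log-OR-scale dataset


class ExposomeSim(NamedTuple):
    exposures: list
    outcomes: dict
    truth: pd.DataFrame


def _truncated_gamma(
    rng: np.random.Generator, j: int, sigma: float, floor: float
) -> np.ndarray:
    """Half-normal(sigma) draws with gamma > floor.

    Instrument effects are oriented to the exposure-increasing allele (the
    conventional coding in MR simulation studies: it gives directional
    pleiotropy a consistent direction relative to the instruments) and
    truncated away from zero for instrument relevance.
    """
    g = np.abs(rng.normal(0.0, sigma, j))
    while True:
        bad = g <= floor
        if not bad.any():
            return g
        g[bad] = np.abs(rng.normal(0.0, sigma, int(bad.sum())))


def _pleiotropy(
    rng: np.random.Generator, truth: SimTruth, gamma: np.ndarray
) -> np.ndarray:
    j = len(gamma)
    alpha = np.zeros(j)
    if truth.sigma_alpha > 0:
        z = rng.normal(size=j)
        if truth.inside_violation:
            # alpha correlated (rho = 0.7) with the instrument effects
            corr = 0.7 * gamma / truth.sigma_gamma
            alpha = truth.mu_alpha + truth.sigma_alpha * (
                corr + np.sqrt(1 - 0.7**2) * z
            )
        else:
            alpha = truth.mu_alpha + truth.sigma_alpha * z
    for idx, magnitude in truth.outlier_ids.items():
        alpha[int(idx)] += magnitude
    return alpha


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(beta) / se)
    return np.clip(p, PVAL_FLOOR, 1.0)


def _variant_frame(
    snp_ids: list[str],
    beta: np.ndarray,
    se: np.ndarray,
    eaf: np.ndarray,
    alleles: list[tuple[str, str]],
    n: int,
) -> pd.DataFrame:
    j = len(snp_ids)
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": np.arange(1, j + 1) * 1000,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _pvals(beta, np.asarray(se, float)),
            "n": n,
        },
        columns=VARIANT_COLUMNS,
    )


def simulate_pair(
    truth: SimTruth,
    j_snps: int,
    se_x: float = 0.004,
    se_y: float = 0.01,
    *,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    snp_prefix: str = "rs",
    n_exposure: int = N_EXPOSURE,
    n_outcome: int = N_CASES_P90 + N_CONTROLS,
    n_outcome_cases: int = N_CASES_P90,
) -> PairSim:
    """Simulate one exposure / outcome summary-statistics pair.

    Instrument effects are truncated at |gamma| > 2 se_x; the returned LD
    matrix is the identity (the screen clumps to near-independence anyway).
    """
    if j_snps < 4:
        raise DomainError(f"j_snps must be >= 4, got {j_snps}")
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed))

    gamma = _truncated_gamma(rng, j_snps, truth.sigma_gamma, 2.0 * se_x)
    alpha = _pleiotropy(rng, truth, gamma)
    sx = np.full(j_snps, se_x)
    sy = np.full(j_snps, se_y)
    bx = rng.normal(gamma, sx)
    by = rng.normal(truth.theta * gamma + alpha, sy)
    eaf = rng.uniform(0.05, 0.95, j_snps)
    alleles = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), j_snps)]
    snp_ids = [f"{snp_prefix}{i:04d}" for i in range(j_snps)]

    exposure = SummaryStats(
        trait_id=exposure_id,
        trait_type="quantitative",
        variants=_variant_frame(snp_ids, bx, sx, eaf, alleles, n_exposure),
        n_total=n_exposure,
    )
    outcome = SummaryStats(
        trait_id=outcome_id,
        trait_type="binary_logistic",
        variants=_variant_frame(snp_ids, by, sy, eaf, alleles, n_outcome),
        n_total=n_outcome,
        n_cases=n_outcome_cases,
    )
    return PairSim(exposure, outcome, LDMatrix.identity(snp_ids))


def simulate_linear_binary(
    truth: SimTruth,
    j_snps: int,
    mu: float,
    se_x: float = 0.004,
    *,
    exposure_id: str = "binary_exposure",
    snp_prefix: str = "rs",
    n_exposure: int = N_EXPOSURE,
) -> LinearBinarySim:
    """Simulate a binary exposure analysed on the linear scale.

    Effects are generated on the log-OR scale and stored multiplied by
    mu (1 - mu), so :func:`~mrexposome.sumstats.linear_to_logodds` recovers
    the underlying log-OR dataset exactly.
    """
    if not 0.0 < mu < 1.0:
        raise DomainError(f"mu must be in (0,1), got {mu}")
    rng = np.random.default_rng(np.random.SeedSequence(truth.seed))
    gamma = _truncated_gamma(rng, j_snps, truth.sigma_gamma, 2.0 * se_x)
    sx = np.full(j_snps, se_x)
    bx = rng.normal(gamma, sx)
    eaf = rng.uniform(0.05, 0.95, j_snps)
    alleles = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), j_snps)]
    snp_ids = [f"{snp_prefix}{i:04d}" for i in range(j_snps)]

    logodds = SummaryStats(
        trait_id=exposure_id,
        trait_type="binary_logistic",
        variants=_variant_frame(snp_ids, bx, sx, eaf, alleles, n_exposure),
        n_total=n_exposure,
        n_cases=round(mu * n_exposure),
    )
    scale = mu * (1.0 - mu)
    linear_variants = logodds.variants.copy()
    linear_variants["beta"] = linear_variants["beta"] * scale
    linear_variants["se"] = linear_variants["se"] * scale
    linear = SummaryStats(
        trait_id=exposure_id,
        trait_type="binary_linear",
        variants=linear_variants,
        n_total=n_exposure,
        case_fraction=mu,
        n_cases=round(mu * n_exposure),
    )
    return LinearBinarySim(linear, logodds)


def simulate_exposome(
    e_exposures: int = 200,
    causal_fraction: float = 0.1,
    *,
    effect_size: float = 0.35,
    j_snps: int = 30,
    se_x: float = 0.004,
    sigma_gamma: float = 0.05,
    se_y_primary: float = 0.01,
    se_y_secondary: float = 0.018,
    binary_linear_fraction: float = 0.25,
    seed: int = 0,
) -> ExposomeSim:
    """Simulate a many-exposure screen with a small causal fraction.

    Exactly ``round(e_exposures * causal_fraction)`` exposures receive a
    causal effect of magnitude ``effect_size`` (log-OR per exposure SD,
    random sign); the rest are null.  Two outcome datasets share the causal
    structure: the primary (90th-percentile-like) outcome and a secondary
    (99th-percentile-like) one whose larger per-SNP standard errors emulate
    its smaller case count.  A ``binary_linear_fraction`` of exposures is
    stored on the raw linear scale to exercise the log-OR conversion.
    """
    if e_exposures < 10:
        raise DomainError(f"e_exposures must be >= 10, got {e_exposures}")
    if not 0.0 <= causal_fraction <= 1.0:
        raise DomainError(f"causal_fraction must be in [0,1], got {causal_fraction}")

    master = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    n_causal = round(e_exposures * causal_fraction)
    causal = np.zeros(e_exposures, bool)
    causal[master.permutation(e_exposures)[:n_causal]] = True
    thetas = np.where(
        causal, effect_size * master.choice([-1.0, 1.0], e_exposures), 0.0
    )
    is_binary = master.uniform(size=e_exposures) < binary_linear_fraction

    exposures: list[SummaryStats] = []
    out_frames = {"p90": [], "p99": []}
    truth_rows = []
    for i in range(e_exposures):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1, i]))
        eid = f"exposure_{i:04d}"
        gamma = _truncated_gamma(rng, j_snps, sigma_gamma, 2.0 * se_x)
        bx = rng.normal(gamma, se_x)
        by90 = rng.normal(thetas[i] * gamma, se_y_primary)
        by99 = rng.normal(thetas[i] * gamma, se_y_secondary)
        eaf = rng.uniform(0.05, 0.95, j_snps)
        alleles = [
            _ALLELE_PAIRS[k] for k in rng.integers(0, len(_ALLELE_PAIRS), j_snps)
        ]
        snp_ids = [f"rs{i:04d}_{j:02d}" for j in range(j_snps)]

        mu = None
        n_cases = None
        trait_type = "quantitative"
        exp_beta, exp_se = bx, np.full(j_snps, se_x)
        if is_binary[i]:
            trait_type = "binary_linear"
            mu = float(rng.uniform(0.1, 0.5))
            n_cases = round(mu * N_EXPOSURE)
            exp_beta = bx * mu * (1.0 - mu)
            exp_se = exp_se * mu * (1.0 - mu)
        exposures.append(
            SummaryStats(
                trait_id=eid,
                trait_type=trait_type,
                variants=_variant_frame(
                    snp_ids, exp_beta, exp_se, eaf, alleles, N_EXPOSURE
                ),
                n_total=N_EXPOSURE,
                case_fraction=mu,
                n_cases=n_cases,
            )
        )
        out_frames["p90"].append(
            _variant_frame(snp_ids, by90, np.full(j_snps, se_y_primary),
                           eaf, alleles, N_CASES_P90 + N_CONTROLS)
        )
        out_frames["p99"].append(
            _variant_frame(snp_ids, by99, np.full(j_snps, se_y_secondary),
                           eaf, alleles, N_CASES_P99 + N_CONTROLS)
        )
        truth_rows.append(
            {
                "exposure_id": eid,
                "theta": thetas[i],
                "causal": bool(causal[i]),
                "trait_type": trait_type,
                "case_fraction": mu,
            }
        )

    outcomes = {
        "p90": SummaryStats(
            trait_id="longevity_p90",
            trait_type="binary_logistic",
            variants=pd.concat(out_frames["p90"], ignore_index=True),
            n_total=N_CASES_P90 + N_CONTROLS,
            n_cases=N_CASES_P90,
        ),
        "p99": SummaryStats(
            trait_id="longevity_p99",
            trait_type="binary_logistic",
            variants=pd.concat(out_frames["p99"], ignore_index=True),
            n_total=N_CASES_P99 + N_CONTROLS,
            n_cases=N_CASES_P99,
        ),
    }
    return ExposomeSim(exposures, outcomes, pd.DataFrame(truth_rows))


def block_ld_matrix(
    snp_ids: list[str], block_size: int, r2_within: float = 1.0
) -> LDMatrix:
    """Block-diagonal LD: consecutive SNPs share r^2 = r2_within within
    blocks of ``block_size`` and r^2 = 0 across blocks (for clump testing)."""
    j = len(snp_ids)
    m = np.zeros((j, j))
    for start in range(0, j, block_size):
        stop = min(start + block_size, j)
        m[start:stop, start:stop] = r2_within
    np.fill_diagonal(m, 1.0)
    return LDMatrix(list(snp_ids), m)
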