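"""Instrument selection: eligibility, genome-wide filtering, LD clumping,
instrument strength (F-statistic) and statistical power.

The screen only analyses exposures with at least ``min_snps`` independent
genome-wide-significant SNPs (default 3) and, for categorical exposures,
at least ``min_cases`` cases (default 250).  Candidate instruments are
SNPs with p < 5e-8 and MAF > 0.01, pruned to pairwise r^2 < 0.001 by
greedy p-value-ordered clumping against a user-supplied LD matrix.

Instrument strength is summarised by F = ((n-k-1)/k) * (R^2/(1-R^2)) with
R^2 the summed variance explained, and power for a binary outcome by the
normal-approximation closed form
``power = Phi(sqrt(n r^2 mu(1-mu)) |log OR| - z_{1-alpha/2})``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, DomainError
from .sumstats import SummaryStats

logger = logging.getLogger(__name__)

F_STRONG_THRESHOLD = 10.0


@dataclass
class InstrumentDiagnostics:
    """Instrument-strength and power summary for one exposure."""

    r2_total: float
    k: int
    n: int
    f_stat: float
    strong: bool
    power: float
    f_stat_mean_per_snp: float | None = None


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r^2) matrix over named SNPs."""

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        m = self.r2
        if m.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ConfigurationError("LD matrix shape does not match snp_ids")
        if not np.allclose(np.diag(m), 1.0):
            raise ConfigurationError("LD matrix diagonal must be 1")
        if not np.array_equal(m, m.T):
            raise ConfigurationError("LD matrix must be exactly symmetric")
        if (m < 0).any() or (m > 1).any():
            raise ConfigurationError("LD r^2 values must lie in [0,1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def lookup(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    @classmethod
    def identity(cls, snp_ids: list[str]) -> "LDMatrix":
        return cls(list(snp_ids), np.eye(len(snp_ids)))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = [str(c) for c in df.columns]
        if [str(i) for i in df.index] != ids:
            raise ConfigurationError(f"{path}: row and column snp_ids differ")
        return cls(ids, df.to_numpy(dtype=float))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(
            path, sep="\t", float_format="%.17g"
        )


def exposure_eligible(
    stats: SummaryStats,
    n_independent_snps: int,
    min_cases: int = 250,
    min_snps: int = 3,
) -> tuple[bool, str]:
    """Eligibility of an exposure for the screen.

    Binary exposures need at least ``min_cases`` cases; every exposure needs
    at least ``min_snps`` independent genome-wide-significant instruments
    (counted after clumping).
    """
    if stats.is_binary and stats.n_cases is not None and stats.n_cases < min_cases:
        return False, "too_few_cases"
    if n_independent_snps < min_snps:
        return False, "too_few_instruments"
    return True, "ok"


def select_instruments(
    stats: SummaryStats, p_max: float = 5e-8, maf_min: float = 0.01
) -> pd.DataFrame:
    """Candidate instruments: p < p_max and MAF strictly above maf_min."""
    v = stats.variants
    maf = np.minimum(v["eaf"], 1.0 - v["eaf"])
    keep = (v["pval"] < p_max) & (maf > maf_min)
    return v.loc[keep.fillna(False)].reset_index(drop=True)


def clump(
    candidates: pd.DataFrame,
    ld: LDMatrix | None,
    r2_max: float = 0.001,
    *,
    warn_missing_ld: bool = True,
) -> pd.DataFrame:
    """Greedy LD clumping keeping the most significant SNP of each clump.

    Repeatedly emit the remaining SNP with the smallest p-value (ties broken
    by lexicographically smaller snp_id) and discard all remaining SNPs with
    r^2 >= r2_max to it.  With ``ld=None`` all pairwise r^2 are assumed 0
    (i.e. no pruning) and a loud warning is logged.
    """
    if candidates.empty:
        return candidates.reset_index(drop=True)
    if ld is None:
        if warn_missing_ld:
            logger.warning(
                "clump: no LD matrix supplied; assuming all pairwise r^2 = 0 "
                "(no pruning applied)"
            )
        return candidates.reset_index(drop=True)
    missing = [s for s in candidates["snp_id"] if s not in ld._index]
    if missing:
        raise ConfigurationError(f"candidates missing from LD matrix: {missing}")

    order = candidates.sort_values(
        ["pval", "snp_id"], kind="mergesort"
    ).index.to_list()
    idx = {s: ld._index[s] for s in candidates["snp_id"]}
    kept: list = []
    removed: set = set()
    for i in order:
        if i in removed:
            continue
        kept.append(i)
        row = ld.r2[idx[candidates.at[i, "snp_id"]]]
        for j in order:
            if j not in removed and j != i:
                if row[idx[candidates.at[j, "snp_id"]]] >= r2_max:
                    removed.add(j)
    kept_set = set(kept)
    keep_mask = [i in kept_set for i in candidates.index]
    return candidates.loc[keep_mask].reset_index(drop=True)


def variance_explained(instruments: pd.DataFrame) -> float:
    """Summed variance explained R^2 = sum 2 p (1-p) beta^2 on a
    standardized trait; capped just below 1."""
    if instruments["eaf"].isna().any():
        bad = instruments.loc[instruments["eaf"].isna(), "snp_id"].iloc[0]
        raise ConfigurationError(f"variance_explained: missing eaf for {bad!r}")
    p = instruments["eaf"].to_numpy(float)
    b = instruments["beta"].to_numpy(float)
    r2 = float(np.sum(2.0 * p * (1.0 - p) * b * b))
    return min(r2, 1.0 - 1e-12)


def f_statistic(r2: float, n: int, k: int) -> tuple[float, bool]:
    """Joint instrument F-statistic and the strong-instrument flag (F > 10).

    F = ((n - k - 1) / k) * (R^2 / (1 - R^2)).
    """
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if not 0.0 <= r2 < 1.0:
        raise DomainError(f"R^2 must be in [0,1), got {r2}")
    if n <= k + 1:
        raise DomainError(f"need n > k + 1 (n={n}, k={k})")
    f = ((n - k - 1) / k) * (r2 / (1.0 - r2))
    return f, f > F_STRONG_THRESHOLD


def power_binary(
    n: int,
    case_fraction: float,
    r2: float,
    or_hyp: float,
    alpha: float = 0.05,
) -> float:
    """Two-sided power to detect a hypothesized OR with a binary outcome.

    Normal-approximation closed form:
    power = Phi( sqrt(n r^2 mu(1-mu)) |log OR| - z_{1-alpha/2} ).
    At OR = 1 this leaves only one rejection tail, alpha/2.
    """
    if not 0.0 < case_fraction < 1.0:
        raise DomainError(f"case_fraction must be in (0,1), got {case_fraction}")
    if not 0.0 <= r2 < 1.0:
        raise DomainError(f"R^2 must be in [0,1), got {r2}")
    if or_hyp <= 0:
        raise DomainError(f"or_hyp must be positive, got {or_hyp}")
    z_crit = sps.norm.ppf(1.0 - alpha / 2.0)
    ncp = np.sqrt(n * r2 * case_fraction * (1.0 - case_fraction)) * abs(np.log(or_hyp))
    return float(sps.norm.cdf(ncp - z_crit))


def diagnose_instruments(
    instruments: pd.DataFrame,
    n_exposure: int,
    *,
    outcome_n: int | None = None,
    outcome_case_fraction: float | None = None,
    or_hyp: float = 0.8,
    alpha: float = 0.05,
) -> InstrumentDiagnostics:
    """Bundle R^2, joint F (primary), mean per-SNP F, and power."""
    k = len(instruments)
    r2 = variance_explained(instruments)
    f, strong = f_statistic(r2, n_exposure, k)
    # mean per-SNP F from each SNP's own variance explained, k=1 each
    per_snp = [
        f_statistic(min(r, 1 - 1e-12), n_exposure, 1)[0]
        for r in 2.0 * instruments["eaf"] * (1 - instruments["eaf"])
        * instruments["beta"] ** 2
    ]
    power = np.nan
    if outcome_n is not None and outcome_case_fraction is not None:
        power = power_binary(outcome_n, outcome_case_fraction, r2, or_hyp, alpha)
    return InstrumentDiagnostics(
        r2_total=r2,
        k=k,
        n=n_exposure,
        f_stat=f,
        strong=strong,
        power=float(power),
        f_stat_mean_per_snp=float(np.mean(per_snp)) if per_snp else None,
    )
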