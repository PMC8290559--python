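"""Exposome-wide screen orchestration.

Per exposure x outcome the pipeline runs: duplicate removal, eligibility
(case count, instrument count), instrument selection and LD clumping,
allele harmonization, linear-scale-to-log-OR conversion for binary-linear
exposures, IVW/MR-Egger/weighted-median/MR-PRESSO estimation with seeded
per-exposure substreams, instrument diagnostics, Benjamini-Hochberg FDR over
all eligible exposures within each outcome, tier classification, and a
sign-concordance check across sensitivity analyses.  A validation stage
merges an independent-exposure re-screen to classify robust exposures as
components of the longevity exposome.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import estimators, harmonize, instruments, presso
from .estimators import MREstimate
from .exceptions import (
    CollinearityError,
    ConfigurationError,
    DomainError,
    HarmonizationError,
)
from .instruments import InstrumentDiagnostics, LDMatrix
from .presso import PressoResult
from .sumstats import SummaryStats, linear_to_logodds

logger = logging.getLogger(__name__)

TIERS = ("significant", "suggestive", "null")


@dataclass
class ScreenConfig:
    """All thresholds of the screen; defaults follow the study design."""

    seed: int
    p_max: float = 5e-8
    maf_min: float = 0.01
    r2_max: float = 0.001
    palindromic_maf_max: float = 0.42
    eaf_tolerance: float = 0.2
    min_cases: int = 250
    min_snps: int = 3
    fdr_alpha: float = 0.05
    suggestive_alpha: float = 0.05
    alpha_power: float = 0.05
    power_or_hyp: float = 0.8
    presso_nsim: int = 1000
    wm_nboot: int = 1000
    power_threshold_validation: float = 0.8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("ScreenConfig requires a seed")
        for name in ("p_max", "maf_min", "fdr_alpha", "suggestive_alpha",
                     "alpha_power"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0,1), got {v}")


@dataclass
class ScreenRecord:
    """Everything the screen knows about one exposure x outcome pair."""

    exposure_id: str
    outcome: str
    category: str = ""
    domain: str = ""
    excluded: bool = False
    reason: str = "ok"
    estimates: dict = field(default_factory=dict)
    het: estimators.HeterogeneityResult | None = None
    egger_intercept_p: float | None = None
    presso: PressoResult | None = None
    diagnostics: InstrumentDiagnostics | None = None
    pval_ivw: float | None = None
    q_fdr: float | None = None
    tier: str | None = None
    concordant: bool | None = None
    component: bool | None = None
    flag: str = ""


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), returned in
    input order."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_tier(pval_ivw: float, q_fdr: float, cfg: ScreenConfig) -> str:
    """significant (q < fdr_alpha), suggestive (raw p < suggestive_alpha),
    or null."""
    if q_fdr < cfg.fdr_alpha:
        return "significant"
    if pval_ivw < cfg.suggestive_alpha:
        return "suggestive"
    return "null"


def concordant(estimates: dict) -> bool:
    """Sign agreement of the point estimates across IVW and the sensitivity
    analyses.

    The PRESSO-corrected estimate replaces raw IVW when outliers were
    removed; a point estimate of exactly zero counts as discordant.
    """
    if "ivw" not in estimates:
        raise ConfigurationError("concordance requires an IVW estimate")
    base = estimates.get("presso_corrected", estimates["ivw"])
    others = [
        estimates[m]
        for m in ("weighted_median", "egger_slope")
        if m in estimates
    ]
    if not others and "presso_corrected" not in estimates:
        raise ConfigurationError(
            "concordance requires at least one sensitivity estimate"
        )
    signs = [np.sign(e.beta_hat) for e in [base, *others]]
    if any(s == 0 for s in signs):
        return False
    return len(set(signs)) == 1


def _analysis_seeds(master_seed: int, exposure_id: str, outcome_idx: int):
    """Two deterministic sub-seeds (weighted median, PRESSO) for one
    exposure x outcome analysis, keyed by exposure id."""
    key = zlib.crc32(exposure_id.encode("utf-8"))
    ss = np.random.SeedSequence([master_seed, key, outcome_idx])
    wm_seed, presso_seed = (int(s) & 0x7FFFFFFF for s in ss.generate_state(2))
    return wm_seed, presso_seed


def _analyse_pair(
    work: SummaryStats,
    work_instruments: pd.DataFrame,
    outcome: SummaryStats,
    diagnostics: InstrumentDiagnostics,
    cfg: ScreenConfig,
    outcome_idx: int,
) -> ScreenRecord:
    rec = ScreenRecord(exposure_id=work.trait_id, outcome=outcome.trait_id,
                       diagnostics=diagnostics)
    try:
        h = harmonize.harmonize_pair(
            work,
            outcome,
            instruments=work_instruments,
            palindromic_maf_max=cfg.palindromic_maf_max,
            eaf_tolerance=cfg.eaf_tolerance,
        )
    except HarmonizationError:
        rec.excluded, rec.reason = True, "no_harmonizable_instruments"
        return rec
    if h.n_snps < 2:
        rec.excluded, rec.reason = True, "too_few_harmonized"
        return rec

    est_ivw, het = estimators.ivw(h)
    rec.estimates["ivw"] = est_ivw
    rec.het = het
    rec.pval_ivw = est_ivw.pval

    wm_seed, presso_seed = _analysis_seeds(cfg.seed, work.trait_id, outcome_idx)
    if h.n_snps >= 3:
        try:
            slope, intercept = estimators.egger(h)
            rec.estimates["egger_slope"] = slope
            rec.estimates["egger_intercept"] = intercept
            rec.egger_intercept_p = intercept.pval
        except CollinearityError:
            logger.warning("%s/%s: Egger skipped (collinear instruments)",
                           work.trait_id, outcome.trait_id)
        rec.estimates["weighted_median"] = estimators.weighted_median(
            h, n_boot=cfg.wm_nboot, seed=wm_seed
        )
    if h.n_snps >= 4:
        pres = presso.presso_test(h, n_sim=cfg.presso_nsim, seed=presso_seed)
        rec.presso = pres
        if pres.corrected is not None:
            rec.estimates["presso_corrected"] = pres.corrected
    return rec


def run_screen(
    exposures: list[SummaryStats],
    outcomes: dict[str, SummaryStats],
    ld: LDMatrix | None,
    cfg: ScreenConfig,
    metadata: dict[str, dict] | None = None,
) -> list[ScreenRecord]:
    """Run the full screen over every exposure x outcome combination.

    ``outcomes`` maps outcome labels (e.g. ``p90``, ``p99``) to log-OR-scale
    binary summary statistics.  FDR is computed separately within each
    outcome over all exposures that produced an IVW estimate.  Excluded
    exposures are emitted with their exclusion reason.  Deterministic for a
    fixed (inputs, cfg.seed).
    """
    metadata = metadata or {}
    if ld is None:
        logger.warning(
            "run_screen: no LD matrix supplied; instruments are assumed "
            "pairwise independent (r^2 = 0)"
        )
    for label, out in outcomes.items():
        if out.trait_type != "binary_logistic":
            raise TypeError(
                f"outcome {label!r} must be binary_logistic (log-OR scale), "
                f"got {out.trait_type!r}"
            )

    records: list[ScreenRecord] = []
    seen: set[str] = set()
    for stats in exposures:
        meta_all = metadata.get(stats.trait_id, {})
        meta = {k: meta_all[k] for k in ("category", "domain") if k in meta_all}
        if stats.trait_id in seen:
            for label in outcomes:
                records.append(
                    ScreenRecord(
                        exposure_id=stats.trait_id,
                        outcome=outcomes[label].trait_id,
                        excluded=True,
                        reason="duplicated",
                        **meta,
                    )
                )
            continue
        seen.add(stats.trait_id)

        candidates = instruments.select_instruments(stats, cfg.p_max, cfg.maf_min)
        clumped = instruments.clump(candidates, ld, cfg.r2_max,
                                    warn_missing_ld=False)
        eligible, reason = instruments.exposure_eligible(
            stats, len(clumped), cfg.min_cases, cfg.min_snps
        )

        work = stats
        work_instr = clumped
        if eligible and stats.trait_type == "binary_linear":
            work = linear_to_logodds(stats)
            keep = work.variants["snp_id"].isin(set(clumped["snp_id"]))
            work_instr = work.variants.loc[keep].reset_index(drop=True)

        for outcome_idx, (label, outcome) in enumerate(sorted(outcomes.items())):
            if not eligible:
                records.append(
                    ScreenRecord(
                        exposure_id=stats.trait_id,
                        outcome=outcome.trait_id,
                        excluded=True,
                        reason=reason,
                        **meta,
                    )
                )
                continue
            mu_out = (
                outcome.n_cases / outcome.n_total
                if outcome.n_cases is not None
                else None
            )
            diag = instruments.diagnose_instruments(
                clumped,
                stats.n_total,
                outcome_n=outcome.n_total,
                outcome_case_fraction=mu_out,
                or_hyp=cfg.power_or_hyp,
                alpha=cfg.alpha_power,
            )
            rec = _analyse_pair(work, work_instr, outcome, diag, cfg, outcome_idx)
            rec.category = meta.get("category", "")
            rec.domain = meta.get("domain", "")
            records.append(rec)

    # per-outcome FDR over exposures that produced an IVW estimate
    for label, outcome in outcomes.items():
        idx = [
            i
            for i, r in enumerate(records)
            if r.outcome == outcome.trait_id and not r.excluded
        ]
        if not idx:
            continue
        qs = fdr_adjust([records[i].pval_ivw for i in idx])
        for i, q in zip(idx, qs):
            r = records[i]
            r.q_fdr = float(q)
            r.tier = classify_tier(r.pval_ivw, r.q_fdr, cfg)
            try:
                r.concordant = concordant(r.estimates)
            except ConfigurationError:
                r.concordant = None
    return records


def records_to_frame(records: list[ScreenRecord]) -> pd.DataFrame:
    """Flatten ScreenRecords into a fixed-column table for writing."""
    rows = []
    for r in records:
        row = {
            "exposure_id": r.exposure_id,
            "outcome": r.outcome,
            "category": r.category,
            "domain": r.domain,
            "excluded": r.excluded,
            "reason": r.reason,
            "n_snps": r.estimates["ivw"].n_snps if "ivw" in r.estimates else 0,
            "q_fdr": r.q_fdr,
            "tier": r.tier,
            "concordant": r.concordant,
            "component": r.component,
            "flag": r.flag,
            "egger_intercept_p": r.egger_intercept_p,
            "q_stat": r.het.q_stat if r.het else None,
            "q_pval": r.het.pval if r.het else None,
            "presso_global_p": r.presso.global_p if r.presso else None,
            "presso_n_outliers": len(r.presso.outliers) if r.presso else None,
            "r2_total": r.diagnostics.r2_total if r.diagnostics else None,
            "f_stat": r.diagnostics.f_stat if r.diagnostics else None,
            "power": r.diagnostics.power if r.diagnostics else None,
        }
        for method in ("ivw", "egger_slope", "egger_intercept",
                       "weighted_median", "presso_corrected"):
            est = r.estimates.get(method)
            row[f"beta_{method}"] = est.beta_hat if est else None
            row[f"se_{method}"] = est.se if est else None
            row[f"or_{method}"] = est.or_point if est else None
            row[f"pval_{method}"] = est.pval if est else None
        rows.append(row)
    return pd.DataFrame(rows)


def merge_validation(
    screen: list[ScreenRecord],
    validation: list[ScreenRecord] | None,
    cfg: ScreenConfig,
    primary_outcome: str | None = None,
) -> pd.DataFrame:
    """Combine screen and validation records into the component table.

    An exposure is a component of the longevity exposome when it is
    significant or suggestive for BOTH outcomes in the screen with
    concordant sensitivity analyses, or when its validation result is
    significant.  A validation-stage null with power at or above
    ``cfg.power_threshold_validation`` excludes the exposure outright;
    otherwise the screen verdict stands, flagged as unvalidated.
    """
    by_exposure: dict[str, dict[str, ScreenRecord]] = {}
    for r in screen:
        by_exposure.setdefault(r.exposure_id, {})[r.outcome] = r

    val_by_exposure: dict[str, ScreenRecord] = {}
    for r in validation or []:
        if r.exposure_id not in by_exposure:
            logger.warning(
                "validation exposure %r absent from screen", r.exposure_id
            )
        prev = val_by_exposure.get(r.exposure_id)
        if prev is None or (primary_outcome and r.outcome == primary_outcome):
            val_by_exposure[r.exposure_id] = r

    rows = []
    for eid, group in by_exposure.items():
        recs = list(group.values())
        tiers = [r.tier for r in recs]
        both_supported = len(recs) >= 2 and all(
            t in ("significant", "suggestive") for t in tiers
        )
        conc = any(r.concordant for r in recs if r.concordant is not None)
        screen_support = both_supported and conc

        val = val_by_exposure.get(eid)
        val_tier = val.tier if val else None
        val_power = (
            val.diagnostics.power if val and val.diagnostics else None
        )
        if val is not None and val_tier == "significant":
            component, flag = True, "validated"
        elif (
            val is not None
            and val_tier == "null"
            and val_power is not None
            and val_power >= cfg.power_threshold_validation
        ):
            component, flag = False, "excluded_validation_null_high_power"
        elif screen_support:
            component = True
            flag = "unvalidated" if val is None else "validation_inconclusive"
        else:
            component, flag = False, "unvalidated"
        rows.append(
            {
                "exposure_id": eid,
                "tiers": ";".join(f"{r.outcome}={r.tier}" for r in recs),
                "concordant": conc,
                "validation_tier": val_tier,
                "validation_power": val_power,
                "component": component,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)
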