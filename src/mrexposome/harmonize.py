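"""Allele harmonization between exposure instruments and outcome statistics.

Two-sample MR requires both datasets' betas to refer to the same effect
allele.  For each instrument the outcome row is aligned by: direct match,
allele swap (sign-flip the outcome beta), or strand flip (complement the
outcome alleles, then direct/swap).  Palindromic SNPs (A/T or C/G) cannot be
resolved from alleles alone: they are oriented by allele frequency when the
exposure MAF is at most ``palindromic_maf_max`` (default 0.42) and dropped
as ambiguous otherwise.  Retained palindromes must also pass a frequency
concordance check (|eaf_x - eaf_y| below ``eaf_tolerance``) guarding
against population mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import DomainError, HarmonizationError
from .sumstats import SummaryStats

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

ACTIONS = (
    "kept_direct",
    "kept_swapped",
    "kept_strand_flipped",
    "kept_palindromic_aligned",
    "dropped_palindromic_ambiguous",
    "dropped_missing",
    "dropped_incompatible",
)

RECORD_COLUMNS = ["snp_id", "beta_x", "se_x", "beta_y", "se_y", "eaf_x", "eaf_y"]


def complement(a: str) -> str:
    """Watson-Crick complement of a single base."""
    try:
        return COMPLEMENT[a]
    except KeyError:
        raise DomainError(f"not an ACGT allele: {a!r}") from None


def is_palindromic(a1: str, a2: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    if a1 not in COMPLEMENT or a2 not in COMPLEMENT:
        raise DomainError(f"not ACGT alleles: {a1!r}/{a2!r}")
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


@dataclass
class HarmonizedSet:
    """Exposure/outcome SNP pairs aligned to the exposure's effect allele.

    ``records`` columns: snp_id, beta_x, se_x, beta_y, se_y, eaf_x, eaf_y.
    ``actions`` logs one row (snp_id, action) per candidate instrument.
    """

    exposure_id: str
    outcome_id: str
    records: pd.DataFrame
    actions: pd.DataFrame

    @property
    def n_snps(self) -> int:
        return len(self.records)


def _dedupe_outcome(outcome: pd.DataFrame) -> pd.DataFrame:
    """Duplicate snp_id in the outcome: keep the most precise row."""
    if outcome["snp_id"].duplicated().any():
        outcome = outcome.sort_values("se", kind="mergesort").drop_duplicates(
            "snp_id", keep="first"
        )
    return outcome.set_index("snp_id", drop=False)


def harmonize_pair(
    exposure,
    outcome: SummaryStats,
    *,
    instruments: pd.DataFrame | None = None,
    palindromic_maf_max: float = 0.42,
    eaf_tolerance: float = 0.2,
) -> HarmonizedSet:
    """Harmonize selected exposure instruments against outcome statistics.

    ``exposure`` is a SummaryStats whose variants are the (clumped)
    instruments, unless ``instruments`` overrides the variant table.  Raises
    :class:`HarmonizationError` when no instrument survives.
    """
    exp_df = instruments if instruments is not None else exposure.variants
    out_df = _dedupe_outcome(outcome.variants)

    actions: list[tuple[str, str]] = []
    rows: list[dict] = []

    for rec in exp_df.itertuples(index=False):
        snp = rec.snp_id
        ea_x, oa_x = rec.effect_allele, rec.other_allele
        if snp not in out_df.index:
            actions.append((snp, "dropped_missing"))
            continue
        o = out_df.loc[snp]
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        beta_y, se_y, eaf_y = float(o["beta"]), float(o["se"]), o["eaf"]
        eaf_x = rec.eaf

        if is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                actions.append((snp, "dropped_incompatible"))
                continue
            if pd.isna(eaf_x) or pd.isna(eaf_y):
                actions.append((snp, "dropped_palindromic_ambiguous"))
                continue
            maf_x = min(eaf_x, 1.0 - eaf_x)
            if maf_x > palindromic_maf_max:
                actions.append((snp, "dropped_palindromic_ambiguous"))
                continue
            if eaf_y == 0.5:
                actions.append((snp, "dropped_palindromic_ambiguous"))
                continue
            # orient the outcome so both frequencies sit on the same side of 0.5
            if (eaf_x < 0.5) != (eaf_y < 0.5):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            if abs(eaf_x - eaf_y) >= eaf_tolerance:
                actions.append((snp, "dropped_incompatible"))
                continue
            action = "kept_palindromic_aligned"
        else:
            pair_y = (ea_y, oa_y)
            flipped = (COMPLEMENT.get(ea_y), COMPLEMENT.get(oa_y))
            if pair_y == (ea_x, oa_x):
                action = "kept_direct"
            elif pair_y == (oa_x, ea_x):
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else eaf_y
                action = "kept_swapped"
            elif flipped == (ea_x, oa_x):
                action = "kept_strand_flipped"
            elif flipped == (oa_x, ea_x):
                beta_y = -beta_y
                eaf_y = 1.0 - eaf_y if pd.notna(eaf_y) else eaf_y
                action = "kept_strand_flipped"
            else:
                actions.append((snp, "dropped_incompatible"))
                continue

        actions.append((snp, action))
        rows.append(
            {
                "snp_id": snp,
                "beta_x": float(rec.beta),
                "se_x": float(rec.se),
                "beta_y": beta_y,
                "se_y": se_y,
                "eaf_x": eaf_x,
                "eaf_y": eaf_y,
            }
        )

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    actions_df = pd.DataFrame(actions, columns=["snp_id", "action"])
    if records.empty:
        raise HarmonizationError(
            f"no harmonizable instruments for {exposure.trait_id!r} "
            f"against {outcome.trait_id!r}"
        )
    return HarmonizedSet(
        exposure_id=exposure.trait_id,
        outcome_id=outcome.trait_id,
        records=records,
        actions=actions_df,
    )


def harmonized_from_frame(
    records: pd.DataFrame, exposure_id: str = "exposure", outcome_id: str = "outcome"
) -> HarmonizedSet:
    """Wrap an already-aligned record table (e.g. read from disk)."""
    records = records[RECORD_COLUMNS].reset_index(drop=True)
    actions = pd.DataFrame(
        {"snp_id": records["snp_id"], "action": "kept_direct"}
    )
    return HarmonizedSet(exposure_id, outcome_id, records, actions)
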