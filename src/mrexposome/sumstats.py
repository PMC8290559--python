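"""GWAS summary-statistics data model and I/O.

A trait's summary statistics are held as a :class:`SummaryStats`: a pandas
DataFrame of per-variant associations plus trait-level metadata (trait type,
case fraction, sample size).  Traits come in three flavours:

``quantitative``
    betas in trait-SD units per effect allele.
``binary_linear``
    a case/control trait analysed with a linear model; betas are on the raw
    0/1 scale and must be rescaled to log odds ratios before MR
    (:func:`linear_to_logodds`).
``binary_logistic``
    betas already on the log-OR scale.

The linear-to-log-OR conversion is the standard approximation for
linear-model GWAS of binary traits: ``log OR = beta / (mu * (1 - mu))`` with
``mu`` the case fraction; standard errors are rescaled by the same factor,
so z-scores and p-values are unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError, EmptyInputError

logger = logging.getLogger(__name__)

TRAIT_TYPES = ("quantitative", "binary_linear", "binary_logistic")

#: Internal (DataFrame) column names for a variant table.
VARIANT_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

#: Canonical file-header names, in fixed output order.
CANONICAL_HEADER = [
    "snp", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_FILE_TO_INTERNAL = {"snp": "snp_id"}

VALID_ALLELES = frozenset("ACGT")

#: p-values of exactly zero are clipped here so downstream logs/quantiles
#: stay finite.
PVAL_FLOOR = 1e-300

#: Float rendering used by every writer; 17 significant digits round-trip
#: IEEE doubles exactly.
FLOAT_FORMAT = "%.17g"


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP-trait association row (convenience constructor for tests)."""

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int
    chrom: str = "1"
    pos: int = 1


def variants_frame(variants: Iterable[VariantAssociation]) -> pd.DataFrame:
    """Build a canonical variant DataFrame from VariantAssociation records."""
    rows = [
        {
            "snp_id": v.snp_id, "chrom": str(v.chrom), "pos": int(v.pos),
            "effect_allele": v.effect_allele, "other_allele": v.other_allele,
            "eaf": v.eaf, "beta": v.beta, "se": v.se, "pval": v.pval,
            "n": v.n,
        }
        for v in variants
    ]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


@dataclass
class SummaryStats:
    """One trait's GWAS summary statistics plus trait metadata.

    ``variants`` holds one row per SNP with columns :data:`VARIANT_COLUMNS`.
    ``case_fraction`` is required exactly when ``trait_type`` is
    ``binary_linear`` (it parameterises the log-OR conversion).
    """

    trait_id: str
    trait_type: str
    variants: pd.DataFrame
    n_total: int
    case_fraction: float | None = None
    n_cases: int | None = None
    drop_log: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.trait_type not in TRAIT_TYPES:
            raise ConfigurationError(
                f"unknown trait_type {self.trait_type!r}; expected one of {TRAIT_TYPES}"
            )
        if self.trait_type == "binary_linear":
            if self.case_fraction is None:
                raise ConfigurationError(
                    f"trait {self.trait_id!r}: binary_linear requires case_fraction"
                )
            if not 0.0 < self.case_fraction < 1.0:
                raise DomainError(
                    f"case_fraction must be in (0,1), got {self.case_fraction}"
                )
        elif self.case_fraction is not None:
            raise ConfigurationError(
                f"trait {self.trait_id!r}: case_fraction only valid for binary_linear"
            )
        if self.n_cases is not None and self.n_cases > self.n_total:
            raise DomainError(
                f"n_cases ({self.n_cases}) exceeds n_total ({self.n_total})"
            )
        ids = self.variants["snp_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ConfigurationError(f"duplicate snp_id {dup!r} in {self.trait_id!r}")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def is_binary(self) -> bool:
        return self.trait_type in ("binary_linear", "binary_logistic")

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStats":
        """Restrict to the given snp_ids (order of the variant table kept)."""
        keep = self.variants["snp_id"].isin(set(snp_ids))
        return replace(self, variants=self.variants.loc[keep].reset_index(drop=True))


def _resolve_dialect(dialect: Mapping | None) -> tuple[dict, dict | None]:
    """Split a dialect mapping into a column map and a compound-field rule."""
    dialect = dict(dialect or {})
    compound = dialect.pop("compound", None)
    colmap = {c: dialect.get(c, c) for c in CANONICAL_HEADER}
    if compound is not None:
        missing = {"column", "sep", "fields"} - set(compound)
        if missing:
            raise ConfigurationError(
                f"compound dialect rule missing keys: {sorted(missing)}"
            )
    return colmap, compound


def read_sumstats(
    path: str | Path,
    dialect: Mapping | None = None,
    *,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    case_fraction: float | None = None,
    n_total: int | None = None,
    n_cases: int | None = None,
) -> SummaryStats:
    """Read a tab-separated summary-statistics file into a SummaryStats.

    ``dialect`` maps canonical column names (snp, chrom, pos, effect_allele,
    other_allele, eaf, beta, se, pval, n) to the file's headers, and may
    carry a ``compound`` rule ``{"column": ..., "sep": ..., "fields": [...]}``
    that splits e.g. ``1:1000:A:G`` into chrom/pos/alleles.

    Rows violating the variant invariants (non-ACGT or identical alleles,
    se <= 0, eaf outside (0,1), p outside (0,1], missing numerics, duplicate
    snp_id) are dropped; the counts are logged and recorded in
    ``result.drop_log``.  p-values of exactly 0 are clipped to 1e-300 rather
    than dropped.
    """
    path = Path(path)
    colmap, compound = _resolve_dialect(dialect)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if raw.empty:
        raise EmptyInputError(f"{path} contains a header but no rows")

    df = pd.DataFrame(index=raw.index)
    covered: set[str] = set()
    if compound is not None:
        col, sep, fields = compound["column"], compound["sep"], compound["fields"]
        if col not in raw.columns:
            raise ConfigurationError(f"compound column {col!r} missing from {path}")
        parts = raw[col].str.split(sep, expand=True)
        if parts.shape[1] < len(fields):
            raise ConfigurationError(
                f"compound column {col!r} does not split into {len(fields)} fields"
            )
        for i, name in enumerate(fields):
            df[name if name != "snp" else "snp_id"] = parts[i]
            covered.add(name)
        if "snp" not in covered and colmap["snp"] not in raw.columns:
            # identifier defaults to the full compound string
            df["snp_id"] = raw[col]
            covered.add("snp")

    required = ["snp", "effect_allele", "other_allele", "beta", "se", "pval"]
    for canon in CANONICAL_HEADER:
        if canon in covered:
            continue
        src = colmap[canon]
        if src in raw.columns:
            df[_FILE_TO_INTERNAL.get(canon, canon)] = raw[src]
        elif canon in required:
            raise ConfigurationError(
                f"required column {canon!r} (mapped to {src!r}) missing from {path}"
            )
    if "n" not in df.columns:
        if n_total is None:
            raise ConfigurationError(
                f"no sample-size column in {path} and no n_total supplied"
            )
        df["n"] = n_total
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    if "chrom" not in df.columns:
        df["chrom"] = "."
    if "pos" not in df.columns:
        df["pos"] = 0

    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce").fillna(0).astype(int)
    df["chrom"] = df["chrom"].astype(str)
    df["snp_id"] = df["snp_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    drop_log: dict[str, int] = {}
    d = df
    d.loc[d["pval"] == 0, "pval"] = PVAL_FLOOR
    rules = [
        ("non_acgt_allele",
         lambda d: ~(d["effect_allele"].isin(VALID_ALLELES)
                     & d["other_allele"].isin(VALID_ALLELES))),
        ("identical_alleles", lambda d: d["effect_allele"] == d["other_allele"]),
        ("missing_numeric",
         lambda d: d["beta"].isna() | d["se"].isna() | d["pval"].isna() | d["n"].isna()),
        ("nonpositive_se", lambda d: ~(d["se"] > 0)),
        ("pval_out_of_range", lambda d: (d["pval"] < 0) | (d["pval"] > 1)),
        ("eaf_out_of_range",
         lambda d: d["eaf"].notna() & ~((d["eaf"] > 0) & (d["eaf"] < 1))),
        ("duplicate_snp_id", lambda d: d["snp_id"].duplicated()),
    ]
    for reason, rule in rules:
        mask = rule(d)
        k = int(mask.sum())
        if k:
            drop_log[reason] = k
            d = d.loc[~mask]

    n_missing_eaf = int(d["eaf"].isna().sum())
    if n_missing_eaf:
        drop_log["flagged_missing_eaf"] = n_missing_eaf
        logger.warning("%s: %d variants lack eaf; palindromic SNPs among them "
                       "cannot be frequency-aligned", path, n_missing_eaf)
    if drop_log:
        logger.info("%s: dropped/flagged rows: %s", path, drop_log)
    if d.empty:
        raise EmptyInputError(f"{path}: no rows passed validation")

    d = d[VARIANT_COLUMNS].reset_index(drop=True)
    d["n"] = d["n"].astype(int)
    if n_total is None:
        n_total = int(d["n"].max())
    return SummaryStats(
        trait_id=trait_id or path.stem,
        trait_type=trait_type,
        variants=d,
        n_total=n_total,
        case_fraction=case_fraction,
        n_cases=n_cases,
        drop_log=drop_log,
    )


def linear_to_logodds(stats: SummaryStats) -> SummaryStats:
    """Convert a linear-model binary trait to the log-OR scale.

    beta -> beta / (mu (1 - mu)), se -> se / (mu (1 - mu)); p-values are
    unchanged because the transformation is a positive rescaling of both.
    """
    if stats.trait_type != "binary_linear":
        raise TypeError(
            f"linear_to_logodds requires trait_type binary_linear, "
            f"got {stats.trait_type!r}"
        )
    mu = stats.case_fraction
    if mu is None or not 0.0 < mu < 1.0:
        raise DomainError(f"case_fraction must be in (0,1), got {mu}")
    scale = mu * (1.0 - mu)
    variants = stats.variants.copy()
    variants["beta"] = variants["beta"] / scale
    variants["se"] = variants["se"] / scale
    return SummaryStats(
        trait_id=stats.trait_id,
        trait_type="binary_logistic",
        variants=variants,
        n_total=stats.n_total,
        case_fraction=None,
        n_cases=stats.n_cases,
        drop_log=dict(stats.drop_log),
    )


def _records_to_frame(records) -> pd.DataFrame:
    import dataclasses

    if isinstance(records, pd.DataFrame):
        return records
    if isinstance(records, SummaryStats):
        out = records.variants.rename(columns={"snp_id": "snp"})
        return out[CANONICAL_HEADER]
    records = list(records)
    if records and dataclasses.is_dataclass(records[0]):
        return pd.DataFrame([dataclasses.asdict(r) for r in records])
    return pd.DataFrame(records)


def write_table(records, path: str | Path, *, allow_empty: bool = False) -> None:
    """Write a result collection as tab-separated text.

    Accepts a DataFrame, a SummaryStats (variant table with canonical
    headers), or an iterable of dataclass records.  Floats are rendered with
    17 significant digits so a read-back is bit-equal.
    """
    df = _records_to_frame(records)
    if df.empty and not allow_empty:
        raise EmptyInputError(
            f"refusing to write empty table to {path} (pass allow_empty=True)"
        )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    """Generic reader for tables written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
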