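"""Mutation and copy-number burden summaries plus the pre-inference filters.

SCNA burden is the length-weighted per-allele distance between the tumor and
a diploid genome, ``sum_k (L_k / sum L) (|C^A_k - 1| + |C^B_k - 1|)``.  TMB is
the count of retained point mutations.  Both are conventionally binned into
cohort tertiles for survival modeling.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SegmentRecord",
    "scna_burden",
    "tmb",
    "tertile_bin",
    "filter_spms",
]

_AUTOSOMES = {str(i) for i in range(1, 23)}
_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SegmentRecord:
    """One genome segment with clonal allele-specific copy numbers."""

    length: int
    cn_minor: int
    cn_major: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("segment length must be positive")


def scna_burden(segments: Sequence[SegmentRecord]) -> float:
    """Genome-wide copy-number burden.

    Length-weighted mean of ``|C^A - 1| + |C^B - 1|`` over segments — zero for
    a diploid genome, and invariant to splitting segments.
    """
    if len(segments) == 0:
        raise ValueError("at least one segment is required")
    lengths = np.array([s.length for s in segments], dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("total segment length must be positive")
    dev = np.array(
        [abs(s.cn_minor - 1) + abs(s.cn_major - 1) for s in segments], dtype=float
    )
    return float((lengths / total) @ dev)


def tmb(spms: pd.DataFrame, nonsynonymous_only: bool = False) -> int:
    """Tumor mutation burden: the number of retained point mutations.

    With ``nonsynonymous_only`` and a ``consequence`` column present, only
    rows whose consequence contains "synonymous" are excluded (annotation
    itself happens upstream).
    """
    if nonsynonymous_only and "consequence" in spms.columns:
        keep = ~spms["consequence"].astype(str).str.fullmatch(
            r"synonymous(_variant)?", case=False
        )
        return int(keep.sum())
    return int(len(spms))


def tertile_bin(values: Sequence[float]) -> pd.Categorical:
    """Cohort tertile bins ("low"/"mid"/"high") at the 33rd/66th quantiles.

    Values tied with a cutoff go to the lower bin.  A constant cohort
    degenerates to all-"low" with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot bin an empty cohort")
    q33, q66 = np.quantile(v, [0.33, 0.66])  # type-7 sample quantiles
    if q33 == q66 and np.all(v == v[0]):
        warnings.warn("constant values; all samples binned 'low'", RuntimeWarning)
    labels = np.where(v <= q33, "low", np.where(v <= q66, "mid", "high"))
    return pd.Categorical(labels, categories=["low", "mid", "high"], ordered=True)


def _norm_chrom(c: object) -> str:
    return re.sub(r"^chr", "", str(c), flags=re.IGNORECASE)


def filter_spms(
    table: pd.DataFrame, min_alt: int = 7, report: dict | None = None
) -> pd.DataFrame:
    """Pre-inference mutation filters.

    Keeps autosomal single-base substitutions with at least ``min_alt``
    alternate reads and non-zero total copy number.  ``report``, when given,
    collects removal counts per rule.  Idempotent.
    """
    required = {"chrom", "ref", "alt", "alt_count", "cn_minor", "cn_major"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"mutation table is missing columns: {sorted(missing)}")
    chrom = table["chrom"].map(_norm_chrom)
    ref = table["ref"].astype(str).str.upper()
    alt = table["alt"].astype(str).str.upper()
    autosome = chrom.isin(_AUTOSOMES)
    substitution = ref.isin(_BASES) & alt.isin(_BASES) & (ref != alt)
    enough_alt = table["alt_count"] >= min_alt
    has_cn = (table["cn_minor"] + table["cn_major"]) >= 1
    keep = autosome & substitution & enough_alt & has_cn
    if report is not None:
        report["non_autosome"] = int((~autosome).sum())
        report["non_substitution"] = int((autosome & ~substitution).sum())
        report["low_alt_count"] = int((autosome & substitution & ~enough_alt).sum())
        report["zero_copy"] = int(
            (autosome & substitution & enough_alt & ~has_cn).sum()
        )
        report["kept"] = int(keep.sum())
    return table.loc[keep].reset_index(drop=True)
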