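"""Peptide-to-protein fold-change aggregation by nested geometric medians.

The fold change (FC) of a protein between two groups is computed in two
stages, mirroring how label-free replicate designs are rolled up:

1. for each peptide, form *all* cross-replicate abundance ratios between the
   two groups (the full Cartesian product of observed replicate values) and
   take their geometric median — the peptide group ratio;
2. the protein FC is the geometric median of its peptide group ratios.

"Geometric median" of scalar ratios is the median in log space: for vectors
the geometric median is the L1-minimising point, which in one dimension is
the ordinary median, applied here to log-ratios since the objects are
multiplicative. Even counts resolve to the geometric mean of the two central
values (equivalently, the arithmetic mean of the two central logs).

Missing or non-positive abundances contribute no ratios; no imputation is
performed. A protein observed in only one of the two groups cannot be given
a finite ratio — it is reported with an infinite/zero sentinel and a flag so
that downstream detection-set logic stays explicit.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "RatioResult",
    "ratio_combinations",
    "geometric_median_scalar",
    "protein_fold_change",
    "fold_change_table",
    "threshold_filter",
    "results_frame",
]

logger = logging.getLogger(__name__)

#: Flags attached to a RatioResult.
FLAG_OK = "ok"                       # finite fold change from >=1 usable peptide
FLAG_A_ONLY = "a_only"               # detected only in group A -> FC sentinel +inf
FLAG_B_ONLY = "b_only"               # detected only in group B -> FC sentinel 0
FLAG_UNQUANTIFIABLE = "unquantifiable"  # detected in both groups but no peptide pairs


@dataclasses.dataclass
class RatioResult:
    """Fold change of one protein (group A over group B)."""

    protein_id: str
    fold_change: float
    n_peptides_used: int
    peptide_ratios: list[float]
    flag: str = FLAG_OK


def _clean(values: Iterable[float]) -> np.ndarray:
    a = np.asarray(list(values), dtype=float)
    return a[np.isfinite(a) & (a > 0)]


def ratio_combinations(
    values_a: Sequence[float], values_b: Sequence[float]
) -> np.ndarray:
    """All pairwise ratios a/b between observed replicate values.

    Absent (NaN) and non-positive entries are dropped first. The result has
    length |A|*|B|, ordered lexicographically by (index_a, index_b). If either
    side is empty after cleaning, an empty array is returned — the caller
    treats such a peptide as unusable rather than raising.
    """
    a = _clean(values_a)
    b = _clean(values_b)
    if a.size == 0 or b.size == 0:
        return np.empty(0, dtype=float)
    return (a[:, None] / b[None, :]).ravel()


def geometric_median_scalar(xs: Sequence[float]) -> float:
    """Median in log space; even counts give the geometric mean of the two
    central values. Invariant to input order.
    """
    x = np.asarray(list(xs), dtype=float)
    if x.size == 0:
        raise DataError("geometric median of an empty sequence is undefined")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise DataError("geometric median requires strictly positive finite values")
    logs = np.sort(np.log(x))
    mid = logs.size // 2
    if logs.size % 2:
        m = logs[mid]
    else:
        m = 0.5 * (logs[mid - 1] + logs[mid])
    return float(math.exp(m))


def _group_columns(sheet: pd.DataFrame, label: str) -> list[str]:
    cols = sheet.loc[sheet["group"] == label, "sample_id"].tolist()
    if not cols:
        raise ConfigError(f"unknown group label {label!r}")
    return cols


def _protein_result(
    protein_id: str, sub: pd.DataFrame, cols_a: list[str], cols_b: list[str]
) -> RatioResult:
    peptide_ratios: list[float] = []
    seen_a = seen_b = False
    for _, row in sub.iterrows():
        a_vals = _clean(row[cols_a].to_numpy())
        b_vals = _clean(row[cols_b].to_numpy())
        seen_a = seen_a or a_vals.size > 0
        seen_b = seen_b or b_vals.size > 0
        ratios = ratio_combinations(a_vals, b_vals)
        if ratios.size:
            peptide_ratios.append(geometric_median_scalar(ratios))
    if peptide_ratios:
        fc = geometric_median_scalar(peptide_ratios)
        return RatioResult(protein_id, fc, len(peptide_ratios), peptide_ratios)
    if seen_a and not seen_b:
        return RatioResult(protein_id, math.inf, 0, [], FLAG_A_ONLY)
    if seen_b and not seen_a:
        return RatioResult(protein_id, 0.0, 0, [], FLAG_B_ONLY)
    return RatioResult(protein_id, math.nan, 0, [], FLAG_UNQUANTIFIABLE)


def protein_fold_change(
    tbl: pd.DataFrame,
    sheet: pd.DataFrame,
    group_a: str,
    group_b: str,
    protein_id: str,
) -> RatioResult:
    """Fold change of one protein via the nested geometric-median procedure."""
    cols_a = _group_columns(sheet, group_a)
    cols_b = _group_columns(sheet, group_b)
    sub = tbl.loc[tbl["protein_id"] == protein_id]
    if sub.empty:
        raise DataError(f"protein {protein_id!r} has no peptides in the table")
    res = _protein_result(protein_id, sub, cols_a, cols_b)
    if res.flag != FLAG_OK:
        logger.warning("protein %s not quantifiable (%s)", protein_id, res.flag)
    return res


def fold_change_table(
    tbl: pd.DataFrame, sheet: pd.DataFrame, group_a: str, group_b: str
) -> list[RatioResult]:
    """Fold changes for every protein in the table, ordered by protein_id.

    Proteins with zero usable peptides are retained with sentinel flags
    (a_only / b_only / unquantifiable) and logged; filters that want only
    finite ratios should select ``flag == "ok"`` (``threshold_filter`` does).
    """
    cols_a = _group_columns(sheet, group_a)
    cols_b = _group_columns(sheet, group_b)
    results = []
    for pid, sub in tbl.groupby("protein_id", sort=True):
        res = _protein_result(str(pid), sub, cols_a, cols_b)
        if res.flag != FLAG_OK:
            logger.warning("protein %s not quantifiable (%s)", pid, res.flag)
        results.append(res)
    if not any(r.flag == FLAG_OK for r in results):
        logger.warning(
            "no protein had a valid replicate ratio pair between %r and %r",
            group_a, group_b,
        )
    return results


def threshold_filter(
    results: Iterable[RatioResult], min_fold: float, direction: str
) -> list[str]:
    """Protein ids whose finite FC clears a fold threshold.

    direction="over" keeps FC >= min_fold; "under" keeps FC <= 1/min_fold.
    Sentinel-flagged proteins (single-group detections) are excluded — they
    belong to the detection-set logic, not to ratio thresholds.
    """
    if not min_fold > 0:
        raise ConfigError("min_fold must be positive")
    if direction not in ("over", "under"):
        raise ConfigError(f"direction must be 'over' or 'under', got {direction!r}")
    keep = []
    for r in results:
        if r.flag != FLAG_OK:
            continue
        if direction == "over" and r.fold_change >= min_fold:
            keep.append(r.protein_id)
        elif direction == "under" and r.fold_change <= 1.0 / min_fold:
            keep.append(r.protein_id)
    return sorted(keep)


def results_frame(results: Iterable[RatioResult]) -> pd.DataFrame:
    """Tabular view of fold-change results (for TSV output)."""
    return pd.DataFrame(
        [
            {
                "protein_id": r.protein_id,
                "fold_change": r.fold_change,
                "n_peptides_used": r.n_peptides_used,
                "flag": r.flag,
            }
            for r in results
        ]
    )
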