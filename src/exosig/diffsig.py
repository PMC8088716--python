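"""Differential signatures: normalization, t-score ranking, reference-relative
heatmaps, detection-set (Venn) logic, ortholog-similarity filtering and
gene-set odds-ratio enrichment.

Conventions
-----------
* Protein tables are pandas DataFrames, index ``protein_id``, one column per
  sample, nonnegative abundances.
* Columns are normalized by total-sum scaling (each sample's abundances sum
  to 1) before any cohort comparison, matching standard practice for
  compositional MS data.
* The per-protein statistic is the two-sample Student t (pooled variance,
  two-sided p); Welch's variant is available behind a flag. Raw p-values are
  the primary output; Benjamini-Hochberg q-values are emitted alongside as a
  clearly-labelled extension because 5-vs-5 proteomics demands multiplicity
  awareness.
* Heatmap cells are log2 of a sample's normalized value relative to the mean
  of a reference cohort's columns, so the reference cohort's mean profile
  maps to the zero vector.
"""
from __future__ import annotations

import dataclasses
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError

__all__ = [
    "HeatmapMatrix",
    "GeneSetCollection",
    "normalize_columns",
    "feature_t_scores",
    "heatmap_matrix",
    "detection_sets",
    "presence_sets",
    "presence_from_peptide_table",
    "ortholog_similarity_filter",
    "read_gmt",
    "enrichment_odds_ratios",
]


def normalize_columns(tbl: pd.DataFrame) -> pd.DataFrame:
    """Total-sum scaling: divide each column by its total.

    Every output column sums to 1, so the operation is idempotent. A column
    with non-positive total cannot be normalized and raises a
    :class:`DataError` naming the sample.
    """
    sums = tbl.sum(axis=0, skipna=True)
    bad = sums[~(sums > 0)]
    if len(bad):
        raise DataError(f"column(s) with non-positive total: {list(bad.index)}")
    return tbl.div(sums, axis=1)


def _cohort_columns(sheet: pd.DataFrame, label: str) -> list[str]:
    for key in ("cohort", "group"):
        if key in sheet.columns:
            cols = sheet.loc[sheet[key] == label, "sample_id"].tolist()
            if cols:
                return cols
    raise ConfigError(f"no samples with cohort/group label {label!r}")


def feature_t_scores(
    tbl: pd.DataFrame,
    sheet: pd.DataFrame,
    cohort1: str,
    cohort2: str,
    equal_var: bool = True,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-protein two-sample t statistics (cohort1 - cohort2), ranked.

    Returns a DataFrame with columns ``protein_id, t_score, p_value, q_value,
    mean_group1, mean_group2, direction`` sorted by descending t_score (ties
    broken by protein_id), which is the row order of the signature heatmap.

    Degenerate rows: zero variance in both cohorts with equal means gives
    t = 0, p = 1; unequal means with zero pooled variance gives a +/-inf
    sentinel with p = 0.
    """
    cols1 = _cohort_columns(sheet, cohort1)
    cols2 = _cohort_columns(sheet, cohort2)
    if len(cols1) < 2 or len(cols2) < 2:
        raise ConfigError("each cohort needs at least 2 samples for a t-test")
    if normalize:
        tbl = normalize_columns(tbl)
    x1 = tbl[cols1].to_numpy(dtype=float)
    x2 = tbl[cols2].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            df = np.full(m1.shape, n1 + n2 - 2, dtype=float)
        else:
            se = np.sqrt(v1 / n1 + v2 / n2)
            num = (v1 / n1 + v2 / n2) ** 2
            den = (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            df = np.where(den > 0, num / den, n1 + n2 - 2)
        t = (m1 - m2) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    diff = m1 - m2
    zero_se = ~(se > 0)
    t = np.where(zero_se & (diff == 0), 0.0, t)
    p = np.where(zero_se & (diff == 0), 1.0, p)
    t = np.where(zero_se & (diff > 0), np.inf, t)
    t = np.where(zero_se & (diff < 0), -np.inf, t)
    p = np.where(zero_se & (diff != 0), 0.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "protein_id": tbl.index.astype(str),
            "t_score": t,
            "p_value": p,
            "q_value": q,
            "mean_group1": m1,
            "mean_group2": m2,
            "direction": np.where(t >= 0, "positive", "negative"),
        }
    )
    return out.sort_values(
        ["t_score", "protein_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


@dataclasses.dataclass
class HeatmapMatrix:
    """Reference-relative log2 matrix with a t-score row ordering."""

    values: pd.DataFrame          # protein x sample, log2 scale
    row_order: list[str]
    reference_columns: list[str]
    eps: float


def heatmap_matrix(
    tbl: pd.DataFrame,
    sheet: pd.DataFrame,
    reference_cohort: str,
    scores: pd.DataFrame,
    eps: float | None = None,
    normalize: bool = True,
) -> HeatmapMatrix:
    """log2 expression of each sample relative to the reference-cohort mean.

    value(p, s) = log2((x_ps + eps) / (mean over reference columns + eps)),
    rows ordered by the t-score ranking in ``scores``. ``eps`` defaults to
    1e-9 of the matrix mean, small enough not to distort nonzero cells while
    keeping zero entries finite.
    """
    ref_cols = _cohort_columns(sheet, reference_cohort)
    if normalize:
        tbl = normalize_columns(tbl)
    if eps is None:
        eps = 1e-9 * float(np.nanmean(tbl.to_numpy(dtype=float)))
    order = [p for p in scores["protein_id"] if p in tbl.index]
    x = tbl.loc[order]
    ref_mean = x[ref_cols].mean(axis=1)
    vals = np.log2(x.add(eps).div(ref_mean + eps, axis=0))
    return HeatmapMatrix(values=vals, row_order=order,
                         reference_columns=list(ref_cols), eps=float(eps))


def presence_sets(
    tbl: pd.DataFrame, sheet: pd.DataFrame, min_replicates: int = 1
) -> dict[str, set[str]]:
    """Protein detection per group: observed (> 0, non-NaN) in >= k replicates."""
    out: dict[str, set[str]] = {}
    for g, sub in sheet.groupby("group", sort=False):
        cols = sub["sample_id"].tolist()
        counts = (tbl[cols].gt(0) & tbl[cols].notna()).sum(axis=1)
        out[str(g)] = set(tbl.index[counts >= min_replicates].astype(str))
    return out


def presence_from_peptide_table(
    peptides: pd.DataFrame, sheet: pd.DataFrame, min_replicates: int = 1
) -> dict[str, set[str]]:
    """Roll peptide observations up to protein detection per group.

    A protein is detected in a group if any of its peptides is observed in at
    least ``min_replicates`` of the group's samples.
    """
    sample_cols = [c for c in peptides.columns if c != "protein_id"]
    obs = peptides[sample_cols].gt(0) & peptides[sample_cols].notna()
    out: dict[str, set[str]] = {}
    for g, sub in sheet.groupby("group", sort=False):
        cols = [c for c in sub["sample_id"] if c in sample_cols]
        per_pep = obs[cols].sum(axis=1)
        hit = peptides.loc[per_pep >= min_replicates, "protein_id"]
        out[str(g)] = set(hit.astype(str))
    return out


def detection_sets(presence: Mapping[str, Iterable[str]]) -> dict[str, dict]:
    """Venn regions for 2 or 3 detection sets.

    Region keys are group labels joined by ``&`` and denote *exact*
    membership (e.g. ``"A&B"`` = detected in A and B but not in any other
    group). The regions partition the union of all sets.
    """
    labels = list(presence)
    if len(labels) not in (2, 3):
        raise ConfigError(
            f"detection_sets supports 2 or 3 groups, got {len(labels)}"
        )
    sets = {lab: set(presence[lab]) for lab in labels}
    regions: dict[str, dict] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[lab] for lab in combo))
            outside = set().union(
                *(sets[lab] for lab in labels if lab not in combo)
            ) if len(combo) < len(labels) else set()
            ids = inside - outside
            regions["&".join(combo)] = {"count": len(ids), "ids": sorted(ids)}
    return regions


def ortholog_similarity_filter(
    rows: pd.DataFrame, min_similarity: float = 99.0
) -> list[str]:
    """Retain proteins whose cross-species ortholog similarity is strictly
    greater than ``min_similarity`` percent (default: the >99% rule used to
    keep only canine proteins with near-identical human orthologs).
    """
    if rows.empty:
        return []
    missing = {"protein_id", "percent_similarity"} - set(rows.columns)
    if missing:
        raise DataError(f"similarity table lacks columns: {sorted(missing)}")
    sim = pd.to_numeric(rows["percent_similarity"], errors="raise")
    if ((sim < 0) | (sim > 100)).any():
        bad = rows.loc[(sim < 0) | (sim > 100), "protein_id"].tolist()
        raise DataError(f"percent_similarity outside [0, 100] for {bad}")
    keep = rows.loc[sim > min_similarity, "protein_id"].astype(str)
    return sorted(keep)


@dataclasses.dataclass(frozen=True)
class GeneSetCollection:
    """Named identifier sets over a background universe.

    Members outside the background are dropped at construction so that every
    set is a subset of the universe used by the 2x2 enrichment tables.
    """

    sets: dict[str, frozenset[str]]
    background: frozenset[str]

    @classmethod
    def from_dict(
        cls, sets: Mapping[str, Iterable[str]], background: Iterable[str] | None = None
    ) -> "GeneSetCollection":
        raw = {name: frozenset(map(str, members)) for name, members in sets.items()}
        bg = frozenset(map(str, background)) if background is not None else frozenset(
            set().union(*raw.values()) if raw else set()
        )
        return cls({name: s & bg for name, s in raw.items()}, bg)


def read_gmt(
    path: str | Path, background: Iterable[str] | None = None
) -> GeneSetCollection:
    """Read a GMT file (tab-separated: set name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise DataError(f"malformed GMT line (need >= 3 fields): {line[:80]!r}")
        name, _desc, *members = parts
        sets[name] = [m for m in members if m]
    return GeneSetCollection.from_dict(sets, background)


def enrichment_odds_ratios(
    query: Iterable[str], collection: GeneSetCollection
) -> pd.DataFrame:
    """Per-set sample odds ratio and one-sided hypergeometric enrichment p.

    For each set S with background N, query Q: the 2x2 table is
    (|Q∩S|, |Q\\S|; |S\\Q|, |N\\(Q∪S)|). The odds ratio is the sample OR with
    a Haldane–Anscombe 0.5 correction applied to all cells when any cell is
    zero; the p-value is P(X >= |Q∩S|) for X hypergeometric(N, |S|, |Q|).
    """
    q = frozenset(map(str, query))
    bg = collection.background
    if not q:
        raise ConfigError("query set is empty")
    if not bg:
        raise ConfigError("background is empty")
    stray = q - bg
    if stray:
        raise ConfigError(
            f"query contains ids outside the background: {sorted(stray)[:5]}..."
        )
    rows = []
    n_bg, n_q = len(bg), len(q)
    for name, s in collection.sets.items():
        a = len(q & s)
        b = n_q - a
        c = len(s) - a
        d = n_bg - n_q - c
        if min(a, b, c, d) == 0:
            aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
        else:
            aa, bb, cc, dd = a, b, c, d
        odds = (aa * dd) / (bb * cc)
        p = float(stats.hypergeom.sf(a - 1, n_bg, len(s), n_q))
        rows.append(
            {
                "set_name": name,
                "set_size": len(s),
                "overlap": a,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["p_value", "set_name"]).reset_index(drop=True)
    return out
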