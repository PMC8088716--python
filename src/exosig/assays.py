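"""Phenotype mathematics for the cell-line assays.

Covers four small but load-bearing computations from the wet-lab side of the
study: exponential-growth generation time from hemocytometer counts, MTS
viability normalization to vehicle control, four-parameter-logistic (4PL)
dose-response fitting with a relative IC50, and dichotomisation of canine
patients into good/poor carboplatin responders by disease-free interval (DFI).
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ConfigError, DataError, NonGrowthError

__all__ = [
    "GrowthRecord",
    "DoseResponse",
    "DoseResponseFit",
    "generation_time",
    "normalize_viability",
    "fit_dose_response",
    "assign_cohorts",
]

#: DFI thresholds (days) used to define responder cohorts. Both inequalities
#: are strict: a good responder has DFI > GOOD_MIN_DAYS, a poor responder has
#: DFI < POOR_MAX_DAYS, and anything else (including missing DFI) is left
#: unclassified.
GOOD_MIN_DAYS = 300
POOR_MAX_DAYS = 100


@dataclasses.dataclass(frozen=True)
class GrowthRecord:
    """One plating/counting experiment on exponentially growing cells.

    Attributes
    ----------
    h_elapsed : float
        Hours between plating and counting (symbol H).
    c1 : float
        Cell count at plating.
    c2 : float
        Cell count at the end of the incubation.
    t_gen : float or None
        Generation (doubling) time in hours, if known.
    """

    h_elapsed: float
    c1: float
    c2: float
    t_gen: float | None = None

    def generation_time(self) -> float:
        return generation_time(self.h_elapsed, self.c1, self.c2)


def generation_time(h_elapsed: float, c1: float, c2: float) -> float:
    """Doubling time t = H * ln(2) / ln(c2 / c1) for exponential growth.

    Raises
    ------
    DataError
        If any input is non-positive.
    NonGrowthError
        If ``c2 <= c1`` (no net growth; a positive finite doubling time does
        not exist and no complex/negative value is fabricated).
    """
    if h_elapsed <= 0 or c1 <= 0 or c2 <= 0:
        raise DataError("h_elapsed, c1 and c2 must all be positive")
    if c2 <= c1:
        raise NonGrowthError(
            f"count did not increase (c1={c1}, c2={c2}); generation time undefined"
        )
    return h_elapsed * math.log(2.0) / math.log(c2 / c1)


@dataclasses.dataclass
class DoseResponse:
    """Viability (fraction of vehicle control) per dose per replicate well.

    ``dose``, ``viability`` and ``replicate`` are aligned 1-D arrays, one
    entry per well. A dose of 0 denotes the vehicle control.
    """

    dose: np.ndarray
    viability: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.dose.shape != self.viability.shape:
            raise DataError("dose and viability must have the same length")
        if np.any(self.dose < 0):
            raise DataError("doses must be nonnegative")
        if np.any(self.viability < 0):
            raise DataError("viability fractions must be nonnegative")
        if self.replicate is None:
            self.replicate = np.zeros(self.dose.shape, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose": self.dose, "replicate": self.replicate, "viability": self.viability}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DoseResponse":
        missing = {"dose", "viability"} - set(df.columns)
        if missing:
            raise DataError(f"dose-response table lacks columns: {sorted(missing)}")
        rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
        return cls(df["dose"].to_numpy(), df["viability"].to_numpy(), rep)


@dataclasses.dataclass
class DoseResponseFit:
    """4PL fit result. ``ic50`` is the curve inflection (relative IC50)."""

    ic50: float
    hill: float
    lower: float
    upper: float
    rss: float
    converged: bool
    ic50_in_range: bool = True
    message: str = ""


def normalize_viability(
    absorbance: Sequence[float], control_wells: Sequence[int]
) -> np.ndarray:
    """Divide raw absorbances by the mean of the control wells.

    After normalization the control wells average exactly 1.0. Idempotent on
    already-normalized data (the control mean is then 1).
    """
    a = np.asarray(absorbance, dtype=float)
    idx = np.asarray(control_wells, dtype=int)
    if idx.size == 0:
        raise DataError("at least one control well is required")
    ctrl = float(a[idx].mean())
    if not ctrl > 0:
        raise DataError(f"control mean must be positive, got {ctrl}")
    return a / ctrl


def fourpl(dose, lower: float, upper: float, ic50: float, hill: float) -> np.ndarray:
    """Evaluate v(d) = lower + (upper - lower) / (1 + (d/ic50)^hill).

    The zero dose maps to ``upper`` (the untreated-control asymptote); with
    hill > 0 the curve decreases monotonically toward ``lower``.
    """
    d = np.asarray(dose, dtype=float)
    out = np.full(d.shape, upper, dtype=float)
    pos = d > 0
    out[pos] = lower + (upper - lower) / (1.0 + (d[pos] / ic50) ** hill)
    return out


def fit_dose_response(
    dr: DoseResponse,
    fix_lower: float | None = None,
    fix_upper: float | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit of a viability curve.

    ic50 and hill are optimised on a log scale (both are positive by
    construction); the asymptotes are free unless fixed by the caller.
    Three hill-slope starting values (0.5, 1, 2) guard against local minima.
    Zero-dose wells participate in the residuals and anchor the upper
    asymptote only. ``converged`` is honest: it requires optimiser success,
    finite parameters and lower < upper; ``ic50_in_range`` reports whether
    the inflection lies inside the tested positive dose range.
    """
    d = dr.dose
    v = dr.viability
    n_free = 2 + (fix_lower is None) + (fix_upper is None)
    if np.unique(d).size < n_free:
        raise ConfigError(
            f"need at least {n_free} distinct doses to fit {n_free} free parameters"
        )
    pos = d > 0
    if not np.any(pos):
        raise ConfigError("at least one positive dose is required")

    upper0 = fix_upper if fix_upper is not None else float(np.max(v))
    lower0 = fix_lower if fix_lower is not None else float(np.min(v))
    half = 0.5 * (upper0 + lower0)
    # positive dose whose mean viability is closest to the half-range crossing
    pos_doses = np.unique(d[pos])
    mean_v = np.array([v[d == x].mean() for x in pos_doses])
    ic50_0 = float(pos_doses[int(np.argmin(np.abs(mean_v - half)))])

    def unpack(theta):
        i = 0
        log_ic50 = theta[i]; i += 1
        log_hill = theta[i]; i += 1
        lower = fix_lower if fix_lower is not None else theta[i]
        if fix_lower is None:
            i += 1
        upper = fix_upper if fix_upper is not None else theta[i]
        return math.exp(log_ic50), math.exp(log_hill), lower, upper

    def residuals(theta):
        ic50, hill, lower, upper = unpack(theta)
        return fourpl(d, lower, upper, ic50, hill) - v

    best = None
    for hill0 in (0.5, 1.0, 2.0):
        theta0 = [math.log(ic50_0), math.log(hill0)]
        if fix_lower is None:
            theta0.append(lower0)
        if fix_upper is None:
            theta0.append(upper0)
        try:
            res = least_squares(
                residuals, theta0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                max_nfev=20000,
            )
        except Exception:  # pragma: no cover - LM rarely raises
            continue
        rss = float(np.sum(res.fun**2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        return DoseResponseFit(
            math.nan, math.nan, math.nan, math.nan, math.inf, False,
            message="optimiser failed for every start",
        )
    rss, res = best
    ic50, hill, lower, upper = unpack(res.x)
    finite = all(map(math.isfinite, (ic50, hill, lower, upper)))
    converged = bool(res.success) and finite and lower < upper
    in_range = finite and (pos_doses.min() <= ic50 <= pos_doses.max())
    msg = "" if converged else "fit did not satisfy lower < upper or failed to converge"
    return DoseResponseFit(ic50, hill, lower, upper, rss, converged, in_range, msg)


def assign_cohorts(
    sheet: pd.DataFrame,
    good_min_days: int = GOOD_MIN_DAYS,
    poor_max_days: int = POOR_MAX_DAYS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label samples good/poor/unclassified by disease-free interval.

    Strict inequalities: cohort "good" iff dfi_days > good_min_days, "poor"
    iff dfi_days < poor_max_days. Rows with DFI in [poor_max_days,
    good_min_days] or with no recorded DFI are labelled "unclassified" —
    missing values are reported, never imputed.

    Returns the sheet with a filled ``cohort`` column plus per-cohort counts.
    """
    out = sheet.copy()
    if "dfi_days" not in out.columns:
        raise DataError("sample sheet has no dfi_days column")
    dfi = pd.to_numeric(out["dfi_days"], errors="coerce")
    if (dfi.dropna() < 0).any():
        bad = out.loc[dfi < 0, "sample_id"].tolist()
        raise DataError(f"negative DFI for samples {bad}")
    cohort = np.where(dfi > good_min_days, "good",
                      np.where(dfi < poor_max_days, "poor", "unclassified"))
    cohort = np.where(dfi.isna(), "unclassified", cohort)
    out["cohort"] = cohort
    counts = {
        "good": int((out["cohort"] == "good").sum()),
        "poor": int((out["cohort"] == "poor").sum()),
        "unclassified": int((out["cohort"] == "unclassified").sum()),
    }
    return out, counts
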