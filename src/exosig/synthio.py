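"""Synthetic input generators mirroring the study's experimental designs.

The pipeline downstream expects four kinds of input, all emulated here with
known ground truth so every stage can be exercised end to end without any
external data:

* a peptide-level label-free MS abundance table for three cell-line groups
  (a carboplatin-sensitive parent plus two resistant derivatives) measured in
  replicate, with peptide multiplicity and optional missingness;
* a protein-level serum-exosome matrix for two patient cohorts (good and poor
  responders, five dogs each) in which a small subset of proteins
  discriminates the cohorts;
* 4PL dose-response viability readouts from an MTS plate;
* hemocytometer growth records (plate, incubate, count).

Abundances are lognormal with multiplicative group effects — the standard
stochastic model for label-free MS intensities — which is exactly the regime
in which log-space (geometric-median) aggregation is the natural estimator.
All generators are bit-reproducible under a fixed :class:`SimConfig`.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .assays import DoseResponse, GrowthRecord
from .errors import ConfigError

__all__ = [
    "SimConfig",
    "SimTruth",
    "serum_config",
    "simulate_peptide_table",
    "simulate_serum_cohorts",
    "simulate_dose_response",
    "simulate_growth",
    "CELL_LINE_GROUPS",
    "SERUM_COHORTS",
    "MTS_DOSES_UM",
]

#: The three cell-line groups of the resistance study: parent (sensitive)
#: line and the derivatives selected at 2.5 and 10 uM carboplatin.
CELL_LINE_GROUPS = ("HMPOS-S", "HMPOS-2.5R", "HMPOS-10R")

#: Serum cohort labels: responders with DFI > 300 days vs < 100 days.
SERUM_COHORTS = ("good", "poor")

#: Carboplatin doses (uM) of the MTS panel; 0 is the vehicle control.
MTS_DOSES_UM = (0.0, 0.5, 1.0, 2.5, 4.0, 6.0, 8.0, 10.0)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of the abundance simulators.

    Parameters
    ----------
    seed : int
        PRNG seed; identical config (including seed) gives bit-identical output.
    n_proteins : int
        Number of simulated proteins.
    frac_discriminating : float
        Fraction of proteins carrying a true between-group effect; the number
        flagged in the truth record is ``floor(frac * n_proteins)``.
    effect_log2 : float
        log2 abundance shift of discriminating proteins in non-reference
        groups (reference = first group label).
    cv : float
        Coefficient of variation of the lognormal measurement noise.
    peptides_per_protein_range : (int, int)
        Inclusive bounds for the uniform peptide count per protein.
    missing_rate : float
        Expected fraction of missing peptide observations (encoded as NaN).
    n_per_group : int
        Replicates (cell lines) or subjects (serum) per group.
    group_labels : tuple of str
        Distinct group labels; the first is the reference group.
    missing_mode : {"mcar", "intensity"}
        Missing completely at random, or abundance-biased (low-intensity
        observations preferentially missing, mean rate preserved).
    """

    seed: int = 0
    n_proteins: int = 500
    frac_discriminating: float = 0.04
    effect_log2: float = 2.0
    cv: float = 0.2
    peptides_per_protein_range: tuple[int, int] = (1, 5)
    missing_rate: float = 0.0
    n_per_group: int = 3
    group_labels: tuple[str, ...] = CELL_LINE_GROUPS
    missing_mode: str = "mcar"

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_labels", tuple(self.group_labels))
        object.__setattr__(
            self, "peptides_per_protein_range",
            tuple(int(x) for x in self.peptides_per_protein_range),
        )
        self.validate()

    def validate(self) -> None:
        if self.n_proteins <= 0:
            raise ConfigError("n_proteins must be positive")
        if not 0.0 <= self.frac_discriminating <= 1.0:
            raise ConfigError("frac_discriminating must lie in [0, 1]")
        if not self.cv > 0:
            raise ConfigError("cv must be positive")
        lo, hi = self.peptides_per_protein_range
        if lo < 1 or hi < lo:
            raise ConfigError("peptides_per_protein_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if len(self.group_labels) == 0:
            raise ConfigError("group_labels must be nonempty")
        if len(set(self.group_labels)) != len(self.group_labels):
            raise ConfigError("group_labels must be distinct")
        if self.missing_mode not in ("mcar", "intensity"):
            raise ConfigError(f"unknown missing_mode {self.missing_mode!r}")


@dataclasses.dataclass(frozen=True)
class SimTruth:
    """Ground truth accompanying a simulated table."""

    discriminating_ids: tuple[str, ...]
    true_log2_effects: dict[str, float]
    generating_params: SimConfig

    def to_dict(self) -> dict:
        return {
            "discriminating_ids": list(self.discriminating_ids),
            "true_log2_effects": dict(self.true_log2_effects),
            "generating_params": dataclasses.asdict(self.generating_params),
        }


def serum_config(**overrides) -> SimConfig:
    """A :class:`SimConfig` with the serum-cohort study defaults.

    Two cohorts of five subjects, 500 proteins of which 4% (20) discriminate
    the cohorts with a 2-log2 (4-fold) shift at cv = 0.2.
    """
    params = dict(
        n_proteins=500,
        frac_discriminating=0.04,
        effect_log2=2.0,
        cv=0.2,
        missing_rate=0.0,
        n_per_group=5,
        group_labels=SERUM_COHORTS,
    )
    params.update(overrides)
    return SimConfig(**params)


def _sigma_log2(cv: float) -> float:
    # lognormal: cv^2 = exp(sigma_ln^2) - 1  =>  sigma on the log2 scale
    return math.sqrt(math.log1p(cv * cv)) / math.log(2.0)


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def _pick_discriminating(rng: np.random.Generator, ids: list[str], frac: float):
    n_disc = int(math.floor(frac * len(ids)))
    idx = np.sort(rng.choice(len(ids), size=n_disc, replace=False))
    return [ids[i] for i in idx]


def _apply_missing(
    rng: np.random.Generator, log2_values: np.ndarray, values: np.ndarray,
    rate: float, mode: str,
) -> np.ndarray:
    if rate <= 0:
        return values
    if mode == "mcar":
        mask = rng.random(values.shape) < rate
    else:  # intensity-biased: drop probability decreasing in abundance rank
        pct = rankdata(log2_values, axis=None).reshape(values.shape) / values.size
        prob = np.clip(2.0 * rate * (1.0 - pct), 0.0, 1.0)
        mask = rng.random(values.shape) < prob
    out = values.copy()
    out[mask] = np.nan
    return out


def _sample_sheet(group_labels, n_per_group, cohort_from_group=False,
                  dfi=None) -> pd.DataFrame:
    rows = []
    for g in group_labels:
        for r in range(n_per_group):
            sid = f"{g}_r{r + 1}"
            rows.append(
                {
                    "sample_id": sid,
                    "group": g,
                    "cohort": g if cohort_from_group else pd.NA,
                    "replicate": r + 1,
                    "dfi_days": dfi[sid] if dfi is not None else pd.NA,
                }
            )
    return pd.DataFrame(rows)


def simulate_peptide_table(cfg: SimConfig):
    """Generate a peptide x sample abundance table with known truth.

    Each protein gets 1+ peptides (uniform in ``peptides_per_protein_range``);
    every peptide inherits its protein's group effect, so the protein-level
    truth is well defined for the fold-change quantifier. Observed abundances
    are strictly positive; missing entries are NaN at rate ~ ``missing_rate``.

    Returns
    -------
    (pandas.DataFrame, pandas.DataFrame, SimTruth)
        Peptide table (index ``peptide_id``, first column ``protein_id``,
        then one column per sample), sample sheet, and the truth record.
    """
    cfg.validate()
    if len(cfg.group_labels) < 2:
        raise ConfigError("peptide-table simulation needs >= 2 groups")
    rng = np.random.default_rng(cfg.seed)
    prot_ids = _protein_ids(cfg.n_proteins)
    disc = _pick_discriminating(rng, prot_ids, cfg.frac_discriminating)
    disc_set = set(disc)

    base_log2 = rng.normal(20.0, 2.0, size=cfg.n_proteins)
    lo, hi = cfg.peptides_per_protein_range
    n_pep = rng.integers(lo, hi + 1, size=cfg.n_proteins)
    m = int(n_pep.sum())
    pep_protein_idx = np.repeat(np.arange(cfg.n_proteins), n_pep)
    pep_offsets = rng.normal(0.0, 1.0, size=m)  # per-peptide ionisation efficiency

    groups = list(cfg.group_labels)
    sheet = _sample_sheet(groups, cfg.n_per_group)
    sample_ids = sheet["sample_id"].tolist()
    nonref = np.array([g != groups[0] for g in sheet["group"]], dtype=float)

    effect_vec = np.array(
        [cfg.effect_log2 if pid in disc_set else 0.0 for pid in prot_ids]
    )
    shift = effect_vec[pep_protein_idx][:, None] * nonref[None, :]
    noise = rng.normal(0.0, _sigma_log2(cfg.cv), size=(m, len(sample_ids)))
    log2_vals = base_log2[pep_protein_idx][:, None] + pep_offsets[:, None] + shift + noise
    values = np.exp2(log2_vals)
    values = _apply_missing(rng, log2_vals, values, cfg.missing_rate, cfg.missing_mode)

    pep_ids, seen = [], {}
    for i in pep_protein_idx:
        pid = prot_ids[i]
        seen[pid] = seen.get(pid, 0) + 1
        pep_ids.append(f"{pid}_pep{seen[pid]}")

    tbl = pd.DataFrame(values, columns=sample_ids)
    tbl.insert(0, "protein_id", [prot_ids[i] for i in pep_protein_idx])
    tbl.index = pd.Index(pep_ids, name="peptide_id")

    truth = SimTruth(
        discriminating_ids=tuple(disc),
        true_log2_effects={pid: cfg.effect_log2 for pid in disc},
        generating_params=cfg,
    )
    return tbl, sheet, truth


def simulate_serum_cohorts(cfg: SimConfig):
    """Generate a protein x sample serum-exosome matrix for two cohorts.

    Discriminating proteins are shifted by ``effect_log2`` (log2 scale) in the
    second cohort relative to the first. Plausible DFI values are drawn for
    the sample sheet (good responders > 300 days, poor responders < 100 days)
    so the cohort-assignment stage can be exercised on simulated data.
    """
    cfg.validate()
    if len(cfg.group_labels) != 2:
        raise ConfigError("serum simulation requires exactly 2 group_labels")
    rng = np.random.default_rng(cfg.seed)
    prot_ids = _protein_ids(cfg.n_proteins)
    disc = _pick_discriminating(rng, prot_ids, cfg.frac_discriminating)
    disc_set = set(disc)

    base_log2 = rng.normal(20.0, 2.0, size=cfg.n_proteins)
    g_good, g_poor = cfg.group_labels
    dfi = {}
    for r in range(cfg.n_per_group):
        dfi[f"{g_good}_r{r + 1}"] = int(rng.integers(301, 900))
    for r in range(cfg.n_per_group):
        dfi[f"{g_poor}_r{r + 1}"] = int(rng.integers(10, 100))
    sheet = _sample_sheet(cfg.group_labels, cfg.n_per_group,
                          cohort_from_group=True, dfi=dfi)
    sample_ids = sheet["sample_id"].tolist()
    second = np.array([g == g_poor for g in sheet["group"]], dtype=float)

    effect_vec = np.array(
        [cfg.effect_log2 if pid in disc_set else 0.0 for pid in prot_ids]
    )
    shift = effect_vec[:, None] * second[None, :]
    noise = rng.normal(0.0, _sigma_log2(cfg.cv), size=(cfg.n_proteins, len(sample_ids)))
    log2_vals = base_log2[:, None] + shift + noise
    values = np.exp2(log2_vals)
    values = _apply_missing(rng, log2_vals, values, cfg.missing_rate, cfg.missing_mode)

    tbl = pd.DataFrame(values, columns=sample_ids,
                       index=pd.Index(prot_ids, name="protein_id"))
    truth = SimTruth(
        discriminating_ids=tuple(disc),
        true_log2_effects={pid: cfg.effect_log2 for pid in disc},
        generating_params=cfg,
    )
    return tbl, sheet, truth


def simulate_dose_response(
    ic50: float,
    hill: float,
    lower: float,
    upper: float,
    doses: Iterable[float] = MTS_DOSES_UM,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
) -> DoseResponse:
    """Simulate MTS viability wells from a 4PL curve.

    viability(d) = lower + (upper - lower) / (1 + (d/ic50)^hill) + N(0, noise_sd),
    truncated at 0 (absorbance cannot be negative). A dose of 0 evaluates to
    ``upper`` (untreated control).
    """
    if ic50 <= 0:
        raise ConfigError("ic50 must be positive")
    if not upper > lower:
        raise ConfigError("upper asymptote must exceed lower")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be nonnegative")
    d = np.asarray(list(doses), dtype=float)
    if np.any(d < 0):
        raise ConfigError("doses must be nonnegative")
    rng = np.random.default_rng(seed)
    dd = np.repeat(d, n_replicates)
    rep = np.tile(np.arange(1, n_replicates + 1), d.size)
    clean = np.full(dd.shape, upper, dtype=float)
    pos = dd > 0
    clean[pos] = lower + (upper - lower) / (1.0 + (dd[pos] / ic50) ** hill)
    v = clean + rng.normal(0.0, noise_sd, size=dd.shape) if noise_sd > 0 else clean
    return DoseResponse(dose=dd, viability=np.maximum(v, 0.0), replicate=rep)


def simulate_growth(h_elapsed: float, c1: float, t_gen: float) -> GrowthRecord:
    """Exponential-growth record: c2 = c1 * 2^(H / t_gen).

    Inverse of the generation-time formula, so the round trip through
    :func:`exosig.assays.generation_time` recovers ``t_gen`` exactly.
    """
    if h_elapsed <= 0 or c1 <= 0 or t_gen <= 0:
        raise ConfigError("h_elapsed, c1 and t_gen must all be positive")
    c2 = c1 * 2.0 ** (h_elapsed / t_gen)
    return GrowthRecord(h_elapsed=h_elapsed, c1=c1, c2=c2, t_gen=t_gen)
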