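"""Serum-exosome outcome classifier: t-score-weighted net prediction score.

The classifier formalises the prognosis-score figure of the study as the
minimal linear model consistent with its axes: each selected protein
contributes its training t-score (good - poor) times the standardized
abundance; contributions are split by weight sign into the two plotted sums
("positively correlated with good outcome" vs "negatively correlated"), and

    net score = contrib_negative - contrib_positive

so that a lower net score means better predicted prognosis. The decision
boundary is the midpoint of the two training cohorts' mean net scores;
samples on the boundary are called "poor" (the conservative clinical
default). Leave-one-out validation retrains everything — normalization,
feature selection, standardization and the boundary — inside every fold.

The original study does not describe its score construction; this module is
an explicit interpretation (see the package methods note), validated on
synthetic cohorts rather than the study's sera.
"""
from __future__ import annotations

import dataclasses
import json
from typing import Iterable

import numpy as np
import pandas as pd

from .diffsig import feature_t_scores, normalize_columns
from .errors import ConfigError, DataError, NoSignatureError

__all__ = [
    "SignatureModel",
    "ScoreDecomposition",
    "train_signature",
    "score_sample",
    "loo_accuracy",
    "decompositions_frame",
]


@dataclasses.dataclass
class SignatureModel:
    """Trained linear prognosis signature.

    ``weights`` maps each selected protein to its training t-score computed
    as good-cohort minus poor-cohort; ``standardization`` holds per-feature
    (mean, sd) over all training samples of the column-normalized table.
    Orientation is fixed: net score < boundary predicts the good outcome.
    """

    features: list[str]
    weights: dict[str, float]
    standardization: dict[str, tuple[float, float]]
    boundary: float
    good_label: str
    poor_label: str

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["orientation"] = "net score < boundary predicts good outcome"
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        d = json.loads(text)
        d.pop("orientation", None)
        d["standardization"] = {
            k: tuple(v) for k, v in d["standardization"].items()
        }
        return cls(**d)


@dataclasses.dataclass
class ScoreDecomposition:
    """Per-sample score split into the two plotted contribution axes.

    Identity: ``net_score == contrib_negative - contrib_positive``.
    ``contrib_negative`` sums contributions of features negatively correlated
    with good outcome (higher in poor responders); ``contrib_positive`` those
    positively correlated with good outcome.
    """

    sample_id: str
    contrib_negative: float
    contrib_positive: float
    net_score: float
    predicted: str | None
    flagged: bool = False


def _net_parts(
    model: SignatureModel, values: pd.Series
) -> tuple[float, float, float]:
    neg = pos = 0.0
    for f in model.features:
        if f not in values.index or pd.isna(values[f]):
            raise DataError(f"sample lacks a value for selected protein {f!r}")
        mean, sd = model.standardization[f]
        z = (float(values[f]) - mean) / sd
        w = model.weights[f]
        if w > 0:
            pos += w * z
        elif w < 0:
            neg += -w * z
    return neg, pos, neg - pos


def train_signature(
    tbl: pd.DataFrame,
    sheet: pd.DataFrame,
    good_label: str,
    poor_label: str,
    p_cutoff: float = 0.05,
    max_features: int | None = None,
    equal_var: bool = True,
) -> SignatureModel:
    """Select features by t-test, weight by t-score, place the boundary.

    The table is column-normalized internally (idempotent if already
    normalized). Features are proteins with p < ``p_cutoff``, truncated to
    ``max_features`` by |t|; features with zero standard deviation across the
    training samples are dropped. The boundary is the midpoint between the
    mean net scores of the two training cohorts.

    Raises :class:`NoSignatureError` when selection retains nothing —
    the advice is to relax ``p_cutoff``.
    """
    if not 0 < p_cutoff <= 1:
        raise ConfigError("p_cutoff must lie in (0, 1]")
    norm = normalize_columns(tbl)
    scores = feature_t_scores(
        norm, sheet, good_label, poor_label, equal_var=equal_var, normalize=False
    )
    sel = scores.loc[scores["p_value"] < p_cutoff].copy()
    if max_features is not None:
        sel = sel.reindex(
            sel["t_score"].abs().sort_values(ascending=False).index
        ).head(max_features)
    if sel.empty:
        raise NoSignatureError(
            f"no protein passed p < {p_cutoff}; relax the cutoff or check cohorts"
        )
    from .diffsig import _cohort_columns  # shared label resolution

    cols_good = _cohort_columns(sheet, good_label)
    cols_poor = _cohort_columns(sheet, poor_label)
    train_cols = cols_good + cols_poor

    features, weights, standardization = [], {}, {}
    for _, row in sel.iterrows():
        f = str(row["protein_id"])
        vals = norm.loc[f, train_cols].to_numpy(dtype=float)
        sd = float(vals.std(ddof=1))
        if not sd > 0:
            continue
        features.append(f)
        weights[f] = float(row["t_score"])
        standardization[f] = (float(vals.mean()), sd)
    if not features:
        raise NoSignatureError(
            "all selected proteins had zero variance across training samples"
        )
    model = SignatureModel(features, weights, standardization, 0.0,
                           good_label, poor_label)
    nets_good = [_net_parts(model, norm[c])[2] for c in cols_good]
    nets_poor = [_net_parts(model, norm[c])[2] for c in cols_poor]
    model.boundary = 0.5 * (float(np.mean(nets_good)) + float(np.mean(nets_poor)))
    return model


def score_sample(
    model: SignatureModel,
    sample: pd.Series,
    sample_id: str | None = None,
    normalize: bool = True,
) -> ScoreDecomposition:
    """Score one sample column and predict its cohort.

    ``sample`` is a full protein column (index = protein ids). With
    ``normalize=True`` (default) the column is divided by its own total
    first, matching the training normalization; this is a purely per-sample
    operation, so scoring a held-out sample leaks nothing. A missing value
    for any selected feature raises a :class:`DataError` naming the protein —
    never silently imputed. Samples exactly on the boundary are called poor.
    """
    values = sample.astype(float)
    if normalize:
        total = values.sum(skipna=True)
        if not total > 0:
            raise DataError("sample column total must be positive to normalize")
        values = values / total
    neg, pos, net = _net_parts(model, values)
    predicted = model.good_label if net < model.boundary else model.poor_label
    sid = sample_id if sample_id is not None else str(sample.name)
    return ScoreDecomposition(sid, neg, pos, net, predicted)


def loo_accuracy(
    tbl: pd.DataFrame,
    sheet: pd.DataFrame,
    good_label: str,
    poor_label: str,
    p_cutoff: float = 0.05,
    max_features: int | None = None,
    equal_var: bool = True,
) -> tuple[float, list[ScoreDecomposition]]:
    """Leave-one-out accuracy with full in-fold retraining.

    For every sample, a signature is trained on the remaining samples
    (normalization, selection, standardization and boundary all recomputed
    within the fold) and the held-out sample is scored. A fold in which no
    feature is selectable counts the sample as misclassified and flags it.
    """
    from .diffsig import _cohort_columns

    cols_good = _cohort_columns(sheet, good_label)
    cols_poor = _cohort_columns(sheet, poor_label)
    truth = {c: good_label for c in cols_good}
    truth.update({c: poor_label for c in cols_poor})
    samples = cols_good + cols_poor
    if len(cols_good) < 2 or len(cols_poor) < 2:
        raise ConfigError("leave-one-out requires >= 2 samples per cohort")

    decomps: list[ScoreDecomposition] = []
    n_correct = 0
    for held in samples:
        rest = [c for c in samples if c != held]
        fold_sheet = sheet.loc[sheet["sample_id"].isin(rest)]
        fold_tbl = tbl[rest]
        try:
            model = train_signature(
                fold_tbl, fold_sheet, good_label, poor_label,
                p_cutoff=p_cutoff, max_features=max_features, equal_var=equal_var,
            )
        except NoSignatureError:
            decomps.append(
                ScoreDecomposition(held, np.nan, np.nan, np.nan, None, flagged=True)
            )
            continue
        dec = score_sample(model, tbl[held], sample_id=held)
        decomps.append(dec)
        if dec.predicted == truth[held]:
            n_correct += 1
    return n_correct / len(samples), decomps


def decompositions_frame(
    decomps: Iterable[ScoreDecomposition], truth: dict[str, str] | None = None
) -> pd.DataFrame:
    """Tabular view mirroring the score-scatter figure columns."""
    rows = []
    for d in decomps:
        row = {
            "sample_id": d.sample_id,
            "contrib_negative": d.contrib_negative,
            "contrib_positive": d.contrib_positive,
            "net_score": d.net_score,
            "predicted": d.predicted,
            "flagged": d.flagged,
        }
        if truth is not None:
            row["true"] = truth.get(d.sample_id)
        rows.append(row)
    return pd.DataFrame(rows)
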