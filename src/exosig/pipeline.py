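"""End-to-end pipeline runner with provenance.

A :class:`PipelineConfig` (usually parsed from YAML) names the inputs and
stage parameters; :func:`run_pipeline` executes the requested subset of
quantify -> signature -> prognose and writes every stage's tables plus a
run manifest (package and library versions, seed, input hashes, resolved
config) so identical config + inputs reproduce identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__, diffsig, io, pepquant, prognosis
from .errors import ConfigError, ExosigError

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("quantify", "signature", "prognose")


@dataclasses.dataclass
class PipelineConfig:
    """Resolved pipeline configuration; unknown keys are rejected on parse."""

    samples: str
    out: str
    stages: tuple[str, ...] = STAGES
    peptides: str | None = None
    proteins: str | None = None
    group_a: str | None = None
    group_b: str | None = None
    cohort1: str | None = None
    cohort2: str | None = None
    gmt: str | None = None
    min_fold: float = 100.0
    p_cutoff: float = 0.05
    max_features: int | None = None
    eps: float | None = None
    min_replicates: int = 1
    loo: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        missing = {"samples", "out"} - set(d)
        if missing:
            raise ConfigError(f"missing required config key(s): {sorted(missing)}")
        cfg = cls(**d)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stage(s): {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("pipeline config must be a YAML mapping")
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls.from_dict(d)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the configured stages; returns the output directory.

    A failing stage halts the run with the stage named; outputs written so
    far are listed as partial in the manifest.
    """
    outdir = Path(cfg.out)
    outdir.mkdir(parents=True, exist_ok=True)
    sheet = io.read_sample_sheet(cfg.samples)
    inputs = {"samples": _sha256(cfg.samples)}
    written: list[str] = []
    manifest = {
        "exosig_version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        "inputs": inputs,
        "outputs": written,
        "status": "partial",
    }

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written.append(name)

    current_stage = None
    try:
        if "quantify" in cfg.stages:
            current_stage = "quantify"
            if not (cfg.peptides and cfg.group_a and cfg.group_b):
                raise ConfigError(
                    "quantify stage needs peptides, group_a and group_b"
                )
            peps = io.read_matrix(cfg.peptides, kind="peptide")
            inputs["peptides"] = _sha256(cfg.peptides)
            results = pepquant.fold_change_table(
                peps, sheet, cfg.group_a, cfg.group_b
            )
            frame = pepquant.results_frame(results)
            emit("fold_changes.tsv",
                 lambda p: frame.to_csv(p, sep="\t", index=False))
            over = pepquant.threshold_filter(results, cfg.min_fold, "over")
            emit("over_threshold.json",
                 lambda p: p.write_text(json.dumps(
                     {"min_fold": cfg.min_fold, "protein_ids": over}, indent=2)))
            presence = diffsig.presence_from_peptide_table(
                peps, sheet, cfg.min_replicates
            )
            if len(presence) in (2, 3):
                venn = diffsig.detection_sets(presence)
                emit("venn.json",
                     lambda p: p.write_text(json.dumps(venn, indent=2)))

        proteins = None
        if {"signature", "prognose"} & set(cfg.stages):
            if not cfg.proteins:
                raise ConfigError("signature/prognose stages need proteins")
            proteins = io.read_matrix(cfg.proteins, kind="protein")
            inputs["proteins"] = _sha256(cfg.proteins)
            if not (cfg.cohort1 and cfg.cohort2):
                raise ConfigError("signature/prognose stages need cohort1 and cohort2")

        if "signature" in cfg.stages:
            current_stage = "signature"
            scores = diffsig.feature_t_scores(
                proteins, sheet, cfg.cohort1, cfg.cohort2
            )
            emit("scores.tsv",
                 lambda p: scores.to_csv(p, sep="\t", index=False))
            hm = diffsig.heatmap_matrix(
                proteins, sheet, cfg.cohort1, scores, eps=cfg.eps
            )
            emit("heatmap.tsv",
                 lambda p: hm.values.to_csv(p, sep="\t"))
            if cfg.gmt:
                collection = diffsig.read_gmt(
                    cfg.gmt, background=proteins.index
                )
                query = set(
                    scores.loc[scores["p_value"] < cfg.p_cutoff, "protein_id"]
                ) & set(collection.background)
                if query:
                    enr = diffsig.enrichment_odds_ratios(query, collection)
                    emit("enrichment.tsv",
                         lambda p: enr.to_csv(p, sep="\t", index=False))
                inputs["gmt"] = _sha256(cfg.gmt)

        if "prognose" in cfg.stages:
            current_stage = "prognose"
            model = prognosis.train_signature(
                proteins, sheet, cfg.cohort1, cfg.cohort2,
                p_cutoff=cfg.p_cutoff, max_features=cfg.max_features,
            )
            emit("model.json", lambda p: p.write_text(model.to_json()))
            truth = dict(zip(sheet["sample_id"], sheet["cohort"].fillna("")))
            if cfg.loo:
                acc, decomps = prognosis.loo_accuracy(
                    proteins, sheet, cfg.cohort1, cfg.cohort2,
                    p_cutoff=cfg.p_cutoff, max_features=cfg.max_features,
                )
                frame = prognosis.decompositions_frame(decomps, truth)
                emit("prognosis.tsv",
                     lambda p: frame.to_csv(p, sep="\t", index=False))
                emit("loo_accuracy.json",
                     lambda p: p.write_text(json.dumps(
                         {"loo_accuracy": acc, "n_samples": len(decomps)},
                         indent=2)))
            else:
                decomps = [
                    prognosis.score_sample(model, proteins[c], sample_id=c)
                    for c in proteins.columns
                ]
                frame = prognosis.decompositions_frame(decomps, truth)
                emit("prognosis.tsv",
                     lambda p: frame.to_csv(p, sep="\t", index=False))
    except ExosigError as err:
        manifest["status"] = f"failed in stage {current_stage}: {err}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise ExosigError(f"stage {current_stage!r} failed: {err}") from err

    manifest["status"] = "complete"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
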