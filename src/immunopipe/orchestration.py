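"""End-to-end pipeline driver with deterministic seeding and a manifest.

Stage order: score -> network/modules -> cluster -> markers -> itb ->
evaluate, with the mutational-signature stage optional.  Every artifact
embeds the config hash and stage seed; reruns with an identical config
are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ImmunopipeError, ParameterError
from . import io_formats as io
from .evaluation import combine_predictors, compare_nested_lrt, roc_auc
from .itb_pipeline import compare_classifiers, run_itb, split_cohort
from .mutsig_nmf import decompose
from .signature_network import build_network, detect_modules, select_eigen_signatures
from .signature_scoring import ssgsea_score, zscore_rows
from .subtype_clustering import select_model_bic
from .subtype_stats import subtype_marker_genes

logger = logging.getLogger(__name__)

_STAGES = ("score", "modules", "cluster", "markers", "itb", "evaluate", "mutsig")


@dataclass
class PipelineConfig:
    expression: str = ""
    gene_sets: str = ""
    survival: str = ""
    catalog: str | None = None
    out_dir: str = "results"
    seed: int = 0
    # stage parameters (paper-default values where the source states them)
    alpha: float = 0.25
    ssgsea_normalize: bool = False
    power: float = 20.0
    min_module_size: int = 3
    k_min: int = 2
    k_max: int = 28
    covariance_models: list[str] = field(
        default_factory=lambda: ["spherical-equal", "spherical-varying", "diagonal", "full"]
    )
    gmm_n_init: int = 10
    standardize_scores: bool = True
    fdr: float = 0.05
    lfc: float = 1.0
    train_fraction: float = 0.7
    cv_folds: int = 5
    run_classifiers: bool = False
    minprop: float = 0.1
    pca_mode: str = "pooled"
    run_mutsig: bool = False
    max_rank: int = 10
    nmf_restarts: int = 10

    def validate(self) -> None:
        if self.power < 1:
            raise ParameterError(f"power must be >= 1, got {self.power}")
        if self.min_module_size < 1:
            raise ParameterError("min_module_size must be >= 1")
        if not 2 <= self.k_min <= self.k_max:
            raise ParameterError("need 2 <= k_min <= k_max")
        if not 0 < self.fdr < 1:
            raise ParameterError("fdr must lie in (0, 1)")
        if not 0 < self.train_fraction < 1:
            raise ParameterError("train_fraction must lie in (0, 1)")
        if not 0 < self.minprop <= 0.5:
            raise ParameterError("minprop must lie in (0, 0.5]")
        if self.alpha < 0:
            raise ParameterError("alpha must be >= 0")
        if self.max_rank < 1:
            raise ParameterError("max_rank must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def config_hash(self) -> str:
        # out_dir is a location, not an analysis parameter: reruns into a
        # different directory must stay byte-identical
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(len(_STAGES))
        return {stage: int(s) % (2**31) for stage, s in zip(_STAGES, state)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    meta = {"config_hash": config.config_hash(), "version": __version__}
    artifacts: dict[str, str] = {}
    current = "setup"
    try:
        expr = io.read_expression(config.expression)
        sets = io.read_gmt(config.gene_sets)
        survival = io.read_survival(config.survival)
        catalog = io.read_catalog(config.catalog) if config.catalog else None
        expr, survival, catalog = io.align_samples(expr, survival, catalog)

        current = "score"
        scores = ssgsea_score(expr, sets, alpha=config.alpha, normalize=config.ssgsea_normalize)
        io.write_scores(scores, out / "scores.tsv")
        artifacts["scores"] = "scores.tsv"

        current = "modules"
        net = build_network(scores, power=config.power)
        modules = detect_modules(net, min_module_size=config.min_module_size)
        representatives = select_eigen_signatures(modules)
        io.write_model(
            {**modules.to_dict(), "representatives": representatives,
             "power": config.power, "stage_seed": seeds["modules"], **meta},
            out / "modules.json",
        )
        artifacts["modules"] = "modules.json"

        current = "cluster"
        rep_scores = scores.loc[representatives]
        if config.standardize_scores:
            rep_scores = zscore_rows(rep_scores)
        model = select_model_bic(
            rep_scores.to_numpy().T,
            k_range=range(config.k_min, config.k_max + 1),
            n_init=config.gmm_n_init,
            seed=seeds["cluster"],
            sample_ids=list(scores.columns),
            feature_ids=representatives,
            models=config.covariance_models,
        )
        io.write_model({**model.to_dict(), "stage_seed": seeds["cluster"], **meta},
                       out / "subtypes.json")
        artifacts["cluster"] = "subtypes.json"
        labels = model.assignment

        current = "markers"
        markers = subtype_marker_genes(expr, labels, fdr_max=config.fdr, lfc_min=config.lfc)
        markers["table"].to_csv(out / "markers.tsv", sep="\t", index=False)
        artifacts["markers"] = "markers.tsv"
        if not markers["panel"]:
            raise ImmunopipeError("no subtype-specific genes found; cannot build the score")

        current = "itb"
        classifier_reports = []
        if config.run_classifiers:
            train, test = split_cohort(
                list(expr.columns), labels, config.train_fraction, seed=seeds["itb"]
            )
            lab = pd.Series(labels, index=expr.columns)
            classifier_reports = compare_classifiers(
                expr.loc[markers["panel"], train], lab[train].to_numpy(),
                expr.loc[markers["panel"], test], lab[test].to_numpy(),
                folds=config.cv_folds, seed=seeds["itb"],
            )
        itb = run_itb(expr, markers["panel"], survival,
                      pca_mode=config.pca_mode, minprop=config.minprop)
        io.write_model(
            {**itb.to_dict(),
             "classifiers": [r.to_dict() for r in classifier_reports],
             "stage_seed": seeds["itb"], **meta},
            out / "itb.json",
        )
        itb.group.to_frame().to_csv(out / "groups.tsv", sep="\t", index_label="sample_id")
        artifacts["itb"] = "itb.json"
        artifacts["groups"] = "groups.tsv"

        current = "evaluate"
        label = survival["event"].to_numpy()
        evaluation: dict = {"stage_seed": seeds["evaluate"], **meta}
        if len(np.unique(label)) == 2:
            evaluation["itb_auc"] = roc_auc(itb.score.to_numpy(), label, "itbscore").auc
            if catalog is not None:
                tmb = catalog.sum(axis=0).to_numpy(dtype=float)
                evaluation["tmb_auc"] = roc_auc(tmb, label, "tmb").auc
                combined = combine_predictors([itb.score.to_numpy(), tmb], label)
                evaluation["combined_auc"] = roc_auc(combined, label, "combined").auc
                chi2, df, p = compare_nested_lrt(
                    [tmb], [tmb, itb.score.to_numpy()], label
                )
                evaluation["lrt_combined_vs_tmb"] = {"chi2": chi2, "df": df, "p": p}
        io.write_model(evaluation, out / "evaluation.json")
        artifacts["evaluate"] = "evaluation.json"

        if config.run_mutsig and catalog is not None:
            current = "mutsig"
            sigs = decompose(catalog, max_rank=config.max_rank,
                             n_restarts=config.nmf_restarts, seed=seeds["mutsig"])
            io.write_model({**sigs.to_dict(), "stage_seed": seeds["mutsig"], **meta},
                           out / "signatures.json")
            artifacts["mutsig"] = "signatures.json"
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={current}: {exc}\n")
        raise ImmunopipeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    manifest = {
        "artifacts": {name: {"path": rel, "sha256": _sha256(out / rel)}
                      for name, rel in sorted(artifacts.items())},
        "config": config.to_dict(),
        "config_hash": meta["config_hash"],
        "stage_seeds": seeds,
        "version": __version__,
    }
    io.write_model(manifest, out / "manifest.json")
    (out / "FAILED").unlink(missing_ok=True)
    return manifest
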