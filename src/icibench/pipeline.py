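"""End-to-end pipeline: simulate/load -> score -> evaluate -> rank -> report.

A :class:`PipelineConfig` (typically loaded from YAML) names the dataset,
the models to score, the endpoint, and the bootstrap settings; running it
produces, under the output directory:

* ``predictions_<model>.tsv``   per-model prediction files,
* ``evaluation_<model>.json``   point estimates + bootstrap summaries,
* ``ranking.json``              the challenge-rule ranking,
* ``report.tsv`` / ``report.txt``  a per-model DSS table.

Re-running an identical config reproduces every numeric output exactly; the
seed, config hash and package version are recorded in each artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .evaluation import EvaluationResult, bootstrap_evaluate, rank_models
from .models import BaselineModel, make_model, score_dataset
from .trial_data import (
    GeneSet,
    TrialDataset,
    read_gene_sets,
    read_trial,
    validate_predictions,
    write_predictions,
)

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    clinical_path: str = ""
    expression_path: str | None = None
    gene_sets_path: str | None = None
    output_dir: str = "pipeline_out"
    models: list[str] = field(default_factory=list)
    model_settings: dict = field(default_factory=dict)
    endpoint: str = "PFS"
    B: int = 1000
    seed: int = 0
    tie_tol: float | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Fingerprint of the analytic inputs (where results land and how
        chattily is not part of the analysis)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        payload.pop("log_level")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _geneset_lookup(path: str | None) -> dict[str, GeneSet]:
    if not path:
        return {}
    return {gs.name: gs for gs in read_gene_sets(path)}


def build_model(name: str, settings: dict, gene_sets: dict[str, GeneSet]):
    """Instantiate a registered model, resolving gene-set names from config."""
    kwargs = dict(settings.get(name, {}))
    for key in ("proliferation_genes", "icr_genes", "panel_genes"):
        if key in kwargs:
            kwargs[key] = gene_sets[kwargs[key]]
    if "gene_sets" in kwargs:
        kwargs["gene_sets"] = {role: gene_sets[gs_name]
                               for role, gs_name in kwargs["gene_sets"].items()}
    return make_model(name, **kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full flow; returns the report bundle as a dict."""
    if not config.models:
        raise PipelineError("configuration error: empty model list")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": config.digest(), "seed": config.seed,
                  "version": __version__}

    stage = "load"
    try:
        dataset = read_trial(config.clinical_path, config.expression_path)
        gene_sets = _geneset_lookup(config.gene_sets_path)

        stage = "score"
        scores = {}
        for name in config.models:
            model = build_model(name, config.model_settings, gene_sets)
            score = score_dataset(model, dataset, config.endpoint.upper())
            report = validate_predictions(dataset, score)
            if not report.ok:
                raise PipelineError(f"model {name}: invalid predictions: "
                                    f"{report.failures[:3]}")
            scores[name] = score
            write_predictions(score, out / f"predictions_{name}.tsv")

        stage = "evaluate"
        results: dict[str, EvaluationResult] = {}
        for name, score in scores.items():
            res = bootstrap_evaluate(dataset, score, config.endpoint,
                                     B=config.B, seed=config.seed)
            results[name] = res
            payload = {**res.summary(), **provenance}
            (out / f"evaluation_{name}.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True) + "\n")

        stage = "rank"
        if "baseline_tmb" in results:
            reference = results["baseline_tmb"]
        else:
            ref_score = BaselineModel("tmb").fit(dataset).score_patients(
                dataset, config.endpoint.upper())
            reference = bootstrap_evaluate(dataset, ref_score, config.endpoint,
                                           B=config.B, seed=config.seed)
        candidates = [r for n, r in results.items() if n != "baseline_tmb"]
        ranking = rank_models(candidates or list(results.values()), reference,
                              tie_tol=config.tie_tol)
        ranking_payload = {**dataclasses.asdict(ranking), **provenance}
        (out / "ranking.json").write_text(
            json.dumps(ranking_payload, indent=2, sort_keys=True) + "\n")

        stage = "report"
        table = pd.DataFrame([results[n].summary() for n in config.models])
        table = table.sort_values("dss", ascending=False).reset_index(drop=True)
        table.to_csv(out / "report.tsv", sep="\t", index=False, float_format="%.6f")
        lines = [f"icibench ranking report (endpoint={config.endpoint.upper()}, "
                 f"B={config.B}, seed={config.seed}, "
                 f"config={provenance['config_hash']}, v{__version__})", ""]
        for _, row in table.iterrows():
            lines.append(
                f"  {row['model']:<16} DSS={row['dss']:+.4f} "
                f"[boot IQR {row['dss_boot_q25']:+.4f}, {row['dss_boot_q75']:+.4f}] "
                f"BM_ici={row['bm_ici']:.4f} BM_chemo={row['bm_ctrl']:.4f}")
        lines += ["", f"eligible (K vs TMB baseline > 3): {ranking.eligible or '(none)'}",
                  f"tie set (K vs best < 3): {ranking.tie_set or '(none)'}",
                  f"top performers: {ranking.top_performers or '(none)'}", ""]
        (out / "report.txt").write_text("\n".join(lines))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {"results": results, "ranking": ranking, "table": table,
            "provenance": provenance, "output_dir": str(out)}
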