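"""End-to-end orchestration: load → GIP → select → fuse → classify → report.

:class:`RunConfig` gathers every path and stage parameter of a run; it can
be read from a YAML/JSON document and individual fields overridden from the
command line. :func:`run_ndd` performs the cross-validated evaluation and
writes three artifacts to the output directory: a metrics report (JSON), a
ranked per-pair score table (TSV, out-of-fold scores with the
``score > 0.5`` candidate-DDI flag), and the selection provenance (JSON).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .classifier import NNConfig, build_dataset, save_model, train
from .data_model import (
    DrugIndex,
    InteractionMatrix,
    SimilarityMatrix,
    count_pair_universe,
    load_interaction_matrix,
    load_similarity_matrix,
)
from .evaluation import all_unordered_pairs, run_cv
from .exceptions import NDDError, ParameterError
from .gip import GIPConfig, gip_similarity
from .selection import SelectionConfig, select_similarities
from .snf import FusionConfig, fuse

logger = logging.getLogger(__name__)

DECISION_THRESHOLD = 0.5  # flag pairs above this as candidate interactions


@dataclass
class RunConfig:
    drug_list: str = ""
    interactions: str = ""
    similarities: dict[str, str] = field(default_factory=dict)  # name -> path
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    gip: GIPConfig = field(default_factory=GIPConfig)
    gip_scope: str = "fold"
    include_gip: bool = True
    nn: NNConfig = field(default_factory=NNConfig)
    k: int = 5
    repeats: int = 20
    seed: int = 0
    out_dir: str = "ndd_output"

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        kwargs = dict(doc)
        for key, sub in (
            ("selection", SelectionConfig),
            ("fusion", FusionConfig),
            ("gip", GIPConfig),
            ("nn", NNConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                if key == "nn" and "hidden_sizes" in kwargs[key]:
                    kwargs[key]["hidden_sizes"] = tuple(kwargs[key]["hidden_sizes"])
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["nn"]["hidden_sizes"] = list(d["nn"]["hidden_sizes"])
        return d


def load_inputs(
    cfg: RunConfig,
) -> tuple[DrugIndex, InteractionMatrix, list[SimilarityMatrix]]:
    for label, p in [("drug list", cfg.drug_list), ("interactions", cfg.interactions),
                     *[(f"similarity {n!r}", p) for n, p in cfg.similarities.items()]]:
        if not Path(p).exists():
            raise ParameterError(f"missing input file for {label}: {p}")
    index = DrugIndex.from_file(cfg.drug_list)
    Y = load_interaction_matrix(cfg.interactions, index)
    views = [
        load_similarity_matrix(path, name, index)
        for name, path in sorted(cfg.similarities.items())
    ]
    if not views and not cfg.include_gip:
        raise ParameterError("no similarity views and GIP disabled")
    return index, Y, views


def _write_manifest(out: Path, cfg: RunConfig, index, Y, views) -> None:
    counts = count_pair_universe(index, Y)
    manifest = {
        "m": index.m,
        "views": [v.name for v in views],
        "ordered_pairs_total": counts.total,
        "interacting_entries": counts.positives,
        "non_interacting_entries": counts.negatives,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_ndd(cfg: RunConfig):
    """Cross-validated evaluation; returns (MetricsReport, scores DataFrame,
    SelectionResult) and writes report/scores/provenance to ``cfg.out_dir``."""
    index, Y, views = load_inputs(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_manifest(out, cfg, index, Y, views)

    report, scores = run_cv(
        views, Y, cfg.selection, cfg.fusion, cfg.gip, cfg.nn,
        k=cfg.k, repeats=cfg.repeats, seed=cfg.seed,
        gip_scope=cfg.gip_scope, include_gip=cfg.include_gip,
        collect_scores=True,
    )
    # provenance from a full-data selection pass (reporting only)
    candidates = list(views) + ([gip_similarity(Y, cfg.gip)] if cfg.include_gip else [])
    sel = select_similarities(candidates, cfg.selection)

    report_doc = report.to_dict()
    report_doc["seed"] = cfg.seed
    (out / "report.json").write_text(json.dumps(report_doc, indent=2, sort_keys=True))
    report.per_fold.to_csv(out / "per_fold.tsv", sep="\t", index=False)

    scores = scores.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
    scores["drug_id_1"] = [index.ids[i] for i in scores["i"]]
    scores["drug_id_2"] = [index.ids[j] for j in scores["j"]]
    scores["flag"] = scores["score"] > DECISION_THRESHOLD
    scores["rank"] = range(1, len(scores) + 1)
    scores[["drug_id_1", "drug_id_2", "label", "score", "flag", "rank"]].to_csv(
        out / "predictions.tsv", sep="\t", index=False
    )
    (out / "selection.json").write_text(json.dumps(sel.to_dict(), indent=2, sort_keys=True))
    logger.info("run complete: auc=%.3f aupr=%.3f", report.auc, report.aupr)
    return report, scores, sel


def fit_full(cfg: RunConfig, model_path: str | Path):
    """Fit on all pairs (no held-out fold) and save the model archive."""
    index, Y, views = load_inputs(cfg)
    candidates = list(views) + ([gip_similarity(Y, cfg.gip)] if cfg.include_gip else [])
    sel = select_similarities(candidates, cfg.selection)
    chosen = [v for v in candidates if v.name in sel.selected]
    fused = fuse(chosen, cfg.fusion)
    pairs = all_unordered_pairs(Y.m)
    samples = build_dataset(fused, Y, pairs, both_orders=True)
    model = train(samples, dataclasses.replace(cfg.nn, seed=cfg.seed))
    save_model(model, model_path, fused=fused)
    return model, fused, sel


def predict_pairs(
    model_path: str | Path, drug_list: str | Path, out_path: str | Path
) -> pd.DataFrame:
    """Score every unordered pair with a saved model; write the ranked TSV."""
    from .classifier import load_model, score_unordered_pairs

    model, fused = load_model(model_path)
    if fused is None:
        raise NDDError("model archive lacks the fused matrix; re-save with fused=...")
    index = DrugIndex.from_file(drug_list)
    pairs = all_unordered_pairs(fused.m)
    scores = score_unordered_pairs(model, fused, pairs)
    df = pd.DataFrame(
        {
            "drug_id_1": [index.ids[i] for i, _ in pairs],
            "drug_id_2": [index.ids[j] for _, j in pairs],
            "score": scores,
        }
    )
    df = df.sort_values("score", ascending=False, kind="mergesort").reset_index(drop=True)
    df["flag"] = df["score"] > DECISION_THRESHOLD
    df["rank"] = range(1, len(df) + 1)
    df.to_csv(out_path, sep="\t", index=False)
    return df
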