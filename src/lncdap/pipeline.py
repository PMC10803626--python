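"""End-to-end orchestration: similarity -> encode -> denoise -> train -> evaluate.

`run_pipeline_core` works entirely in memory and returns every intermediate
stage product (useful for tests and notebooks); `run_pipeline` wraps it
with file I/O and writes a run manifest sufficient to reproduce the run
(config, derived stage seeds, timings, output paths). All stage seeds are
derived deterministically from the single pipeline seed.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as lio
from .datatypes import (
    AssociationMatrix,
    DiseaseDAG,
    DISEASE_VIEWS,
    LNCRNA_VIEWS,
    SequenceSet,
    VIEW_NAMES,
)
from .denoise import DenoisingResult, PairSet, build_samples, denoise, select_k
from .encoder import EncoderConfig, EncoderState, build_view_graph, train_encoder
from .ensemble import BalancedDataset, StackingModel, build_training_set, train_stacking
from .evaluation import CVReport, all_metrics, cross_validate, select_best_model
from .similarity import compute_all_views

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline_core", "run_pipeline",
           "stage_seeds"]


@dataclass
class PipelineConfig:
    views: tuple[str, ...] = VIEW_NAMES
    seed: int = 0
    epochs: int = 200
    learning_rate: float = 1e-3
    dropout: float = 0.5
    edge_threshold: float = 0.0
    k_range: tuple[int, int] = (2, 10)       # inclusive silhouette candidates
    denoise_rounds: int = 10
    holdout_frac: float = 0.2
    cv_folds: int = 5
    threshold: float = 0.5
    gamma_prime: float = 1.0
    dag_decay: float = 0.5
    base_learners: tuple[str, ...] | None = None
    lses_raw_distance: bool = False

    def encoder_config(self, seed: int) -> EncoderConfig:
        return EncoderConfig(epochs=self.epochs, learning_rate=self.learning_rate,
                             dropout=self.dropout, edge_threshold=self.edge_threshold,
                             seed=seed)


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from the pipeline seed."""
    names = ("encoder_disease", "encoder_lncrna", "select_k", "denoise",
             "negatives", "stacking", "cv")
    return {name: (seed * 131 + i * 7919) % (2**31 - 1) for i, name in enumerate(names)}


@dataclass
class PipelineResult:
    config: PipelineConfig
    seeds: dict[str, int]
    views: dict
    encoder_disease: EncoderState
    encoder_lncrna: EncoderState
    samples: PairSet
    k: int
    silhouette_trace: dict[int, float]
    denoising: DenoisingResult
    dataset: BalancedDataset
    model: StackingModel
    heldout_metrics: dict[str, float]
    cv_report: CVReport
    best_model_name: str
    model_selection_table: dict
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def F_disease(self) -> np.ndarray:
        return self.encoder_disease.F

    @property
    def F_lncrna(self) -> np.ndarray:
        return self.encoder_lncrna.F


def run_pipeline_core(A: AssociationMatrix, dag: DiseaseDAG | None,
                      seqs: SequenceSet | None,
                      config: PipelineConfig | None = None) -> PipelineResult:
    config = config or PipelineConfig()
    seeds = stage_seeds(config.seed)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    views = compute_all_views(A, dag, seqs, views=config.views,
                              gamma_prime=config.gamma_prime,
                              lses_raw_distance=config.lses_raw_distance)
    timings["similarity"] = time.perf_counter() - t0

    d_views = [views[v] for v in DISEASE_VIEWS if v in views]
    l_views = [views[v] for v in LNCRNA_VIEWS if v in views]
    if not d_views or not l_views:
        raise ValueError("need at least one disease view and one lncRNA view")

    t0 = time.perf_counter()
    d_graphs = [build_view_graph(v, config.edge_threshold) for v in d_views]
    l_graphs = [build_view_graph(v, config.edge_threshold) for v in l_views]
    enc_d = train_encoder(d_graphs, config.encoder_config(seeds["encoder_disease"]))
    enc_l = train_encoder(l_graphs, config.encoder_config(seeds["encoder_lncrna"]))
    timings["encoder"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    samples = build_samples(enc_d.F, enc_l.F, A)
    if not samples.labels.any():
        raise ValueError("association matrix has no positives")
    k, sil = select_k(samples, range(config.k_range[0], config.k_range[1] + 1),
                      seed=seeds["select_k"])
    result = denoise(samples, k, rounds=config.denoise_rounds,
                     base_seed=seeds["denoise"])
    timings["denoise"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    dataset = build_training_set(samples.features, samples.positives,
                                 result.reliable_indices, seed=seeds["negatives"],
                                 holdout_frac=config.holdout_frac)
    model = train_stacking(dataset, seed=seeds["stacking"], folds=config.cv_folds,
                           enabled=config.base_learners)
    timings["train"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    heldout = all_metrics(dataset.y_holdout, model.predict_proba(dataset.X_holdout),
                          threshold=config.threshold)

    def factory():
        return _StackingFactory(seed=seeds["stacking"], folds=config.cv_folds,
                                enabled=config.base_learners)

    cv = cross_validate(dataset.X_pool, dataset.y_pool, factory,
                        folds=config.cv_folds, threshold=config.threshold,
                        seed=seeds["cv"])
    best, table = select_best_model(model, dataset)
    timings["evaluate"] = time.perf_counter() - t0

    return PipelineResult(config=config, seeds=seeds, views=views,
                          encoder_disease=enc_d, encoder_lncrna=enc_l,
                          samples=samples, k=k, silhouette_trace=sil,
                          denoising=result, dataset=dataset, model=model,
                          heldout_metrics=heldout, cv_report=cv,
                          best_model_name=best, model_selection_table=table,
                          timings=timings)


class _StackingFactory:
    """fit/predict_proba adapter so cross_validate can train fresh stacks."""

    def __init__(self, seed: int, folds: int, enabled):
        self.seed, self.folds, self.enabled = seed, folds, enabled
        self.model: StackingModel | None = None

    def fit(self, X, y):
        ds = BalancedDataset(X_pool=X, y_pool=y, X_holdout=X[:0], y_holdout=y[:0],
                             pool_indices=np.arange(len(y)),
                             holdout_indices=np.array([], dtype=int),
                             negative_indices=np.array([], dtype=int), seed=self.seed)
        self.model = train_stacking(ds, seed=self.seed, folds=self.folds,
                                    enabled=self.enabled)
        return self

    def predict_proba(self, X):
        return self.model.predict_proba(X)


def run_pipeline(association_path, out_dir, dag_path=None, fasta_path=None,
                 config: PipelineConfig | None = None) -> dict:
    """File-based pipeline run; returns (and writes) the run manifest."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    A = lio.read_associations(association_path)
    needs_dag = "DSS" in config.views or "LFS" in config.views
    dag = lio.read_dag(dag_path, decay=config.dag_decay) if dag_path else None
    seqs = lio.read_fasta(fasta_path) if fasta_path else None
    if needs_dag and dag is None:
        raise ValueError("DSS/LFS view enabled but no DAG file supplied")
    if "LSES" in config.views and seqs is None:
        raise ValueError("LSES view enabled but no FASTA file supplied")

    res = run_pipeline_core(A, dag, seqs, config)

    outputs: dict[str, str] = {}
    for name, net in res.views.items():
        p = out / f"similarity_{name}.tsv"
        lio.write_similarity(net, p)
        outputs[f"similarity_{name}"] = str(p)
        pe = out / f"edges_{name}.tsv"
        lio.write_edge_list(net, pe, config.edge_threshold)
        outputs[f"edges_{name}"] = str(pe)
    pd_ = out / "embedding_disease.tsv"
    lio.write_embedding(res.F_disease, A.disease_ids, pd_)
    outputs["embedding_disease"] = str(pd_)
    pl = out / "embedding_lncrna.tsv"
    lio.write_embedding(res.F_lncrna, A.lncrna_ids, pl)
    outputs["embedding_lncrna"] = str(pl)

    denoise_report = {
        "K": res.k,
        "silhouette_trace": {str(k): v for k, v in res.silhouette_trace.items()},
        "n_unknown": int(len(res.samples) - res.samples.labels.sum()),
        "n_noise": int(res.denoising.noise_indices.size),
        "n_reliable": int(res.denoising.reliable_indices.size),
        "round_seeds": res.denoising.round_seeds,
        "round_selected_sizes": res.denoising.round_selected_sizes,
        "round_positive_rates": res.denoising.round_positive_rates,
        "initial_positive_rates": res.denoising.initial_positive_rates,
    }
    p = out / "denoising_report.json"
    lio.write_metrics_json(denoise_report, p)
    outputs["denoising_report"] = str(p)
    p = out / "removed_pairs.tsv"
    with p.open("w", newline="\n") as fh:
        fh.write("disease_id\tlncrna_id\n")
        for d, l in res.denoising.noise_pairs(A, res.samples):
            fh.write(f"{d}\t{l}\n")
    outputs["removed_pairs"] = str(p)

    metrics = {
        "heldout": res.heldout_metrics,
        "cv": res.cv_report.as_dict(),
        "model_selection": res.model_selection_table,
        "best_model": res.best_model_name,
    }
    p = out / "metrics.json"
    lio.write_metrics_json(metrics, p)
    outputs["metrics"] = str(p)

    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = {
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "seeds": res.seeds,
        "views": sorted(res.views),
        "timings_s": {k: round(v, 3) for k, v in res.timings.items()},
        "outputs": outputs,
    }
    p = out / "manifest.json"
    lio.write_metrics_json(manifest, p)
    return manifest
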