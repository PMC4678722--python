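"""End-to-end pipeline: filter → correlate → binarize → select → split →
scale → train → predict → evaluate, with a machine-readable manifest.

Every stochastic stage (sample split, forest training, bootstrap,
simulation) takes an explicit seed recorded in the manifest, so reruns of
the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import yaml

from . import __version__
from .matrix import (
    FilterParams,
    read_expression,
    write_expression,
    quantile_filter,
    minmax_scale,
    log_transform,
    train_test_split,
)
from .graph import pearson_matrix, binarize, write_matrix
from .selection import GraphParams, ggs_select, parameter_sweep, predictor_sets
from .impute import train_models, predict_expression, evaluate, save_models
from .simulate import SyntheticSpec, generate_block_expression, generate_validation_cohort

__all__ = ["RunConfig", "WorkflowError", "run_full_workflow"]


@dataclass
class RunConfig:
    """Configuration of a full run; mirrors the CLI flags.

    Either ``expression_path`` (TSV/GCT input) or ``synthetic`` (generator
    parameters) must be provided.  ``thresholds``/``redundancies``/
    ``dm_sizes`` with more than one value trigger a parameter sweep in
    addition to the primary single-parameter run (first value of each).
    """

    out_dir: str
    expression_path: str | None = None
    expression_format: str = "tsv"
    synthetic: dict | None = None
    candidates_path: str | None = None
    rnaseq: bool = False  # log-transform the input before anything else
    filter_quantile: float = 0.90
    filter_cutoff: float = 5.0
    thresholds: list[float] = field(default_factory=lambda: [0.60])
    redundancies: list[int] = field(default_factory=lambda: [1])
    dm_sizes: list[int] = field(default_factory=lambda: [50])
    train_fraction: float = 2.0 / 3.0
    split_seed: int = 0
    forest_seed: int = 0
    bootstrap_seed: int = 0
    bootstrap_resamples: int = 1000
    n_trees: int = 500
    validate_cohort: bool = False  # synthetic runs only: independent cohort
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


class WorkflowError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_full_workflow(config: RunConfig) -> dict:
    """Execute the full pipeline and return the manifest (also written to
    ``manifest.json`` in the output directory)."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "ggselect_version": __version__,
        "config": asdict(config),
        "stages": [],
        "outputs": {},
    }
    outputs: dict[str, str] = {}

    def emit(name: str, path: str) -> None:
        outputs[name] = os.path.abspath(path)

    def stage(name: str):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage name
                raise WorkflowError(name, exc) from exc
            manifest["stages"].append(name)
            if config.verbosity:
                print(f"[ggs] stage complete: {name}")
        return deco

    state: dict = {}

    @stage("load")
    def _load():
        if config.synthetic is not None:
            spec = SyntheticSpec(**config.synthetic)
            expr, truth = generate_block_expression(spec)
            state["truth"] = truth
            state["spec"] = spec
        elif config.expression_path is not None:
            expr = read_expression(config.expression_path, config.expression_format)
        else:
            raise ValueError("config needs expression_path or synthetic parameters")
        if config.rnaseq:
            expr = log_transform(expr)
        state["expr"] = expr
        if config.candidates_path:
            with open(config.candidates_path) as fh:
                state["candidates"] = [ln.strip() for ln in fh if ln.strip()]
        else:
            state["candidates"] = None

    @stage("filter")
    def _filter():
        filtered, quantiles = quantile_filter(
            state["expr"], FilterParams(config.filter_quantile, config.filter_cutoff)
        )
        state["filtered"] = filtered
        path = os.path.join(config.out_dir, "filtered.tsv")
        write_expression(filtered, path)
        emit("filtered", path)
        qpath = os.path.join(config.out_dir, "quantiles.tsv")
        quantiles.to_csv(qpath, sep="\t", index_label="gene")
        emit("quantiles", qpath)

    @stage("correlate")
    def _correlate():
        state["corr"] = pearson_matrix(state["filtered"])
        path = os.path.join(config.out_dir, "corr.tsv")
        write_matrix(state["corr"], path)
        emit("correlation", path)

    @stage("binarize")
    def _binarize():
        state["adj"] = binarize(state["corr"], config.thresholds[0])
        path = os.path.join(config.out_dir, "adj.tsv")
        write_matrix(state["adj"], path, as_int=True)
        emit("adjacency", path)

    @stage("select")
    def _select():
        params = GraphParams(
            threshold=config.thresholds[0],
            redundancy=config.redundancies[0],
            dm_size=config.dm_sizes[0],
        )
        result = ggs_select(state["adj"], params, candidates=state["candidates"])
        state["selection"] = result
        path = os.path.join(config.out_dir, "selection.json")
        result.to_json(path)
        emit("selection", path)

    @stage("sweep")
    def _sweep():
        n_combo = (
            len(config.thresholds) * len(config.redundancies) * len(config.dm_sizes)
        )
        if n_combo <= 1:
            return
        table = parameter_sweep(
            state["corr"],
            config.thresholds,
            config.redundancies,
            config.dm_sizes,
            candidates=state["candidates"],
        )
        path = os.path.join(config.out_dir, "sweep.tsv")
        table.to_csv(path, sep="\t", index=False)
        emit("sweep", path)

    @stage("split")
    def _split():
        train, test = train_test_split(
            state["filtered"], config.train_fraction, config.split_seed
        )
        state["train"], state["test"] = train, test
        for name, part in (("train", train), ("test", test)):
            path = os.path.join(config.out_dir, f"{name}.tsv")
            write_expression(part, path)
            emit(name, path)

    @stage("train")
    def _train():
        from .graph import restrict_to_eligible

        sel = state["selection"]
        universe = restrict_to_eligible(state["adj"], sel.params.redundancy)
        predictors = predictor_sets(universe, sel)
        state["predictors"] = predictors
        model_set = train_models(
            minmax_scale(state["train"]),
            predictors,
            seed=config.forest_seed,
            n_trees=config.n_trees,
        )
        state["models"] = model_set
        path = os.path.join(config.out_dir, "models.joblib")
        save_models(model_set, path)
        emit("models", path)
        emit("models_meta", path + ".meta.json")

    @stage("predict")
    def _predict():
        predicted, skipped = predict_expression(
            state["models"], minmax_scale(state["test"])
        )
        state["predicted"], state["skipped"] = predicted, skipped
        path = os.path.join(config.out_dir, "predicted.tsv")
        write_expression(predicted, path)
        emit("predicted", path)

    @stage("evaluate")
    def _evaluate():
        result = evaluate(
            state["predicted"],
            minmax_scale(state["test"]),
            n_skipped=len(state["skipped"]),
            bootstrap=config.bootstrap_resamples,
            seed=config.bootstrap_seed,
        )
        state["evaluation"] = result
        path = os.path.join(config.out_dir, "evaluation.json")
        result.to_json(path)
        emit("evaluation", path)
        if config.validate_cohort and config.synthetic is not None:
            cohort = generate_validation_cohort(state["spec"])
            cohort = cohort.loc[state["filtered"].index]
            pred_v, skipped_v = predict_expression(state["models"], minmax_scale(cohort))
            res_v = evaluate(
                pred_v,
                minmax_scale(cohort),
                n_skipped=len(skipped_v),
                bootstrap=config.bootstrap_resamples,
                seed=config.bootstrap_seed,
            )
            state["evaluation_cohort"] = res_v
            vpath = os.path.join(config.out_dir, "evaluation_cohort.json")
            res_v.to_json(vpath)
            emit("evaluation_cohort", vpath)

    manifest["outputs"] = {
        name: {"path": path, "sha256": _sha256(path)} for name, path in outputs.items()
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["_state"] = state  # in-memory results for programmatic callers
    return manifest
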