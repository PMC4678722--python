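"""Per-gene regression models that infer unmeasured expression from the
directly measured (DM) panel, plus rank-based evaluation.

Each predictable gene gets its own model over its DM predictors (the DM
genes correlated with it beyond the edge threshold).  With two or more
predictors a random forest of regression trees is fitted; with a single
predictor a polynomial regression (intercept + x + x²) is fitted by least
squares.  Inputs are expected on a per-dataset [0, 1] min-max scale;
evaluation uses the Spearman rank correlation, which is invariant to any
monotone rescaling, so relative rather than absolute expression is what is
being predicted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "GeneModel",
    "ImputationModelSet",
    "EvaluationResult",
    "train_models",
    "predict_expression",
    "evaluate",
    "bootstrap_se",
    "save_models",
    "load_models",
]


@dataclass
class GeneModel:
    """Fitted model for one predictable gene."""

    gene: str
    predictors: list[str]
    kind: str  # "forest" | "polynomial"
    estimator: Any = None          # RandomForestRegressor when kind == "forest"
    coefficients: np.ndarray | None = None  # [intercept, x, x^2, ...] otherwise

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "forest":
            return self.estimator.predict(X)
        x = X[:, 0]
        powers = np.vander(x, N=len(self.coefficients), increasing=True)
        return powers @ self.coefficients


@dataclass
class ImputationModelSet:
    """All per-gene models for one selection run, with training metadata."""

    models: dict[str, GeneModel]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.models)

    @property
    def dm_genes(self) -> set[str]:
        return set().union(*(m.predictors for m in self.models.values())) if self.models else set()


@dataclass
class EvaluationResult:
    """Per-gene Spearman accuracy of predicted vs. true expression."""

    per_gene_rs: pd.Series
    mean_rs: float
    bootstrap_se: float | None
    n_models_used: int
    n_models_skipped: int
    n_undefined: int = 0  # genes whose rank correlation is undefined (constant vector)

    def to_json(self, path: str | None = None) -> str:
        payload = {
            "mean_rs": self.mean_rs,
            "bootstrap_se": self.bootstrap_se,
            "n_models_used": self.n_models_used,
            "n_models_skipped": self.n_models_skipped,
            "n_undefined": self.n_undefined,
            "per_gene_rs": {g: (None if np.isnan(v) else v) for g, v in self.per_gene_rs.items()},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def train_models(
    train_expr: pd.DataFrame,
    predictors: dict[str, list[str]],
    seed: int = 0,
    *,
    n_trees: int = 500,
    poly_degree: int = 2,
    forest_kwargs: dict | None = None,
) -> ImputationModelSet:
    """Fit one regression model per predictable gene on [0, 1]-scaled data.

    Dispatch: a seeded random forest (``n_trees`` regression trees,
    scikit-learn regression defaults otherwise) when a gene has at least 2
    predictors, else a least-squares polynomial of ``poly_degree`` in the
    single predictor.  Genes are fitted in sorted order with
    per-gene seeds drawn from one seeded stream, so results do not depend
    on dict ordering.
    """
    needed = set(predictors).union(*predictors.values()) if predictors else set()
    missing = sorted(needed - set(train_expr.index))
    if missing:
        raise ValueError(
            f"gene(s) required for training absent from the matrix: {', '.join(missing)}"
        )
    rng = np.random.default_rng(seed)
    models: dict[str, GeneModel] = {}
    for gene in sorted(predictors):
        preds = list(predictors[gene])
        y = train_expr.loc[gene].to_numpy(dtype=float)
        X = train_expr.loc[preds].to_numpy(dtype=float).T
        if len(preds) >= 2:
            est = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
                **(forest_kwargs or {}),
            )
            est.fit(X, y)
            models[gene] = GeneModel(gene, preds, "forest", estimator=est)
        else:
            rng.integers(0, 2**31 - 1)  # keep the seed stream aligned across dispatch
            x = X[:, 0]
            design = np.vander(x, N=poly_degree + 1, increasing=True)
            coef, *_ = np.linalg.lstsq(design, y, rcond=None)
            models[gene] = GeneModel(gene, preds, "polynomial", coefficients=coef)
    return ImputationModelSet(
        models,
        metadata={
            "seed": seed,
            "n_trees": n_trees,
            "poly_degree": poly_degree,
            "n_training_samples": train_expr.shape[1],
        },
    )


def predict_expression(
    model_set: ImputationModelSet, expr: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Apply the models to a [0, 1]-scaled dataset.

    Only models whose response gene and ALL predictor genes are present in
    the dataset are applied; the rest are skipped and returned for
    accounting.  Returns (predicted genes × samples matrix, skipped genes).
    """
    available = set(expr.index)
    rows = {}
    skipped: list[str] = []
    for gene in sorted(model_set.models):
        model = model_set.models[gene]
        if gene not in available or any(p not in available for p in model.predictors):
            skipped.append(gene)
            continue
        X = expr.loc[model.predictors].to_numpy(dtype=float).T
        rows[gene] = model.predict(X)
    if not rows:
        raise ValueError("no model is applicable to this dataset (all skipped)")
    predicted = pd.DataFrame.from_dict(rows, orient="index", columns=expr.columns)
    predicted.index.name = "gene"
    return predicted, skipped


def evaluate(
    predicted: pd.DataFrame,
    truth: pd.DataFrame,
    *,
    n_skipped: int = 0,
    bootstrap: int | None = None,
    seed: int = 0,
) -> EvaluationResult:
    """Per-gene Spearman rank correlation of predicted vs. true expression.

    Correlations use average ranks for ties.  A gene whose predicted or
    true vector is constant across samples has an undefined rank
    correlation; such genes are excluded from the mean and counted in
    ``n_undefined``.  If ``bootstrap`` is given, a bootstrapped standard
    error of the mean over genes is attached.
    """
    genes = predicted.index.intersection(truth.index)
    samples = predicted.columns.intersection(truth.columns)
    if len(samples) < 3:
        raise ValueError(f"only {len(samples)} shared sample(s); need at least 3")
    if len(genes) == 0:
        raise ValueError("predicted and truth matrices share no genes")
    rs = {}
    for g in genes:
        res = stats.spearmanr(predicted.loc[g, samples], truth.loc[g, samples])
        rs[g] = float(res.statistic)
    per_gene = pd.Series(rs, name="r_s")
    defined = per_gene.dropna()
    se = None
    if bootstrap is not None:
        se = bootstrap_se(defined.to_list(), bootstrap, seed)
    return EvaluationResult(
        per_gene_rs=per_gene,
        mean_rs=float(defined.mean()),
        bootstrap_se=se,
        n_models_used=len(genes),
        n_models_skipped=n_skipped,
        n_undefined=int(per_gene.isna().sum()),
    )


def bootstrap_se(values: list[float], B: int = 1000, seed: int = 0) -> float:
    """Bootstrapped standard error of the mean of per-gene accuracies:
    the standard deviation of the means of B with-replacement resamples."""
    if len(values) == 0:
        raise ValueError("cannot bootstrap an empty value list")
    if B < 2:
        raise ValueError(f"need at least 2 resamples, got {B}")
    arr = np.asarray(values, dtype=float)
    if arr.size == 1:
        return 0.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(B, arr.size))
    means = arr[idx].mean(axis=1)
    return float(means.std(ddof=1))


def save_models(model_set: ImputationModelSet, path: str) -> None:
    """Persist a model set (joblib) alongside a JSON metadata sidecar."""
    joblib.dump(model_set, path)
    meta = dict(model_set.metadata)
    meta["models"] = {
        g: {"kind": m.kind, "predictors": m.predictors}
        for g, m in model_set.models.items()
    }
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def load_models(path: str) -> ImputationModelSet:
    return joblib.load(path)
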