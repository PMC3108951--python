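"""Linear regression of miRNA-induced expression change on energy features.

The scorer is deliberately simple: ordinary least squares of observed
log2 fold change on the 14 per-UTR features.  Training uses only pairs
with negative observed change (down-regulation; positive changes are
dominated by indirect effects), optionally tightened to a -0.1 cutoff to
shed measurement noise.  Evaluation is five-fold cross-validation with
folds split at the gene level, scored by Spearman rank correlation; for
de novo prediction the median of the five fold models is the score, and
lower (more negative) scores mean stronger predicted down-regulation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr
from sklearn.model_selection import KFold

from .features import FEATURE_NAMES


@dataclass(frozen=True)
class LinearModel:
    """A fitted OLS scorer on the log2 fold-change scale."""

    intercept: float
    coefficients: dict[str, float]
    training_meta: dict = field(default_factory=dict)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.coefficients if f not in features.columns]
        if missing:
            raise ValueError(f"feature table lacks columns {missing}")
        X = features[list(self.coefficients)].to_numpy(dtype=float)
        beta = np.array([self.coefficients[f] for f in self.coefficients])
        return self.intercept + X @ beta

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "training_meta": self.training_meta,
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "LinearModel":
        obj = json.loads(text)
        return LinearModel(
            intercept=obj["intercept"],
            coefficients=obj["coefficients"],
            training_meta=obj.get("training_meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @staticmethod
    def load(path: str | Path) -> "LinearModel":
        return LinearModel.from_json(Path(path).read_text())


def filter_training_rows(data: pd.DataFrame, cutoff: float = 0.0) -> pd.DataFrame:
    """Keep rows with observed log2FC <= cutoff.

    ``cutoff=0`` keeps all down-regulated pairs; ``cutoff=-0.1`` is the
    noise-shedding retraining setting.
    """
    out = data[data["observed_log2fc"] <= cutoff]
    if out.empty:
        raise ValueError(f"no training rows at cutoff {cutoff}")
    return out.reset_index(drop=True)


def fit_ols(
    train: pd.DataFrame,
    feature_names: Sequence[str] = tuple(FEATURE_NAMES),
    meta: dict | None = None,
    ridge: float = 0.0,
) -> LinearModel:
    """OLS of observed_log2fc on the features (+ intercept).

    A rank-deficient design is fitted through the pseudoinverse with a
    warning naming the aliased directions; this happens by construction
    when e.g. the three energy sums are present together
    (sum_ddG = sum_dG_H - sum_dG_open identically).  ``ridge`` adds an
    L2 penalty (not on the intercept) for degenerate fixtures; the
    default model is plain least squares.
    """
    feature_names = list(feature_names)
    if len(train) <= len(feature_names):
        raise ValueError("need more rows than features")
    X = sm.add_constant(train[feature_names].to_numpy(dtype=float), has_constant="add")
    y = train["observed_log2fc"].to_numpy(dtype=float)
    if ridge > 0:
        penalty = np.eye(X.shape[1]) * ridge
        penalty[0, 0] = 0.0  # never shrink the intercept
        params = np.linalg.solve(X.T @ X + penalty, X.T @ y)
    else:
        res = sm.OLS(y, X).fit()
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(
                f"design rank {rank} < {X.shape[1]}: collinear features fitted via "
                "pseudoinverse (minimum-norm solution)"
            )
        params = np.asarray(res.params)
    return LinearModel(
        intercept=float(params[0]),
        coefficients={f: float(b) for f, b in zip(feature_names, params[1:])},
        training_meta={"n_train": int(len(train)), **(meta or {})},
    )


def fit_ols_with_se(train: pd.DataFrame, feature_names: Sequence[str] = tuple(FEATURE_NAMES)):
    """Like fit_ols but also returns standard errors (intercept first)."""
    feature_names = list(feature_names)
    X = sm.add_constant(train[feature_names].to_numpy(dtype=float), has_constant="add")
    y = train["observed_log2fc"].to_numpy(dtype=float)
    res = sm.OLS(y, X).fit()
    model = LinearModel(
        intercept=float(res.params[0]),
        coefficients={f: float(b) for f, b in zip(feature_names, res.params[1:])},
        training_meta={"n_train": int(len(train))},
    )
    return model, np.asarray(res.bse)


def cross_validate(
    data: pd.DataFrame,
    k: int = 5,
    rng_seed: int = 0,
    feature_names: Sequence[str] = tuple(FEATURE_NAMES),
) -> tuple[list[LinearModel], list[tuple[float, float]]]:
    """k-fold CV with folds split at the gene level.

    Genes (not rows) are partitioned into k disjoint folds, so each test
    fold contains rows from all miRNAs but no gene seen in training.
    Returns the k fold models and per-fold (Spearman rho, p) on the held
    out predictions.
    """
    genes = np.sort(data["gene_id"].unique())
    if k > len(genes):
        raise ValueError(f"k={k} exceeds number of genes ({len(genes)})")
    kf = KFold(n_splits=k, shuffle=True, random_state=rng_seed)
    models: list[LinearModel] = []
    scores: list[tuple[float, float]] = []
    for fold, (train_idx, test_idx) in enumerate(kf.split(genes)):
        train_genes = set(genes[train_idx])
        test_genes = set(genes[test_idx])
        train = data[data["gene_id"].isin(train_genes)]
        test = data[data["gene_id"].isin(test_genes)]
        model = fit_ols(train, feature_names, meta={"fold": fold})
        models.append(model)
        pred = model.predict(test)
        rho, p = spearmanr(pred, test["observed_log2fc"].to_numpy())
        scores.append((float(rho), float(p)))
    return models, scores


def predict_median(models: Sequence[LinearModel], features: pd.DataFrame) -> np.ndarray:
    """Median of the fold-model predictions (stabilized de novo score)."""
    if not models:
        raise ValueError("need at least one model")
    schema = set(models[0].coefficients)
    for m in models[1:]:
        if set(m.coefficients) != schema:
            raise ValueError("models disagree on feature schema")
    preds = np.vstack([m.predict(features) for m in models])
    return np.median(preds, axis=0)
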