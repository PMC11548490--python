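"""Regression models, the 7:3 split protocol, and accuracy metrics.

Six algorithms are supported — Adaboost, Xgboost, RF, GBRT, SVR, GPR — each
with documented frozen default hyperparameters (the kernel methods run behind
feature/target standardization).  An optional ``tune=True`` path selects
hyperparameters by K-fold cross-validation (default 5-fold) within the 70 %
modeling partition over small grids; held-out metrics always come from the
30 % validation partition.

Accuracy metrics:

.. math::

    R^2 = 1 - \\frac{\\sum (o-p)^2}{\\sum (o-\\bar o)^2} \\qquad
    RMSE = \\sqrt{\\tfrac 1 n \\sum (o-p)^2} \\qquad
    NRMSE = 100 \\cdot RMSE / \\bar o \\;[\\%]
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.compose import TransformedTargetRegressor
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .errors import InsufficientDataError, InvalidArgumentError, SchemaError
from .selection import FeatureScheme

__all__ = [
    "ALGORITHMS",
    "SplitSpec",
    "ModelSpec",
    "EvalResult",
    "split",
    "evaluate",
    "make_model",
    "fit_predict",
    "run_matrix",
]

ALGORITHMS: tuple[str, ...] = ("Adaboost", "Xgboost", "RF", "GBRT", "SVR", "GPR")


@dataclass(frozen=True)
class SplitSpec:
    """Modeling/validation split protocol."""

    train_fraction: float = 0.7
    strategy: str = "stratified"  # "random" | "stratified" (by stage)
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise InvalidArgumentError("train fraction must lie in (0, 1)")
        if self.strategy not in {"random", "stratified"}:
            raise InvalidArgumentError(f"unknown split strategy {self.strategy!r}")
        if self.k_folds < 2:
            raise InvalidArgumentError("k_folds must be >= 2")


@dataclass(frozen=True)
class ModelSpec:
    """One regression algorithm plus hyperparameter overrides."""

    algorithm: str
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0
    tune: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise InvalidArgumentError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )


@dataclass
class EvalResult:
    """Validation accuracy of one (algorithm, scheme, stage) cell."""

    algorithm: str
    scheme: str
    stage: str
    n_train: int
    n_val: int
    r2: float
    rmse: float
    nrmse: float
    seed: int
    observed: np.ndarray
    predicted: np.ndarray
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# split and metrics
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split(
    table: pd.DataFrame, spec: SplitSpec, stage_column: str = "stage"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition samples into modeling and validation sets (default 7:3).

    ``|train| = round(train_fraction * n)``; the stratified strategy preserves
    per-stage proportions to within one sample.  Deterministic under the seed.
    """
    n = len(table)
    if n < 10:
        raise InsufficientDataError(f"need >= 10 samples to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    if spec.strategy == "stratified" and stage_column in table.columns:
        train_idx: list[int] = []
        # largest-remainder allocation keeps the global 7:3 ratio exact
        groups = [
            (stage, np.asarray(idx))
            for stage, idx in table.groupby(stage_column, sort=True).indices.items()
        ]
        quotas = [spec.train_fraction * len(idx) for _, idx in groups]
        base = [int(np.floor(q)) for q in quotas]
        target = _round_half_up(spec.train_fraction * n)
        remainders = np.array([q - b for q, b in zip(quotas, base)])
        extra = target - sum(base)
        order = np.argsort(-remainders, kind="mergesort")[: max(extra, 0)]
        for g, (stage, idx) in enumerate(groups):
            k = base[g] + (1 if g in set(order.tolist()) else 0)
            perm = rng.permutation(len(idx))
            train_idx.extend(idx[perm[:k]].tolist())
        train_mask = np.zeros(n, dtype=bool)
        train_mask[train_idx] = True
    else:
        n_train = _round_half_up(spec.train_fraction * n)
        perm = rng.permutation(n)
        train_mask = np.zeros(n, dtype=bool)
        train_mask[perm[:n_train]] = True
    return table.iloc[train_mask].copy(), table.iloc[~train_mask].copy()


def evaluate(
    observed: Sequence[float], predicted: Sequence[float]
) -> tuple[float, float, float]:
    """Return (R², RMSE, NRMSE %) for paired observed/predicted biomass.

    R² is NaN for zero-variance observations; NRMSE is NaN when the observed
    mean is non-positive.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape or o.size < 2:
        raise InvalidArgumentError("need equal-length observed/predicted with n >= 2")
    sse = float(((o - p) ** 2).sum())
    sst = float(((o - o.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    rmse = float(np.sqrt(sse / o.size))
    mean_obs = float(o.mean())
    nrmse = 100.0 * rmse / mean_obs if mean_obs > 0 else np.nan
    return r2, rmse, nrmse


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def _default_estimator(algorithm: str, seed: int, params: Mapping[str, object]):
    p = dict(params)
    if algorithm == "RF":
        kwargs = dict(n_estimators=500, max_features=0.5, random_state=seed, n_jobs=1)
        kwargs.update(p)
        return RandomForestRegressor(**kwargs)
    if algorithm == "GBRT":
        kwargs = dict(
            n_estimators=500, learning_rate=0.05, max_depth=3, random_state=seed
        )
        kwargs.update(p)
        return GradientBoostingRegressor(**kwargs)
    if algorithm == "Adaboost":
        depth = int(p.pop("base_max_depth", 6))
        kwargs = dict(
            estimator=DecisionTreeRegressor(max_depth=depth, random_state=seed),
            n_estimators=300,
            learning_rate=0.5,
            random_state=seed,
        )
        kwargs.update(p)
        return AdaBoostRegressor(**kwargs)
    if algorithm == "Xgboost":
        kwargs = dict(
            n_estimators=500,
            learning_rate=0.05,
            max_depth=4,
            subsample=0.9,
            colsample_bytree=0.9,
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
        kwargs.update(p)
        return XGBRegressor(**kwargs)
    if algorithm == "SVR":
        kwargs = dict(kernel="rbf", C=10.0, epsilon=0.1, gamma="scale")
        kwargs.update(p)
        pipe = Pipeline([("scale", StandardScaler()), ("svr", SVR(**kwargs))])
        return TransformedTargetRegressor(regressor=pipe, transformer=StandardScaler())
    if algorithm == "GPR":
        kernel = ConstantKernel(1.0) * RBF(length_scale=1.0) + WhiteKernel(
            noise_level=0.1
        )
        kwargs = dict(kernel=kernel, normalize_y=True, random_state=seed, alpha=1e-8)
        kwargs.update(p)
        pipe = Pipeline(
            [("scale", StandardScaler()), ("gpr", GaussianProcessRegressor(**kwargs))]
        )
        return pipe
    raise InvalidArgumentError(f"unknown algorithm {algorithm!r}")


#: small hyperparameter grids used by the optional CV tuning path
_TUNE_GRIDS: dict[str, dict[str, list]] = {
    "RF": {"max_features": [0.33, 0.5, 1.0]},
    "GBRT": {"learning_rate": [0.03, 0.05, 0.1]},
    "Adaboost": {"learning_rate": [0.3, 0.5, 1.0]},
    "Xgboost": {"max_depth": [3, 4, 6]},
    "SVR": {"regressor__svr__C": [1.0, 10.0, 100.0]},
    "GPR": {"gpr__alpha": [1e-8, 1e-4]},
}


def make_model(spec: ModelSpec, k_folds: int = 5):
    """Instantiate the estimator for a model spec (optionally grid-searched by
    K-fold CV on the training partition when fitted)."""
    estimator = _default_estimator(spec.algorithm, spec.seed, spec.params)
    if spec.tune:
        return GridSearchCV(
            estimator,
            _TUNE_GRIDS[spec.algorithm],
            cv=k_folds,
            scoring="neg_root_mean_squared_error",
            n_jobs=1,
        )
    return estimator


def fit_predict(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    model: ModelSpec,
    scheme: FeatureScheme,
    response: str = "agb",
    k_folds: int = 5,
) -> EvalResult:
    """Train on the modeling partition (scheme columns only) and score on the
    held-out validation partition."""
    cols = list(scheme.features)
    for frame, label in ((train, "train"), (validation, "validation")):
        missing = [c for c in cols + [response] if c not in frame.columns]
        if missing:
            raise SchemaError(f"{label} partition lacks columns {missing}")
    train = train.dropna(subset=cols + [response])
    validation = validation.dropna(subset=cols + [response])
    if len(train) < 5 or len(validation) < 2:
        raise InsufficientDataError("too few complete samples after NaN filtering")
    y_train = train[response].to_numpy(dtype=float)
    if np.std(y_train) == 0:
        raise InsufficientDataError("degenerate training response (zero variance)")
    estimator = make_model(model, k_folds)
    estimator.fit(train[cols].to_numpy(dtype=float), y_train)
    observed = validation[response].to_numpy(dtype=float)
    predicted = np.asarray(
        estimator.predict(validation[cols].to_numpy(dtype=float)), dtype=float
    )
    r2, rmse, nrmse = evaluate(observed, predicted)
    flags = []
    if np.isnan(r2):
        flags.append("r2-undefined")
    if np.isnan(nrmse):
        flags.append("nrmse-undefined")
    return EvalResult(
        algorithm=model.algorithm,
        scheme=scheme.name,
        stage="pooled",
        n_train=len(train),
        n_val=len(validation),
        r2=r2,
        rmse=rmse,
        nrmse=nrmse,
        seed=model.seed,
        observed=observed,
        predicted=predicted,
        flags=tuple(flags),
    )


def run_matrix(
    table: pd.DataFrame,
    schemes: Mapping[str, FeatureScheme],
    algorithms: Sequence[str] = ALGORITHMS,
    split_spec: SplitSpec | None = None,
    stages: str = "pooled+stages",
    response: str = "agb",
    stage_column: str = "stage",
    tune: bool = False,
) -> tuple[pd.DataFrame, list[EvalResult]]:
    """Evaluate every (scheme, algorithm, stage ∪ pooled) cell.

    Stage-wise cells are fit on that stage's samples only; the pooled cell uses
    all samples.  Per-cell failures are recorded in the ``status`` column, not
    raised.  Returns a tidy results table plus the full EvalResult list.
    """
    split_spec = split_spec or SplitSpec()
    if stages == "pooled":
        stage_values: list[str | None] = [None]
    elif stages == "pooled+stages":
        stage_values = [None] + sorted(table[stage_column].unique().tolist())
    else:
        raise InvalidArgumentError(f"unknown stages mode {stages!r}")
    rows = []
    results: list[EvalResult] = []
    for stage in stage_values:
        subset = table if stage is None else table[table[stage_column] == stage]
        stage_label = "pooled" if stage is None else str(stage)
        try:
            train, validation = split(subset, split_spec, stage_column)
        except InsufficientDataError as exc:
            for scheme in schemes.values():
                for algorithm in algorithms:
                    rows.append(
                        _result_row(scheme.name, algorithm, stage_label, error=str(exc))
                    )
            continue
        for scheme in schemes.values():
            for algorithm in algorithms:
                spec = ModelSpec(algorithm, seed=split_spec.seed, tune=tune)
                try:
                    result = fit_predict(
                        train, validation, spec, scheme, response, split_spec.k_folds
                    )
                except Exception as exc:  # per-cell failures are not fatal
                    rows.append(
                        _result_row(scheme.name, algorithm, stage_label, error=str(exc))
                    )
                    continue
                result.stage = stage_label
                results.append(result)
                rows.append(
                    _result_row(
                        scheme.name,
                        algorithm,
                        stage_label,
                        n_train=result.n_train,
                        n_val=result.n_val,
                        r2=result.r2,
                        rmse=result.rmse,
                        nrmse=result.nrmse,
                        seed=result.seed,
                    )
                )
    frame = pd.DataFrame.from_records(rows)
    return frame, results


def _result_row(
    scheme: str,
    algorithm: str,
    stage: str,
    n_train: int | None = None,
    n_val: int | None = None,
    r2: float = np.nan,
    rmse: float = np.nan,
    nrmse: float = np.nan,
    seed: int | None = None,
    error: str | None = None,
) -> dict:
    return {
        "scheme": scheme,
        "algorithm": algorithm,
        "stage": stage,
        "n_train": n_train,
        "n_val": n_val,
        "R2": r2,
        "RMSE_kg_ha": rmse,
        "NRMSE_pct": nrmse,
        "seed": seed,
        "status": "ok" if error is None else f"error: {error}",
    }


def scheme_hash(scheme: FeatureScheme) -> str:
    """Stable short hash of a scheme's ordered feature list (provenance)."""
    payload = scheme.name + "|" + "|".join(scheme.features)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
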