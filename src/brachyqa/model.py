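"""RBF-kernel support-vector regression of D2cm3/Dprescription on
sub-OAR ring volumes.

One model per organ maps the six-element feature vector (global volume +
five ring-intersection volumes, cm^3) to the dimensionless per-fraction
D2cm3/Dprescription ratio.  Hyperparameters C and gamma are chosen by a
cross-validated grid search on the training split only; features are
z-scored before kernel evaluation so the squared distances in
K(x, y) = exp(-gamma * ||x - y||^2) combine comparable scales.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from . import stats


def rbf_kernel(x, y, gamma: float) -> float:
    """Gaussian radial basis kernel exp(-gamma * ||x - y||^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return float(np.exp(-gamma * np.sum((x - y) ** 2)))


def gram_matrix(X, gamma: float) -> np.ndarray:
    """RBF Gram matrix for a row-wise sample matrix."""
    X = np.asarray(X, dtype=float)
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    return np.exp(-gamma * np.maximum(d2, 0.0))


@dataclass
class SVRConfig:
    """Grid-search and fitting configuration.

    epsilon is the insensitive-tube half width on the ratio scale
    (0.01 corresponds to ~0.07 Gy at a 7 Gy prescription).
    """

    C_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0)
    gamma_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0)
    epsilon: float = 0.01
    cv_folds: int = 5
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.cv_folds < 2:
            raise ValueError("need at least 2 CV folds")


@dataclass
class TrainedModel:
    """A fitted per-organ epsilon-SVR, self-contained for prediction.

    Stores the standardized support vectors, dual coefficients and bias,
    plus the feature standardization constants, so prediction (and JSON
    serialization) does not depend on the fitting backend.
    """

    organ: str
    C: float
    gamma: float
    epsilon: float
    support_vectors: np.ndarray  # standardized feature space
    dual_coef: np.ndarray
    intercept: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    kept_features: np.ndarray  # indices into the raw feature vector
    n_features_raw: int = 6
    constant_target: float | None = None
    training_mse: float = float("nan")
    training_r2: float = float("nan")
    cv_mse: float = float("nan")

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        X = X[:, self.kept_features]
        return (X - self.feature_mean) / self.feature_scale


def predict(model: TrainedModel, features) -> np.ndarray:
    """Predicted D2cm3/Dprescription ratios for one or more feature rows."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.n_features_raw:
        raise ValueError(
            f"feature dimension {X.shape[1]} != training dimension "
            f"{model.n_features_raw}"
        )
    if model.constant_target is not None:
        return np.full(len(X), model.constant_target)
    Xs = model._standardize(X)
    sv = model.support_vectors
    d2 = (
        np.sum(Xs**2, axis=1)[:, None]
        + np.sum(sv**2, axis=1)[None, :]
        - 2.0 * Xs @ sv.T
    )
    K = np.exp(-model.gamma * np.maximum(d2, 0.0))
    return K @ model.dual_coef + model.intercept


def _fit_svr(Xs, y, C, gamma, epsilon) -> SVR:
    # tol well below epsilon: the default 1e-3 leaves optimizer slack of
    # the same order as the residuals we care about
    svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon, tol=1e-8)
    svr.fit(Xs, y)
    return svr


def train_svr(
    features, targets, cfg: SVRConfig | None = None, organ: str = ""
) -> TrainedModel:
    """Grid-searched epsilon-SVR fit.

    (C, gamma) minimize the k-fold cross-validated MSE on the training
    rows; ties break toward smaller C, then smaller gamma (the smoother
    model).  The winner is refit on all rows and training MSE / R^2
    recorded.  Constant feature columns are dropped with a warning;
    constant targets produce a degenerate model predicting the constant.
    """
    cfg = cfg or SVRConfig()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    if len(X) != len(y):
        raise ValueError("features and targets disagree in length")
    if len(y) < 10:
        raise ValueError("need at least 10 training rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("missing or non-finite values in training data")

    keep = np.flatnonzero(np.ptp(X, axis=0) > 0)
    if len(keep) < X.shape[1]:
        dropped = sorted(set(range(X.shape[1])) - set(keep))
        warnings.warn(f"dropping constant feature columns {dropped}")
    if np.ptp(y) == 0:
        return TrainedModel(
            organ=organ, C=np.nan, gamma=np.nan, epsilon=cfg.epsilon,
            support_vectors=np.empty((0, len(keep))),
            dual_coef=np.empty(0), intercept=0.0,
            feature_mean=np.zeros(len(keep)), feature_scale=np.ones(len(keep)),
            kept_features=keep, n_features_raw=X.shape[1],
            constant_target=float(y[0]), training_mse=0.0,
        )

    Xk = X[:, keep]
    if cfg.standardize:
        mean = Xk.mean(axis=0)
        scale = Xk.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(Xk.shape[1])
        scale = np.ones(Xk.shape[1])
    Xs = (Xk - mean) / scale

    kf = KFold(n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed)
    folds = list(kf.split(Xs))
    best = None  # (cv_mse, C, gamma)
    for C in sorted(cfg.C_grid):
        for gamma in sorted(cfg.gamma_grid):
            errs = []
            for tr, va in folds:
                svr = _fit_svr(Xs[tr], y[tr], C, gamma, cfg.epsilon)
                errs.append(stats.mse(y[va], svr.predict(Xs[va])))
            cv_mse = float(np.mean(errs))
            if best is None or cv_mse < best[0] - 1e-15:
                best = (cv_mse, C, gamma)
    cv_mse, C, gamma = best

    svr = _fit_svr(Xs, y, C, gamma, cfg.epsilon)
    model = TrainedModel(
        organ=organ, C=C, gamma=gamma, epsilon=cfg.epsilon,
        support_vectors=Xs[svr.support_],
        dual_coef=svr.dual_coef_.ravel().copy(),
        intercept=float(svr.intercept_[0]),
        feature_mean=mean, feature_scale=scale, kept_features=keep,
        n_features_raw=X.shape[1], cv_mse=cv_mse,
    )
    pred = predict(model, X)
    model.training_mse = stats.mse(y, pred)
    model.training_r2 = stats.r_squared(y, pred)
    return model


def split_cohort(cohort, n_train: int = 160, n_valid: int = 40, seed: int = 0):
    """Random, reproducible, disjoint and exhaustive train/validation split."""
    cohort = list(cohort)
    if len(cohort) != n_train + n_valid:
        raise ValueError(
            f"cohort size {len(cohort)} != n_train + n_valid = {n_train + n_valid}"
        )
    order = np.random.default_rng(seed).permutation(len(cohort))
    train = [cohort[i] for i in order[:n_train]]
    valid = [cohort[i] for i in order[n_train:]]
    return train, valid


@dataclass
class EvaluationReport:
    """Validation-set performance of one per-organ model."""

    organ: str
    mse: float
    r_squared: float
    delta: stats.DeltaSummary
    pearson: dict[str, tuple[float, float]]  # feature name -> (r, p)
    paired_t: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "organ": self.organ,
            "n": self.n,
            "mse": self.mse,
            "r_squared": self.r_squared,
            "delta_mean": self.delta.mean,
            "delta_sd": self.delta.sd,
            "paired_t": self.paired_t[0],
            "paired_t_p": self.paired_t[1],
            "pearson": {k: {"r": v[0], "p": v[1]} for k, v in self.pearson.items()},
        }


def evaluate(
    model: TrainedModel,
    features,
    actual_ratios,
    feature_names: list[str] | None = None,
) -> EvaluationReport:
    """Score a model on held-out plans.

    Pearson correlations are between each input feature and the actual
    ratio (the volume-dose relationship the model exploits); the paired
    t-test compares predicted with actual ratios.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(actual_ratios, dtype=float).ravel()
    if len(y) == 0:
        raise ValueError("empty validation set")
    pred = predict(model, X)
    names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    pearson = {}
    for j, name in enumerate(names):
        try:
            pearson[name] = stats.pearson_r(X[:, j], y)
        except ValueError:
            pearson[name] = (float("nan"), float("nan"))
    return EvaluationReport(
        organ=model.organ,
        mse=stats.mse(y, pred),
        r_squared=stats.r_squared(y, pred),
        delta=stats.delta_stat(y, pred),
        pearson=pearson,
        paired_t=stats.paired_t_test(pred, y),
        n=len(y),
    )


# ---------------------------------------------------------------------------
# JSON serialization


def save_model(model: TrainedModel, path: str | Path) -> None:
    d = {
        "organ": model.organ,
        "C": model.C,
        "gamma": model.gamma,
        "epsilon": model.epsilon,
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "feature_mean": model.feature_mean.tolist(),
        "feature_scale": model.feature_scale.tolist(),
        "kept_features": model.kept_features.tolist(),
        "n_features_raw": model.n_features_raw,
        "constant_target": model.constant_target,
        "training_mse": model.training_mse,
        "training_r2": model.training_r2,
        "cv_mse": model.cv_mse,
    }
    Path(path).write_text(json.dumps(d))


def load_model(path: str | Path) -> TrainedModel:
    d = json.loads(Path(path).read_text())
    return TrainedModel(
        organ=d["organ"],
        C=d["C"],
        gamma=d["gamma"],
        epsilon=d["epsilon"],
        support_vectors=np.asarray(d["support_vectors"], dtype=float),
        dual_coef=np.asarray(d["dual_coef"], dtype=float),
        intercept=d["intercept"],
        feature_mean=np.asarray(d["feature_mean"], dtype=float),
        feature_scale=np.asarray(d["feature_scale"], dtype=float),
        kept_features=np.asarray(d["kept_features"], dtype=int),
        n_features_raw=d["n_features_raw"],
        constant_target=d["constant_target"],
        training_mse=d["training_mse"],
        training_r2=d["training_r2"],
        cv_mse=d["cv_mse"],
    )
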