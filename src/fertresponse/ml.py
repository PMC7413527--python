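"""Machine-learning response models: KNN, random forest, neural network,
Gaussian process — random-search tuning with 5-fold cross-validation, and
seeded joint posterior sampling for the GP."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.ensemble import RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.model_selection import KFold, RandomizedSearchCV
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor

__all__ = ["ModelSpec", "TunedModel", "tune_fit", "gp_posterior", "draw_samples",
           "FAMILIES"]

FAMILIES = ("KNN", "RF", "NN", "GP")


@dataclass(frozen=True)
class ModelSpec:
    """Family plus hyperparameter search configuration.

    The default spaces mirror the tuned configurations reported for potato
    response modelling: KNN with Euclidean distance and uniform or
    inverse-distance weights; RF over tree counts; a single-hidden-layer
    tanh perceptron sized 100 or 200; a Matern-kernel GP with a searchable
    noise level.
    """

    family: str
    search_space: dict | None = None
    cv_folds: int = 5
    n_search_iter: int = 50
    seed: int = 0
    gp_max_rows: int = 2000

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_search_iter < 1:
            raise ValueError("n_search_iter must be >= 1")
        if self.search_space is not None and not self.search_space:
            raise ValueError("search_space must be non-empty when given")


@dataclass
class TunedModel:
    family: str
    estimator: object
    hyperparameters: dict
    cv_score: float  # mean CV negative RMSE of the chosen configuration

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float)))


def _default_space(family: str, seed: int) -> tuple[object, dict]:
    if family == "KNN":
        est = KNeighborsRegressor(metric="euclidean")
        space = {"n_neighbors": randint(3, 26),
                 "weights": ["uniform", "distance"]}
    elif family == "RF":
        est = RandomForestRegressor(random_state=seed)
        space = {"n_estimators": randint(10, 151),
                 "max_features": ["sqrt", "log2", 1.0]}
    elif family == "NN":
        est = MLPRegressor(activation="tanh", solver="adam", max_iter=1500,
                           n_iter_no_change=25, tol=1e-5, random_state=seed)
        space = {"hidden_layer_sizes": [(100,), (200,)],
                 "alpha": loguniform(1e-5, 1e-1),
                 "learning_rate_init": loguniform(5e-4, 2e-2)}
    elif family == "GP":
        est = GaussianProcessRegressor(normalize_y=True, random_state=seed)
        kernels = []
        for nu in (0.5, 1.5, 2.5):
            base = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
                length_scale=1.0, length_scale_bounds=(1e-2, 1e3), nu=nu)
            kernels.append(base)  # noise-free kernel
            kernels.append(base + WhiteKernel(0.1, (1e-6, 1e1)))
        space = {"kernel": kernels, "alpha": [1e-10, 1e-6, 1e-2]}
    else:  # pragma: no cover
        raise ValueError(family)
    return est, space


def tune_fit(spec: ModelSpec, X, y) -> TunedModel:
    """Random-search CV tuning, then refit of the best configuration.

    Scoring is negative RMSE over seeded shuffled K-fold CV.  GPs are fitted
    on at most ``spec.gp_max_rows`` seeded-subsampled rows for tractability.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if np.std(y) == 0:
        raise ValueError("degenerate target: zero variance")

    rng = np.random.default_rng(spec.seed)
    if spec.family == "GP" and len(y) > spec.gp_max_rows:
        keep = rng.choice(len(y), size=spec.gp_max_rows, replace=False)
        X, y = X[keep], y[keep]

    est, space = _default_space(spec.family, spec.seed)
    if spec.search_space is not None:
        space = spec.search_space

    n_iter = spec.n_search_iter
    sizes = [len(v) for v in space.values() if isinstance(v, (list, tuple))]
    if sizes and all(isinstance(v, (list, tuple)) for v in space.values()):
        n_iter = min(n_iter, int(np.prod(sizes)))

    cv = KFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = RandomizedSearchCV(
        est, space, n_iter=n_iter, cv=cv,
        scoring="neg_root_mean_squared_error",
        random_state=spec.seed, n_jobs=1, refit=True, error_score="raise",
    )
    search.fit(X, y)
    return TunedModel(
        family=spec.family,
        estimator=search.best_estimator_,
        hyperparameters={k: (v if np.isscalar(v) or isinstance(v, (tuple, str))
                             else str(v))
                         for k, v in search.best_params_.items()},
        cv_score=float(search.best_score_),
    )


def _as_gp(model):
    """Unwrap to a posterior-capable regressor (predict with return_cov)."""
    import inspect

    gp = model.estimator if isinstance(model, TunedModel) else model
    if isinstance(gp, GaussianProcessRegressor):
        return gp
    try:
        if "return_cov" in inspect.signature(gp.predict).parameters:
            return gp
    except (AttributeError, TypeError, ValueError):
        pass
    raise TypeError("posterior sampling requires a fitted Gaussian process")


def gp_posterior(model, X) -> tuple[np.ndarray, np.ndarray]:
    """Joint posterior mean and covariance of a fitted GP over rows of X."""
    gp = _as_gp(model)
    mean, cov = gp.predict(np.asarray(X, dtype=float), return_cov=True)
    return np.asarray(mean), np.asarray(cov)


def draw_samples(model, X, n_samples: int, seed: int = 0,
                 max_jitter: float = 1e-4) -> np.ndarray:
    """Seeded joint posterior draws, shape (n_samples, len(X)).

    Uses a Cholesky factor of the posterior covariance with escalating
    diagonal jitter; raises if the covariance stays non-positive-definite at
    ``max_jitter``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    mean, cov = gp_posterior(model, X)
    jitter = 1e-10
    chol = None
    while jitter <= max_jitter:
        try:
            chol = np.linalg.cholesky(cov + jitter * np.eye(len(cov)))
            break
        except np.linalg.LinAlgError:
            jitter *= 100
    if chol is None:
        raise np.linalg.LinAlgError(
            f"posterior covariance not positive definite at jitter {max_jitter}")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_samples, len(mean)))
    return mean[None, :] + z @ chol.T
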