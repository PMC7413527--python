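"""Regression goodness-of-fit metrics: R-squared, MAE, RMSE."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["r_squared", "mean_absolute_error", "root_mean_squared_error", "EvalReport", "evaluate"]


def _check(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty evaluation set")
    if y.size != yhat.size:
        raise ValueError("observed and predicted lengths differ")
    return y, yhat


def r_squared(y, yhat) -> float:
    """Coefficient of determination: 1 - SSE / SST.

    1 for a perfect fit, exactly 0 for a predictor that always outputs the
    observed mean, negative for arbitrarily worse models.
    """
    y, yhat = _check(y, yhat)
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("target has zero variance; R^2 undefined")
    return 1.0 - sse / sst


def mean_absolute_error(y, yhat) -> float:
    y, yhat = _check(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def root_mean_squared_error(y, yhat) -> float:
    y, yhat = _check(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass(frozen=True)
class EvalReport:
    """Metric bundle for one (model, target, split) cell."""

    r2: float
    mae: float
    rmse: float
    n: int
    model: str = ""
    target: str = ""
    split: str = ""
    hyperparameters: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "target": self.target,
            "split": self.split,
            "n": self.n,
            "r2": self.r2,
            "mae": self.mae,
            "rmse": self.rmse,
            **{f"hp_{k}": v for k, v in self.hyperparameters.items()},
        }


def evaluate(y, yhat, *, model: str = "", target: str = "", split: str = "",
             hyperparameters: dict | None = None) -> EvalReport:
    """Compute R^2, MAE and RMSE for one prediction vector."""
    y, yhat = _check(y, yhat)
    return EvalReport(
        r2=r_squared(y, yhat),
        mae=mean_absolute_error(y, yhat),
        rmse=root_mean_squared_error(y, yhat),
        n=int(y.size),
        model=model,
        target=target,
        split=split,
        hyperparameters=dict(hyperparameters or {}),
    )
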